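#!/usr/bin/env python
"""TPS-style corrected PDD curves from the analytic correction algorithms.

Reads the homogeneous curves and beam data produced by 02_monte_carlo_pdd
and applies the generalized Batho, modified Batho, and equivalent-TAR
corrections for the slab phantom, for each of the four fields.

Writes results/corrections/{method}_LxL.csv.
"""

from pathlib import Path

from lungpdd.cli_io import read_beam_data, read_pdd, write_pdd
from lungpdd.hetero_corrections import METHODS, corrected_pdd
from lungpdd.mc_engine import BeamConfig
from lungpdd.synthetic_data import make_reference_phantom, synthesize_spectrum

MC = Path("results/mc")
OUT = Path("results/corrections")
OUT.mkdir(parents=True, exist_ok=True)

phantom = make_reference_phantom()
spectrum = synthesize_spectrum(15.0)
data = read_beam_data(MC / "beam_data.csv")

for side in (1.0, 2.0, 5.0, 10.0):
    tag = f"{side:g}x{side:g}"
    hom = read_pdd(MC / f"hom_{tag}.csv")
    beam = BeamConfig(spectrum=spectrum, square_side_cm=side)
    line = [tag]
    for method in METHODS:
        corr = corrected_pdd(method, hom, phantom, beam, data)
        write_pdd(corr, OUT / f"{method}_{tag}.csv")
        line.append(f"{method}: mid-lung {corr.value_at(11.75):.1f}%")
    print("  ".join(line))
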