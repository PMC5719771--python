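#!/usr/bin/env python
"""Ratio curves and interface metrics: corrected algorithms vs Monte Carlo.

For each field size, forms the per-depth ratio of every corrected curve to
the heterogeneous Monte Carlo reference, extracts the interface metrics
(lung overdose near the soft-tissue/lung interface, soft-tissue underdose
past the lung, worst lung discrepancy), and renders the PDD overlays and
ratio plots.

Writes results/comparison/{metrics.json, ratio_*.csv, fig_*.png}.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from lungpdd.cli_io import read_pdd
from lungpdd.comparison import interface_metrics, ratio_curve
from lungpdd.hetero_corrections import METHODS
from lungpdd.synthetic_data import make_reference_phantom

MC = Path("results/mc")
CORR = Path("results/corrections")
OUT = Path("results/comparison")
OUT.mkdir(parents=True, exist_ok=True)

phantom = make_reference_phantom()
metrics: dict = {}

for side in (1.0, 2.0, 5.0, 10.0):
    tag = f"{side:g}x{side:g}"
    het = read_pdd(MC / f"het_{tag}.csv")
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 8), sharex=True)
    ax1.plot(het.depths_cm, het.values, "k.-", label="Monte Carlo")
    metrics[tag] = {}
    for method in METHODS:
        corr = read_pdd(CORR / f"{method}_{tag}.csv")
        r = ratio_curve(corr, het)
        m = interface_metrics(r, phantom)
        metrics[tag][method] = {
            "lung_overdose_pct": m.lung_overdose_pct,
            "soft_underdose_pct": m.soft_underdose_pct,
            "max_lung_discrepancy_pct": m.max_lung_discrepancy_pct,
        }
        np.savetxt(OUT / f"ratio_{method}_{tag}.csv",
                   np.column_stack([r.depths_cm, r.ratio, r.rel_se]),
                   delimiter=",", header="depth_cm,ratio,rel_se", comments="")
        ax1.plot(corr.depths_cm, corr.values, label=method)
        ax2.plot(r.depths_cm, r.ratio, label=method)
    for ax in (ax1, ax2):
        for z in phantom.interfaces:
            ax.axvline(z, color="0.7", ls="--", lw=0.8)
        ax.legend(fontsize=8)
    ax1.set_ylabel("PDD (%)")
    ax2.set_ylabel("corrected / Monte Carlo")
    ax2.axhline(1.0, color="0.5", lw=0.8)
    ax2.set_xlabel("depth (cm)")
    ax1.set_title(f"{tag} cm$^2$ field, 15 MV, acrylic/lung/acrylic phantom")
    fig.savefig(OUT / f"fig_{tag}.png", dpi=110)
    plt.close(fig)

(OUT / "metrics.json").write_text(json.dumps(metrics, indent=2))

print("worst lung discrepancy (corrected vs MC), % by field and method:")
for tag, per in metrics.items():
    worst = max(m["max_lung_discrepancy_pct"] for m in per.values())
    cells = "  ".join(
        f"{meth}={m['max_lung_discrepancy_pct']:.0f}%" for meth, m in per.items())
    print(f"  {tag}: {cells}   worst={worst:.0f}%")
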