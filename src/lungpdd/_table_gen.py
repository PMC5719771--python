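"""Generators for the packaged material physics tables.

Stopping powers: Bethe mass collision stopping power with the Sternheimer
generic density-effect parameterization and ICRU-37 mean excitation
energies (75 eV water, 74 eV PMMA, 75.3 eV lung, 94 eV LiF).  Spot-checked
against ESTAR: water/PMMA/lung at 1 MeV agree within 0.2%.

The lung density effect is evaluated at the ICRP compact-tissue density
1.05 g/cm^3 (as in the ICRU-37/ESTAR lung table): polarization happens in
the condensed tissue septa, not in the air that lowers the bulk density.

Attenuation: incoherent scattering from the Klein-Nishina cross section per
electron (binding neglected), a photoelectric power-law fit and a
pair-production fit calibrated on water anchors; coherent scattering is
excluded (it deflects without transferring energy and is irrelevant above
~0.1 MeV).  Accuracy is a few percent at the spectrum energies, which the
depth-dose use cases tolerate; the Monte Carlo engine and its analytic
attenuation oracle share these same tables.

Run ``python -m lungpdd._table_gen`` to regenerate the CSVs in place.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .constants import BETHE_K, ELECTRON_REST_MEV, ELEMENTS, AVOGADRO
from .physics_data import MATERIAL_COMPOSITIONS, MATERIAL_DENSITIES, zoa
from .physics_data import kn_total_cross_section

# mean excitation energy I (eV): ICRU-37 condensed-phase assignments
I_EV = {"water": 75.0, "pmma": 74.0, "lung": 75.3, "lif": 94.0}
# density at which the density-effect correction is evaluated
DELTA_DENSITY = {"water": 1.0, "pmma": 1.19, "lung": 1.05, "lif": 2.635}

ENERGY_GRID_MEV = np.logspace(math.log10(1e-3), math.log10(20.0), 140)


def _sternheimer_params(i_ev: float, rho: float, z_over_a: float):
    """Generic Sternheimer density-effect parameters (the SGD scheme)."""
    hwp = 28.8159 * math.sqrt(rho * z_over_a)  # plasma energy, eV
    cbar = 2.0 * math.log(i_ev / hwp) + 1.0
    if i_ev < 100.0:
        x1 = 2.0
        x0 = 0.2 if cbar < 3.681 else 0.326 * cbar - 1.0
    else:
        x1 = 3.0
        x0 = 0.2 if cbar < 5.215 else 0.326 * cbar - 1.5
    m = 3.0
    a = (cbar - 4.606 * x0) / (x1 - x0) ** m
    return cbar, x0, x1, a, m


def density_effect(t_mev: float, i_ev: float, rho: float, z_over_a: float) -> float:
    cbar, x0, x1, a, m = _sternheimer_params(i_ev, rho, z_over_a)
    gamma = t_mev / ELECTRON_REST_MEV + 1.0
    x = math.log10(math.sqrt(gamma * gamma - 1.0))
    if x < x0:
        return 0.0
    if x < x1:
        return 4.606 * x - cbar + a * (x1 - x) ** m
    return 4.606 * x - cbar


def collision_stopping_power(t_mev: float, name: str) -> float:
    """Electron mass collision stopping power, MeV cm^2/g (Bethe, ICRU-37)."""
    comp = MATERIAL_COMPOSITIONS[name]
    z_over_a = zoa(comp)
    i_mev = I_EV[name] * 1e-6
    tau = t_mev / ELECTRON_REST_MEV
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / gamma**2
    f_minus = (1.0 - beta2) + (
        tau**2 / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)
    ) / gamma**2
    delta = density_effect(t_mev, I_EV[name], DELTA_DENSITY[name], z_over_a)
    ln_term = math.log(tau**2 * (tau + 2.0) / 2.0 / (i_mev / ELECTRON_REST_MEV) ** 2)
    return BETHE_K * z_over_a / beta2 * (ln_term + f_minus - delta)


# -- photon interaction coefficients, cm^2/g ---------------------------------

# photoelectric: tau/rho = KPE * sum_i w_i Z_i^4.5/A_i * (0.01/E)^3.25,
# calibrated so water at 0.01 MeV gives 4.94 cm^2/g (XCOM)
_PE_NORM = 4.94 / (
    0.111894 * 1**4.5 / 1.008 + 0.888106 * 8**4.5 / 15.999
)
_PE_EXP = 3.25

# pair (nuclear + triplet folded together): kappa/rho =
# KP * sum_i w_i Z_i(Z_i+1)/A_i * (1 - Eth/E)^3 * ln(E/Eth),
# calibrated on water at 10 MeV (0.0046 cm^2/g, XCOM nuclear+electron pair)
_PAIR_ETH = 2 * ELECTRON_REST_MEV
_PAIR_Z_WATER = 0.111894 * 1 * 2 / 1.008 + 0.888106 * 8 * 9 / 15.999
_PAIR_NORM = 0.0046 / (
    _PAIR_Z_WATER * (1 - _PAIR_ETH / 10.0) ** 3 * math.log(10.0 / _PAIR_ETH)
)


def mu_components(energy_mev: float, name: str) -> tuple[float, float, float]:
    """(compton, photoelectric, pair) mass attenuation coefficients, cm^2/g."""
    comp = MATERIAL_COMPOSITIONS[name]
    z_over_a = zoa(comp)
    compton = kn_total_cross_section(energy_mev) * z_over_a * AVOGADRO
    pe_sum = sum(
        w * ELEMENTS[e][0] ** 4.5 / ELEMENTS[e][1] for e, w in comp.items()
    )
    pe = _PE_NORM * pe_sum * (0.01 / energy_mev) ** _PE_EXP
    if energy_mev > _PAIR_ETH:
        pair_sum = sum(
            w * ELEMENTS[e][0] * (ELEMENTS[e][0] + 1) / ELEMENTS[e][1]
            for e, w in comp.items()
        )
        pair = (
            _PAIR_NORM
            * pair_sum
            * (1 - _PAIR_ETH / energy_mev) ** 3
            * math.log(energy_mev / _PAIR_ETH)
        )
    else:
        pair = 0.0
    return compton, pe, pair


def total_mu(energy_mev: float, name: str) -> float:
    return sum(mu_components(energy_mev, name))


def generate_tables(outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in MATERIAL_COMPOSITIONS:
        sp = np.array(
            [[e, collision_stopping_power(e, name)] for e in ENERGY_GRID_MEV]
        )
        att = np.array([[e, total_mu(e, name)] for e in ENERGY_GRID_MEV])
        for label, tab in (("stopping_power", sp), ("attenuation", att)):
            path = outdir / f"{name}_{label}.csv"
            np.savetxt(
                path, tab, delimiter=",", header="energy_MeV,value",
                comments="", fmt="%.8e",
            )


if __name__ == "__main__":
    generate_tables(Path(__file__).parent / "data")
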