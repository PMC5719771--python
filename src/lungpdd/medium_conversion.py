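"""Bragg-Gray conversion between dose to water and dose to a medium.

Under Bragg-Gray conditions the same secondary-electron fluence crosses the
detector and the medium, so absorbed doses scale with the mass collision
stopping powers: D_g / D_w = (S/rho)_g / (S/rho)_w, both evaluated at the
mean initial secondary-electron energy E0 of the photon spectrum.  A TLD
calibrated to dose-to-water therefore converts to dose-to-medium by
multiplying with the medium/water ratio (about 0.966 for PMMA and 0.988 for
lung tissue at 15 MV).
"""

from __future__ import annotations

from .physics_data import Material, lookup, get_material

__all__ = ["stopping_power_ratio", "dose_to_medium"]


def stopping_power_ratio(a: Material, b: Material, e0_mev: float) -> float:
    """(S/rho)_a / (S/rho)_b at electron energy ``e0_mev`` (unitless).

    Evaluated at the single energy E0, not spectrum-averaged (Spencer-Attix
    averaging is deliberately out of scope).
    """
    return lookup(a, e0_mev, "stopping_power") / lookup(b, e0_mev, "stopping_power")


def dose_to_medium(dose_water_cgy: float, medium: Material, e0_mev: float) -> float:
    """Convert dose-to-water into dose-to-``medium`` at electron energy E0.

    D_g = D_w * (S/rho)_g / (S/rho)_w.  For media with lower mass collision
    stopping power than water (PMMA, lung) the medium dose is *below* the
    water dose for the same electron fluence.
    """
    if dose_water_cgy < 0:
        raise ValueError("dose must be non-negative")
    water = get_material("water")
    if medium.name == "water":
        return float(dose_water_cgy)
    return dose_water_cgy * stopping_power_ratio(medium, water, e0_mev)
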