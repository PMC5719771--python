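"""Material constants, Klein-Nishina cross sections, and table lookups.

Materials carry embedded mass collision stopping-power and mass attenuation
tables (ICRU-37-style Bethe/Sternheimer and KN+photoelectric+pair models,
see :mod:`lungpdd._table_gen`) shipped as packaged CSV resources on a common
log energy grid, 0.001-20 MeV.

The mean initial secondary-electron energy of a photon spectrum,

    E0 = (1/2) * hnu * sigma_tr(hnu) / sigma(hnu),

with hnu the spectrum mean energy and sigma/sigma_tr the Klein-Nishina total
and energy-transfer cross sections per electron, is the single energy at
which Bragg-Gray stopping-power ratios are evaluated in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import integrate

from .constants import (
    AVOGADRO,
    ELECTRON_REST_MEV,
    ELEMENTS,
    RE2_CM2,
)

__all__ = [
    "Material",
    "PhotonSpectrum",
    "ComptonCrossSections",
    "kn_cross_sections",
    "mean_secondary_electron_energy",
    "lookup",
    "get_material",
    "MATERIAL_COMPOSITIONS",
    "MATERIAL_DENSITIES",
]


# -- compositions (mass fractions) -------------------------------------------
# water/PMMA: standard; lung: ICRP soft-tissue lung (the ICRU-44/ESTAR
# composition, which is what EGSnrc's LUNG521ICRU medium tabulates);
# LiF: the TLD-100 host crystal.
MATERIAL_COMPOSITIONS: dict[str, dict[str, float]] = {
    "water": {"H": 0.111894, "O": 0.888106},
    "pmma": {"H": 0.080538, "C": 0.599848, "O": 0.319614},
    "lung": {
        "H": 0.101278, "C": 0.102310, "N": 0.028650, "O": 0.757452,
        "Na": 0.001840, "Mg": 0.000730, "P": 0.000800, "S": 0.002250,
        "Cl": 0.002660, "K": 0.001940, "Ca": 0.000090,
    },
    "lif": {"Li": 0.267585, "F": 0.732415},
}

# bulk densities used for transport, g/cm^3.  Lung is the inflated
# (air-filled) reference value; cork in the physical phantom is modelled as
# lung tissue at this bulk density.
MATERIAL_DENSITIES: dict[str, float] = {
    "water": 1.0,
    "pmma": 1.19,
    "lung": 0.26,
    "lif": 2.635,
}


def zoa(composition: dict[str, float]) -> float:
    """Mean Z/A (electrons per gram / Avogadro) of a composition."""
    return sum(w * ELEMENTS[e][0] / ELEMENTS[e][1] for e, w in composition.items())


_WATER_ZOA = zoa(MATERIAL_COMPOSITIONS["water"])


@dataclass(frozen=True)
class Material:
    """A phantom/detector material with embedded physics tables.

    ``stopping_power_table`` and ``attenuation_table`` are (energy_MeV, value)
    column pairs; stopping powers are mass *collision* stopping powers in
    MeV cm^2/g, attenuation is the total mass attenuation coefficient in
    cm^2/g (coherent scattering excluded).
    """

    name: str
    density: float
    composition: dict[str, float]
    stopping_power_table: np.ndarray  # shape (n, 2)
    attenuation_table: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, not 1"
            )
        for label, tab in (
            ("stopping_power", self.stopping_power_table),
            ("attenuation", self.attenuation_table),
        ):
            e = tab[:, 0]
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"{label} table of {self.name!r}: energies not increasing")
            if np.any(tab <= 0):
                raise ValueError(f"{label} table of {self.name!r}: non-positive entries")

    @property
    def zoa(self) -> float:
        return zoa(self.composition)

    @property
    def electron_density_rel_water(self) -> float:
        """Electron density relative to unit-density water (the quantity the
        Batho-family exponents and ETAR scaling use)."""
        return self.density * self.zoa / _WATER_ZOA


@dataclass(frozen=True)
class PhotonSpectrum:
    """A discrete photon fluence spectrum (bin energies in MeV)."""

    energy_bins: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_bins, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.size == 0:
            raise ValueError("empty spectrum")
        if e.shape != w.shape:
            raise ValueError("energy_bins and weights must have the same shape")
        if np.any(w < 0):
            raise ValueError("negative spectrum weights")
        s = w.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {s}, not 1")
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("energies must be positive and strictly increasing")

    @property
    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy hnu, MeV."""
        return float(np.dot(self.energy_bins, self.weights))


@dataclass(frozen=True)
class ComptonCrossSections:
    """Klein-Nishina total and energy-transfer cross sections per electron."""

    energy: float  # MeV
    sigma_total: float  # cm^2/electron
    sigma_transfer: float  # cm^2/electron

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma_transfer < self.sigma_total):
            raise ValueError("require 0 < sigma_transfer < sigma_total")

    @property
    def mean_transfer_fraction(self) -> float:
        """Mean fraction of the photon energy given to the Compton electron."""
        return self.sigma_transfer / self.sigma_total


def kn_total_cross_section(energy_mev: float) -> float:
    """Closed-form Klein-Nishina total cross section per free electron, cm^2."""
    if energy_mev <= 0:
        raise ValueError("photon energy must be positive")
    a = energy_mev / ELECTRON_REST_MEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - math.log(1 + 2 * a) / a)
    t2 = math.log(1 + 2 * a) / (2 * a)
    t3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * math.pi * RE2_CM2 * (t1 + t2 + t3)


def kn_electron_spectrum(energy_mev: float, t_mev):
    """KN differential cross section in electron kinetic energy, cm^2/MeV.

    Valid for 0 <= T <= Tmax = E * 2a/(1+2a)."""
    a = energy_mev / ELECTRON_REST_MEV
    s = np.asarray(t_mev) / energy_mev
    return (np.pi * RE2_CM2 / (ELECTRON_REST_MEV * a**2)) * (
        2.0 + s**2 / (a**2 * (1.0 - s) ** 2) + s / (1.0 - s) * (s - 2.0 / a)
    )


def kn_cross_sections(energy_mev: float) -> ComptonCrossSections:
    """KN total (closed form) and energy-transfer (quadrature) cross sections.

    sigma_transfer = integral of (T/E) dsigma/dT over the electron spectrum,
    so sigma_transfer/sigma_total is the mean energy-transfer fraction.
    """
    sigma = kn_total_cross_section(energy_mev)
    a = energy_mev / ELECTRON_REST_MEV
    tmax = energy_mev * 2 * a / (1 + 2 * a)
    num, _ = integrate.quad(
        lambda t: t * kn_electron_spectrum(energy_mev, t), 0.0, tmax, limit=200
    )
    sigma_tr = num / energy_mev
    return ComptonCrossSections(energy=energy_mev, sigma_total=sigma, sigma_transfer=sigma_tr)


def mean_secondary_electron_energy(spectrum: PhotonSpectrum) -> float:
    """Mean initial Compton-electron energy E0 = hnu/2 * sigma_tr/sigma, MeV.

    The cross sections are evaluated at the single mean spectrum energy hnu,
    not spectrum-averaged.
    """
    hnu = spectrum.mean_energy
    xs = kn_cross_sections(hnu)
    return 0.5 * hnu * xs.mean_transfer_fraction


def lookup(material: Material, energy_mev: float, quantity: str) -> float:
    """Log-log interpolated table value; exact at grid points.

    ``quantity`` is ``"stopping_power"`` (MeV cm^2/g) or ``"attenuation"``
    (cm^2/g).  Energies outside the tabulated range raise, never extrapolate.
    """
    if quantity == "stopping_power":
        tab = material.stopping_power_table
    elif quantity == "attenuation":
        tab = material.attenuation_table
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    e, v = tab[:, 0], tab[:, 1]
    if not (e[0] <= energy_mev <= e[-1]):
        raise ValueError(
            f"{energy_mev} MeV outside {material.name} {quantity} table "
            f"range [{e[0]}, {e[-1]}]"
        )
    return float(
        np.exp(np.interp(np.log(energy_mev), np.log(e), np.log(v)))
    )


def _read_table(name: str) -> np.ndarray:
    ref = resources.files("lungpdd.data").joinpath(name)
    with ref.open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


_CACHE: dict[str, Material] = {}


def get_material(name: str, density: float | None = None) -> Material:
    """Load a built-in material ('water', 'pmma', 'lung', 'lif') by name.

    ``density`` overrides the bulk density (used e.g. for lung at a
    non-default inflation level); the per-gram tables are unaffected.
    """
    key = name.lower()
    if key not in MATERIAL_COMPOSITIONS:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(MATERIAL_COMPOSITIONS)}"
        )
    if key not in _CACHE:
        _CACHE[key] = Material(
            name=key,
            density=MATERIAL_DENSITIES[key],
            composition=MATERIAL_COMPOSITIONS[key],
            stopping_power_table=_read_table(f"{key}_stopping_power.csv"),
            attenuation_table=_read_table(f"{key}_attenuation.csv"),
        )
    mat = _CACHE[key]
    if density is not None and density != mat.density:
        mat = Material(
            name=key,
            density=density,
            composition=mat.composition,
            stopping_power_table=mat.stopping_power_table,
            attenuation_table=mat.attenuation_table,
        )
    return mat
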