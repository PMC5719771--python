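"""Analytic heterogeneity corrections: generalized Batho, modified Batho,
and a 1-D equivalent-TAR method.

These are the classic TPS-era correction-factor algorithms.  All work from
homogeneous-water beam data (TAR/TMR vs depth and field radius) and the
slab densities only; none models electron transport, which is exactly why
they fail under lateral electronic disequilibrium in low-density media.

Formulas (point P at depth d, layers numbered 1..N upward from the layer
containing P, z_m = distance from P to the top of layer m, rho = electron
density relative to water, with the region above the phantom treated as
water):

* generalized Batho (power law):  CF = prod_m TAR(z_m, r)^(rho_m - rho_{m+1})
* modified Batho: the same product with TMR(z_m + dmax, r) in place of
  TAR(z_m, r), restoring sensible behavior near interfaces and in buildup;
* equivalent TAR (1-D slab form): CF = TAR(d', r~)/TAR(d, r) with d' the
  radiological depth and r~ = r * rho~ the field radius scaled by the
  thickness-weighted mean relative electron density from surface to d.

The power-law exponents use relative *electron* density, the standard
convention for these algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .comparison import PDDCurve, normalize_pdd
from .mc_engine import BIN_CM, BeamConfig, PhantomStack
from .physics_data import get_material

__all__ = [
    "BeamDataTable",
    "CorrectionFactorProfile",
    "radiological_depth",
    "correction_factor",
    "corrected_pdd",
    "METHODS",
]

METHODS = ("batho", "mbatho", "etar")


@dataclass(frozen=True)
class BeamDataTable:
    """TMR and TAR vs depth and field radius on a rectangular grid."""

    field_radii_cm: np.ndarray
    depths_cm: np.ndarray
    tmr: np.ndarray  # shape (n_radii, n_depths)
    tar: np.ndarray
    dmax_cm: float

    def __post_init__(self) -> None:
        if self.tmr.shape != (self.field_radii_cm.size, self.depths_cm.size):
            raise ValueError("TMR table is not rectangular over (radii, depths)")
        if np.any(self.tmr <= 0) or np.any(self.tar <= 0):
            raise ValueError("beam-data tables must be positive")

    def _interp(self, table: np.ndarray, depth_cm: float, radius_cm: float) -> float:
        """Bilinear lookup.  Radii and depths clamp to the table edges (the
        dmax-shifted TMR argument and ETAR's density-scaled radius can fall
        slightly outside the simulated grid); negative depths are an error."""
        if depth_cm < 0:
            raise ValueError(f"negative depth {depth_cm} cm")
        r = np.clip(radius_cm, self.field_radii_cm[0], self.field_radii_cm[-1])
        d = np.clip(depth_cm, self.depths_cm[0], self.depths_cm[-1])
        per_radius = np.array([
            np.interp(d, self.depths_cm, table[i])
            for i in range(self.field_radii_cm.size)
        ])
        return float(np.interp(r, self.field_radii_cm, per_radius))

    def tmr_at(self, depth_cm: float, radius_cm: float) -> float:
        return self._interp(self.tmr, depth_cm, radius_cm)

    def tar_at(self, depth_cm: float, radius_cm: float) -> float:
        return self._interp(self.tar, depth_cm, radius_cm)


@dataclass(frozen=True)
class CorrectionFactorProfile:
    method: str
    depths_cm: np.ndarray
    cf: np.ndarray


def _rel_electron_density(name: str) -> float:
    return get_material(name).electron_density_rel_water


def radiological_depth(phantom: PhantomStack, d_cm: float) -> float:
    """Water-equivalent depth: integral of relative electron density from the
    surface to ``d_cm`` along the axis."""
    if not 0.0 <= d_cm <= phantom.total_depth:
        raise ValueError(f"depth {d_cm} outside the phantom")
    out = 0.0
    z = 0.0
    for name, t in phantom.slabs:
        seg = min(t, d_cm - z)
        if seg <= 0:
            break
        out += seg * _rel_electron_density(name)
        z += t
    return out


def _layers_above(phantom: PhantomStack, d_cm: float):
    """(rho, z_top_distance) for each layer from the one containing the point
    upward; z is the distance from the point to the top of that layer."""
    edges = [0.0]
    for _, t in phantom.slabs:
        edges.append(edges[-1] + t)
    out = []
    for i in range(len(phantom.slabs) - 1, -1, -1):
        top = edges[i]
        if top >= d_cm:
            continue
        rho = _rel_electron_density(phantom.slabs[i][0])
        out.append((rho, d_cm - top))
    return out  # ordered from the point's layer upward


def correction_factor(
    method: str,
    phantom: PhantomStack,
    d_cm: float,
    field: BeamConfig,
    data: BeamDataTable,
) -> float:
    """Heterogeneity correction factor at depth ``d_cm`` on the axis.

    Batho variants are undefined in the buildup region; below dmax the
    factor is held at its value at dmax.  TAR arguments for the generalized
    Batho product are clamped to >= dmax because PDD-derived TAR lacks the
    electronic-equilibrium plateau the power law assumes near zero depth.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    r = field.equivalent_radius_cm
    if method in ("batho", "mbatho"):
        d_eval = max(d_cm, data.dmax_cm)
        layers = _layers_above(phantom, d_eval)
        cf = 1.0
        for m, (rho_m, z_m) in enumerate(layers):
            rho_above = layers[m + 1][0] if m + 1 < len(layers) else 1.0
            if method == "batho":
                base = data.tar_at(max(z_m, data.dmax_cm), r)
            else:
                base = data.tmr_at(z_m + data.dmax_cm, r)
            cf *= base ** (rho_m - rho_above)
        return cf
    # equivalent TAR
    d_eval = min(max(d_cm, 1e-9), phantom.total_depth)
    d_rad = radiological_depth(phantom, d_eval)
    rho_mean = d_rad / d_eval
    return data.tar_at(d_rad, r * rho_mean) / data.tar_at(d_eval, r)


def correction_profile(
    method: str,
    phantom: PhantomStack,
    depths_cm: np.ndarray,
    field: BeamConfig,
    data: BeamDataTable,
) -> CorrectionFactorProfile:
    cf = np.array([
        correction_factor(method, phantom, float(d), field, data)
        for d in depths_cm
    ])
    return CorrectionFactorProfile(
        method=method, depths_cm=np.asarray(depths_cm, dtype=float), cf=cf
    )


def corrected_pdd(
    method: str,
    homogeneous_pdd: PDDCurve,
    phantom: PhantomStack,
    field: BeamConfig,
    data: BeamDataTable,
) -> PDDCurve:
    """TPS-style corrected curve: homogeneous PDD x CF, renormalized to 100
    at its (smoothed) maximum."""
    prof = correction_profile(
        method, phantom, homogeneous_pdd.depths_cm, field, data
    )
    scaled = PDDCurve(
        depths_cm=homogeneous_pdd.depths_cm,
        values=homogeneous_pdd.values * prof.cf,
        rel_se=homogeneous_pdd.rel_se,
        dmax_cm=homogeneous_pdd.dmax_cm,
    )
    return normalize_pdd(scaled)
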