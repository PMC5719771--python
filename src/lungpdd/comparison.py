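"""PDD normalization, ratio curves, and interface dose metrics.

PDD curves are normalized to 100 at the depth of maximum dose; on noisy
Monte Carlo profiles the maximum bin is located on an inverse-variance
weighted 3-bin moving average so a single high outlier bin cannot steal the
normalization, while the value at that bin is taken from the raw profile.

The interface metrics quantify how strongly an algorithm's curve disagrees
with the reference inside the low-density region: the lung overdose just
below the soft-tissue/lung interface, the soft-tissue underdose just below
the lung/soft-tissue interface, and the worst relative discrepancy anywhere
in the lung.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mc_engine import BIN_CM, DoseProfile, PhantomStack

__all__ = [
    "PDDCurve",
    "RatioCurve",
    "ComparisonResult",
    "normalize_pdd",
    "ratio_curve",
    "interface_metrics",
]


@dataclass(frozen=True)
class PDDCurve:
    """Central-axis percentage depth dose (100 at dmax)."""

    depths_cm: np.ndarray
    values: np.ndarray  # percent
    rel_se: np.ndarray
    dmax_cm: float

    def value_at(self, depth_cm: float) -> float:
        i = int(depth_cm / BIN_CM)
        return float(self.values[i])


@dataclass(frozen=True)
class RatioCurve:
    """Per-depth PDD ratio a/b with propagated relative uncertainty."""

    depths_cm: np.ndarray
    ratio: np.ndarray
    rel_se: np.ndarray
    valid: np.ndarray  # False where the denominator bin was excluded


@dataclass(frozen=True)
class ComparisonResult:
    lung_overdose_pct: float
    soft_underdose_pct: float
    max_lung_discrepancy_pct: float
    region: np.ndarray  # per-bin material name
    ratio: RatioCurve


def smoothed_argmax(values: np.ndarray, rel_se: np.ndarray | None = None) -> int:
    """Index of the maximum of the inverse-variance weighted 3-bin moving
    average of ``values``."""
    v = np.asarray(values, dtype=float)
    if rel_se is not None and np.any(np.asarray(rel_se) > 0):
        se = np.asarray(rel_se) * np.abs(v)
        w = np.where(se > 0, 1.0 / se**2, 0.0)
        wmax = w[w > 0].max() if np.any(w > 0) else 1.0
        w = np.where(w > 0, w, wmax)
    else:
        w = np.ones_like(v)
    num = np.convolve(v * w, np.ones(3), mode="same")
    den = np.convolve(w, np.ones(3), mode="same")
    return int(np.argmax(num / den))


def normalize_pdd(profile: DoseProfile | PDDCurve) -> PDDCurve:
    """Normalize a dose profile to 100 at the depth of maximum dose.

    Idempotent: normalizing an already-normalized curve returns it unchanged.
    """
    if isinstance(profile, PDDCurve):
        depths, dose, rel = profile.depths_cm, profile.values, profile.rel_se
    else:
        depths, dose, rel = profile.depth_centers_cm, profile.dose, profile.rel_se
    dose = np.asarray(dose, dtype=float)
    if not np.any(dose > 0):
        raise ValueError("profile has no positive bins")
    k = smoothed_argmax(dose, rel)
    return PDDCurve(
        depths_cm=np.asarray(depths, dtype=float),
        values=100.0 * dose / dose[k],
        rel_se=np.asarray(rel, dtype=float),
        dmax_cm=float(depths[k]),
    )


def ratio_curve(a: PDDCurve, b: PDDCurve) -> RatioCurve:
    """Elementwise a/b with relative uncertainties added in quadrature.

    Bins where the denominator is not positive are flagged invalid and
    excluded from downstream metrics."""
    if a.depths_cm.shape != b.depths_cm.shape or np.any(a.depths_cm != b.depths_cm):
        raise ValueError("PDD curves are on different depth grids")
    valid = b.values > 0
    ratio = np.where(valid, a.values / np.where(valid, b.values, 1.0), np.nan)
    rel = np.hypot(a.rel_se, b.rel_se)
    return RatioCurve(depths_cm=a.depths_cm, ratio=ratio, rel_se=rel, valid=valid)


def region_map(phantom: PhantomStack, depths_cm: np.ndarray) -> np.ndarray:
    """Per-bin material name (bins beyond the stack take the last slab)."""
    return np.array([
        phantom.material_at(min(d, phantom.total_depth - 1e-9)) for d in depths_cm
    ])


def interface_metrics(
    r: RatioCurve, phantom: PhantomStack, window_cm: float = 1.0
) -> ComparisonResult:
    """Interface over/under-dose percentages and worst lung discrepancy.

    * lung_overdose_pct: 100*(max ratio - 1) over lung bins within
      ``window_cm`` below the soft-tissue->lung interface;
    * soft_underdose_pct: 100*(1 - min ratio) over soft-tissue bins within
      ``window_cm`` below the lung->soft-tissue interface;
    * max_lung_discrepancy_pct: 100*max|ratio - 1| over all lung bins.
    """
    if window_cm <= 0:
        raise ValueError("window must be positive")
    region = region_map(phantom, r.depths_cm)
    lung = region == "lung"
    if not np.any(lung):
        raise ValueError("phantom has no lung layer")
    ok = r.valid & np.isfinite(r.ratio)
    d = r.depths_cm

    lung_depths = d[lung]
    soft_to_lung = lung_depths.min() - BIN_CM / 2
    lung_to_soft = lung_depths.max() + BIN_CM / 2

    in_window = lung & ok & (d >= soft_to_lung) & (d <= soft_to_lung + window_cm)
    over = 100.0 * (np.max(r.ratio[in_window]) - 1.0) if np.any(in_window) else float("nan")

    soft_after = (~lung) & ok & (d >= lung_to_soft) & (d <= lung_to_soft + window_cm)
    under = 100.0 * (1.0 - np.min(r.ratio[soft_after])) if np.any(soft_after) else float("nan")

    lung_ok = lung & ok
    max_disc = 100.0 * float(np.max(np.abs(r.ratio[lung_ok] - 1.0)))

    return ComparisonResult(
        lung_overdose_pct=float(over),
        soft_underdose_pct=float(under),
        max_lung_discrepancy_pct=max_disc,
        region=region,
        ratio=r,
    )
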