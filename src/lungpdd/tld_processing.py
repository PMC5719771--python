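"""TLD reading-to-dose chain: batch characterization, session control
factors, reading correction, calibration fit, and dose recovery.

The processing mirrors a standard LiF:Mg,Ti workflow with 60 chips, 8 of
which are stability controls exposed to a fixed dose every read-out session:

* batch characterization gives the mean zero-dose reading TL0, per-chip
  sensitivity factors S_i (normalized to batch mean 1) and a lower
  detection limit;
* each session's control readings give a reader-drift factor
  FC_m = [session mean of (TL_im - TL0)/S_i] / TLref;
* individual readings correct as TLcorr = ((TL - TL0)/S_i) / FC_m;
* a straight line D_w = A * mean(TLcorr) + B fitted over the calibration
  exposures converts corrected readings to dose-to-water;
* per-depth doses come from the mean of the two replicate chips, with an
  uncertainty combining replicate spread, control-factor spread, and the
  calibration-fit covariance in quadrature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TLDReading",
    "BatchCharacterization",
    "SessionControl",
    "CalibrationCurve",
    "DoseEstimate",
    "characterize_batch",
    "session_factor",
    "correct_reading",
    "fit_calibration",
    "reading_to_dose",
    "process_study",
]

log = logging.getLogger(__name__)

READING_COLUMNS = [
    "dosimeter_id", "session_id", "role", "raw", "dose_level_cGy", "depth_cm",
]
ROLES = ("zero", "reference", "control", "calibration", "measurement")


@dataclass(frozen=True)
class TLDReading:
    dosimeter_id: str
    session_id: str
    role: str
    raw: float
    dose_level_cgy: float | None = None
    depth_cm: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.raw < 0:
            raise ValueError("raw reading must be >= 0")
        if self.role == "calibration" and not (self.dose_level_cgy or 0) > 0:
            raise ValueError("calibration readings need dose_level_cgy > 0")


@dataclass(frozen=True)
class BatchCharacterization:
    """TL0 (batch mean zero-dose reading), per-chip sensitivities (mean 1),
    zero-reading spread, and the reader-unit lower detection limit."""

    tl0: float
    sensitivity: dict[str, float]
    zero_sd: float
    ldl_reader_units: float

    def __post_init__(self) -> None:
        s = np.array(list(self.sensitivity.values()))
        if np.any(s <= 0):
            raise ValueError("sensitivity factors must be positive")
        if abs(s.mean() - 1.0) > 1e-6:
            raise ValueError("sensitivity factors must average to 1")

    def ldl_cgy(self, cal: "CalibrationCurve") -> float:
        """Dose-equivalent detection limit through the calibration curve."""
        return cal.a * self.ldl_reader_units


@dataclass
class SessionControl:
    """Reference control reading and per-session correction factors."""

    tlref: float
    fcm: dict[str, float] = field(default_factory=dict)
    fcm_rel_se: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CalibrationCurve:
    """D_w [cGy] = A * TLcorr + B with OLS uncertainty information."""

    a: float  # cGy per reader unit
    b: float  # cGy
    residual_sd: float
    cov: np.ndarray  # 2x2 covariance of (A, B)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("calibration slope must be positive")

    def dose(self, mean_corrected_reading: float) -> float:
        return self.a * mean_corrected_reading + self.b


@dataclass(frozen=True)
class DoseEstimate:
    dose_cgy: float
    u_cgy: float
    below_ldl: bool

    @property
    def rel_u(self) -> float:
        return self.u_cgy / self.dose_cgy if self.dose_cgy > 0 else math.inf


def characterize_batch(
    zero_readings: dict[str, list[float]],
    reference_readings: dict[str, list[float]],
) -> BatchCharacterization:
    """TL0, S_i and the lower detection limit from a characterization run.

    ``reference_readings`` are readings after a common reference exposure
    (the cobalt-unit characterization irradiation); sensitivities are the
    per-chip net signals over the batch mean net signal, so mean(S_i) = 1.
    The LDL is TL0 + 3 sd of the zero readings, in reader units (its dose
    equivalent goes through the calibration curve).
    """
    ids = sorted(reference_readings)
    if len(ids) < 2:
        raise ValueError("need at least two dosimeters")
    for i in ids:
        if i not in zero_readings or not zero_readings[i] or not reference_readings[i]:
            raise ValueError(f"dosimeter {i!r} lacks zero or reference readings")
    zeros = np.concatenate([np.asarray(zero_readings[i], float) for i in ids])
    tl0 = float(zeros.mean())
    net = np.array([np.mean(reference_readings[i]) - tl0 for i in ids])
    if np.any(net <= 0):
        bad = ids[int(np.argmin(net))]
        raise ValueError(f"dosimeter {bad!r} shows no net reference signal")
    s = net / net.mean()
    return BatchCharacterization(
        tl0=tl0,
        sensitivity=dict(zip(ids, s)),
        zero_sd=float(zeros.std(ddof=1)) if zeros.size > 1 else 0.0,
        ldl_reader_units=3.0 * (float(zeros.std(ddof=1)) if zeros.size > 1 else 0.0),
    )


def session_factor(
    control_readings: dict[str, float],
    char: BatchCharacterization,
    session_id: str,
    ref: SessionControl | None = None,
    n_controls: int = 8,
) -> SessionControl:
    """Establish TLref (first call) or add this session's FC_m factor.

    ``control_readings`` maps the control-chip ids to their raw readings in
    this session; the set must match the one that established TLref."""
    if len(control_readings) != n_controls:
        raise ValueError(
            f"expected {n_controls} control readings, got {len(control_readings)}"
        )
    missing = [i for i in control_readings if i not in char.sensitivity]
    if missing:
        raise ValueError(f"control dosimeters not in batch: {missing}")
    net = np.array([
        (raw - char.tl0) / char.sensitivity[i]
        for i, raw in sorted(control_readings.items())
    ])
    mean = float(net.mean())
    se = float(net.std(ddof=1) / math.sqrt(net.size))
    if ref is None:
        out = SessionControl(tlref=mean)
        out.fcm[session_id] = 1.0
        out.fcm_rel_se[session_id] = se / mean
        return out
    if set(control_readings) - set(char.sensitivity):
        raise ValueError("control set differs from the reference session")
    fcm = mean / ref.tlref
    if not 0.5 <= fcm <= 2.0:
        log.warning(
            "session %s control factor %.3f outside [0.5, 2]: reader fault?",
            session_id, fcm,
        )
    ref.fcm[session_id] = fcm
    ref.fcm_rel_se[session_id] = se / mean
    return ref


def correct_reading(
    raw: float,
    char: BatchCharacterization,
    session: SessionControl,
    session_id: str,
    dosimeter_id: str,
) -> float:
    """TLcorr = ((raw - TL0)/S_i) / FC_m.  Negative net readings propagate
    (they are flagged below-LDL downstream, never clamped)."""
    if dosimeter_id not in char.sensitivity:
        raise ValueError(f"dosimeter {dosimeter_id!r} not in batch")
    if session_id not in session.fcm:
        raise ValueError(f"session {session_id!r} has no control factor")
    return (
        (raw - char.tl0)
        / char.sensitivity[dosimeter_id]
        / session.fcm[session_id]
    )


def fit_calibration(groups: dict[float, list[float]]) -> CalibrationCurve:
    """Ordinary least squares of dose (cGy) on the per-group mean corrected
    reading.  ``groups`` maps dose level (cGy) to corrected readings."""
    if len(groups) < 2:
        raise ValueError("need at least two distinct dose levels")
    doses = np.array(sorted(groups))
    means = np.array([np.mean(groups[d]) for d in doses])
    x = np.column_stack([means, np.ones_like(means)])
    coef, res, *_ = np.linalg.lstsq(x, doses, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    n = doses.size
    dof = n - 2
    resid = doses - x @ coef
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    if dof > 0 and s2 == 0.0 and np.any([np.std(groups[d]) > 0 for d in doses]):
        log.warning("calibration residuals are zero despite reading spread")
    cov = s2 * np.linalg.inv(x.T @ x)
    return CalibrationCurve(a=a, b=b, residual_sd=math.sqrt(s2), cov=cov)


def reading_to_dose(
    pair: list[float],
    cal: CalibrationCurve,
    char: BatchCharacterization | None = None,
    fcm_rel_se: float = 0.0,
) -> DoseEstimate:
    """Dose-to-water from the per-depth replicate set of corrected readings.

    D_w = A * mean(TLcorr) + B.  The uncertainty combines, in quadrature:
    type-A replicate spread of the pair, the session control-factor relative
    uncertainty, and the calibration-fit covariance.
    """
    tl = np.asarray(pair, dtype=float)
    if tl.size < 1:
        raise ValueError("need at least one corrected reading")
    mean = float(tl.mean())
    dose = cal.dose(mean)
    u_rep = (
        cal.a * float(tl.std(ddof=1)) / math.sqrt(tl.size) if tl.size > 1 else 0.0
    )
    u_fcm = cal.a * abs(mean) * fcm_rel_se
    j = np.array([mean, 1.0])
    u_fit = math.sqrt(float(j @ cal.cov @ j))
    u = math.sqrt(u_rep**2 + u_fcm**2 + u_fit**2)
    below = False
    if char is not None:
        below = mean < char.ldl_reader_units
        if below:
            log.warning("mean corrected reading below the detection limit")
    return DoseEstimate(dose_cgy=dose, u_cgy=u, below_ldl=below)


def process_study(readings: pd.DataFrame) -> dict:
    """End-to-end processing of a raw-readings table.

    The table follows the readings CSV schema (columns ``dosimeter_id,
    session_id, role, raw, dose_level_cGy, depth_cm``).  Sessions are
    processed in order of first appearance; the first session containing
    control readings establishes TLref.  Returns the characterization, the
    session control, the calibration curve, and per-depth dose estimates.
    """
    missing = [c for c in READING_COLUMNS if c not in readings.columns]
    if missing:
        raise ValueError(f"readings table lacks columns: {missing}")

    zero = readings[readings.role == "zero"]
    zero_map = zero.groupby("dosimeter_id")["raw"].apply(list).to_dict()
    refexp = readings[readings.role == "reference"]
    if not len(refexp):
        raise ValueError("no 'reference' characterization-exposure readings")
    ref_map = refexp.groupby("dosimeter_id")["raw"].apply(list).to_dict()
    char = characterize_batch({i: zero_map.get(i, []) for i in ref_map}, ref_map)

    controls = readings[readings.role == "control"]
    session = None
    for sid in controls.session_id.drop_duplicates():
        sel = controls[controls.session_id == sid]
        cr = dict(zip(sel.dosimeter_id, sel.raw))
        session = session_factor(cr, char, sid, ref=session, n_controls=len(cr))

    cal_rows = readings[readings.role == "calibration"]
    groups: dict[float, list[float]] = {}
    for _, row in cal_rows.iterrows():
        tl = correct_reading(row.raw, char, session, row.session_id, row.dosimeter_id)
        groups.setdefault(float(row.dose_level_cGy), []).append(tl)
    cal = fit_calibration(groups)

    meas = readings[readings.role == "measurement"]
    doses: dict[float, DoseEstimate] = {}
    for depth, sel in meas.groupby("depth_cm"):
        tls = [
            correct_reading(r.raw, char, session, r.session_id, r.dosimeter_id)
            for r in sel.itertuples()
        ]
        fc_se = float(np.mean([
            session.fcm_rel_se[s] for s in sel.session_id.unique()
        ]))
        doses[float(depth)] = reading_to_dose(tls, cal, char=char, fcm_rel_se=fc_se)

    return {
        "characterization": char,
        "session_control": session,
        "calibration": cal,
        "doses": doses,
    }
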