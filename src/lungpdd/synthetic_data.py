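"""Synthetic inputs for the full pipeline: TLD measurement campaigns with
known ground truth, the reference soft-tissue/lung phantom, and a
parametric 15 MV bremsstrahlung spectrum.

The TLD generator emulates a 60-chip campaign: per-chip sensitivities
(lognormal around 1), per-chip zero-dose signals, per-session reader drift,
multiplicative read noise, 8 stability-control chips exposed to 1 Gy every
session, calibration groups of 8 chips at 0.25/0.5/1 Gy, and two
measurement chips per phantom depth.  Hidden truth (true doses and latent
batch parameters) is returned separately from the readings table and never
flows into the pipeline inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mc_engine import PhantomStack
from .physics_data import PhotonSpectrum
from .tld_processing import READING_COLUMNS

__all__ = [
    "SyntheticStudyParams",
    "generate_tld_study",
    "make_reference_phantom",
    "synthesize_spectrum",
]


@dataclass(frozen=True)
class SyntheticStudyParams:
    """Noise model and campaign layout for the synthetic TLD study.

    The defaults mirror the study conditions: 60 chips of which 8 are
    stability controls, calibration exposures at 25/50/100 cGy with 8 chips
    per level, controls always exposed to 100 cGy, and a total measurement
    uncertainty comfortably below 5%.
    """

    n_dosimeters: int = 60
    n_controls: int = 8
    sensitivity_sd: float = 0.05  # lognormal sigma around 1
    zero_dose_mean: float = 500.0  # reader units
    zero_dose_sd: float = 50.0
    session_drift_sd: float = 0.02  # lognormal sigma around 1
    read_noise_cv: float = 0.01  # multiplicative gaussian
    calibration_doses_cgy: tuple[float, ...] = (25.0, 50.0, 100.0)
    control_dose_cgy: float = 100.0
    # characterization irradiation/readout cycles used to average down the
    # per-chip sensitivity error (standard TLD practice uses several)
    n_characterization_cycles: int = 5
    true_calibration: tuple[float, float] = (0.0009, 1.4243)  # (A cGy/unit, B cGy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dosimeters < 10:
            raise ValueError("need at least 10 dosimeters")
        for name in ("sensitivity_sd", "zero_dose_sd", "session_drift_sd",
                     "read_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _signal(dose_cgy: float, a: float, b: float) -> float:
    """Latent net reader signal that the calibration curve maps back to
    ``dose_cgy``: (D - B)/A."""
    return (dose_cgy - b) / a


def generate_tld_study(
    true_depth_doses: dict[float, float],
    params: SyntheticStudyParams,
) -> tuple[pd.DataFrame, dict]:
    """Readings table (the readings CSV schema) plus the hidden-truth record.

    Raw reading = TL0_i + S_i * drift_m * (D - B)/A * (1 + noise): the dark
    signal is chip-specific and unaffected by reader-gain drift, which acts
    on the radiation-induced (net) signal.
    """
    if any(d < 0 for d in true_depth_doses.values()):
        raise ValueError("true doses must be non-negative")
    a, b = params.true_calibration
    rng = np.random.default_rng(params.seed)
    n = params.n_dosimeters
    ids = [f"tld{idx:02d}" for idx in range(n)]
    sens = np.exp(rng.normal(0.0, params.sensitivity_sd, n))
    sens /= sens.mean()
    tl0 = rng.normal(params.zero_dose_mean, params.zero_dose_sd, n)
    tl0 = np.clip(tl0, 0.0, None)
    s_of = dict(zip(ids, sens))
    tl0_of = dict(zip(ids, tl0))

    controls = ids[:params.n_controls]
    others = ids[params.n_controls:]

    rows: list[dict] = []
    drifts: dict[str, float] = {}

    def read(i: str, dose_cgy: float, session: str, role: str,
             dose_level=np.nan, depth=np.nan) -> None:
        drift = drifts[session]
        noise = 1.0 + rng.normal(0.0, params.read_noise_cv)
        raw = tl0_of[i] + s_of[i] * drift * _signal(dose_cgy, a, b) * noise
        rows.append({
            "dosimeter_id": i, "session_id": session, "role": role,
            "raw": max(raw, 0.0), "dose_level_cGy": dose_level,
            "depth_cm": depth,
        })

    def new_session(name: str, is_reference: bool = False) -> None:
        drifts[name] = 1.0 if is_reference else float(
            np.exp(rng.normal(0.0, params.session_drift_sd))
        )

    # characterization sessions: zero readings for every chip, then a common
    # reference exposure (the cobalt characterization irradiation), repeated
    # over several anneal/irradiate/read cycles
    for cycle in range(params.n_characterization_cycles):
        session = f"char{cycle}"
        new_session(session, is_reference=True)
        for i in ids:
            noise = 1.0 + rng.normal(0.0, params.read_noise_cv)
            rows.append({
                "dosimeter_id": i, "session_id": session, "role": "zero",
                "raw": max(tl0_of[i] * noise, 0.0), "dose_level_cGy": np.nan,
                "depth_cm": np.nan,
            })
        for i in ids:
            read(i, 100.0, session, "reference")

    # reference control session establishes TLref
    new_session("ref", is_reference=True)
    for i in controls:
        read(i, params.control_dose_cgy, "ref", "control")

    # calibration session: controls + 8 chips per dose level
    new_session("cal")
    for i in controls:
        read(i, params.control_dose_cgy, "cal", "control")
    per_level = 8
    for k, dose in enumerate(params.calibration_doses_cgy):
        group = others[k * per_level:(k + 1) * per_level]
        if len(group) < per_level:
            raise ValueError("not enough dosimeters for the calibration groups")
        for i in group:
            read(i, dose, "cal", "calibration", dose_level=dose)

    # measurement sessions: two chips per depth, controls re-read each session
    depths = sorted(true_depth_doses)
    pool = others
    per_session = max(1, (len(pool) // 2))
    sid = 0
    for start in range(0, len(depths), per_session):
        chunk = depths[start:start + per_session]
        session = f"meas{sid}"
        sid += 1
        new_session(session)
        for i in controls:
            read(i, params.control_dose_cgy, session, "control")
        for j, depth in enumerate(chunk):
            for i in (pool[2 * j % len(pool)], pool[(2 * j + 1) % len(pool)]):
                read(i, true_depth_doses[depth], session, "measurement",
                     depth=depth)

    table = pd.DataFrame(rows, columns=READING_COLUMNS)
    truth = {
        "true_depth_doses": dict(true_depth_doses),
        "sensitivity": s_of,
        "zero_dose": tl0_of,
        "session_drift": drifts,
        "true_calibration": {"A": a, "B": b},
    }
    return table, truth


def make_reference_phantom() -> PhantomStack:
    """The study phantom: 5 cm acrylic / 13 cm lung-equivalent (cork) /
    10 cm acrylic, 28 cm total, interfaces at 5 and 18 cm."""
    return PhantomStack((("pmma", 5.0), ("lung", 13.0), ("pmma", 10.0)))


# endpoint MeV -> (spectral shape parameters) for the parametric
# bremsstrahlung stand-in w(E) ~ E^p * exp(-E/Ec) * (1 - E/Emax)^q
_SPECTRUM_SHAPE = {
    6.0: (1.0, 0.9, 0.2),
    10.0: (1.0, 1.4, 0.2),
    15.0: (1.0, 2.0, 0.2),
    18.0: (1.0, 2.4, 0.2),
}


def synthesize_spectrum(nominal_mv: float = 15.0, n_bins: int = 60) -> PhotonSpectrum:
    """Parametric bremsstrahlung-shaped stand-in spectrum.

    Shape w(E) ~ E^p exp(-E/Ec) (1-E/Emax)^q on [0.25, Emax] MeV with the
    15 MV parameters chosen so the simulated homogeneous-water depth of
    maximum dose lands near 3.0 cm.
    """
    if nominal_mv not in _SPECTRUM_SHAPE:
        raise ValueError(
            f"unsupported nominal energy {nominal_mv}; "
            f"supported: {sorted(_SPECTRUM_SHAPE)}"
        )
    p, ec, q = _SPECTRUM_SHAPE[nominal_mv]
    emax = nominal_mv
    e = np.linspace(0.25, emax, n_bins)
    w = e**p * np.exp(-e / ec) * np.clip(1.0 - e / emax, 0.0, None) ** q
    w[-1] = w[-2] * 0.5  # keep the endpoint bin populated but small
    w /= w.sum()
    return PhotonSpectrum(energy_bins=e, weights=w)
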