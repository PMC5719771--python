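"""Desk-scale Monte Carlo dose engine in cylindrical slab geometry.

A point source at z = -SSD illuminates a circular field of radius
R = L/sqrt(pi) (the equal-area equivalent of an L x L square field) on a
stack of material slabs.  Photons are tracked analytically (Woodcock
tracking; Klein-Nishina Compton, photoelectric, pair production); secondary
electrons deposit energy along stepped CSDA tracks with Highland
multiple-scattering deflections (``kernel`` mode) or locally (``off``).
Dose is tallied in 60 x 0.5 cm depth bins inside a central scoring
cylinder, by default of TLD-chip cross-sectional area; per-bin statistical
errors come from contiguous history batches.

The detector-perturbation workflow runs paired simulations with and without
a LiF chip inserted on the axis and returns, per depth, Fcor = (dose to the
chip) / (dose the undisturbed medium absorbs in the same chip-sized region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _transport
from ._table_gen import ENERGY_GRID_MEV, mu_components
from .constants import CHIP_RADIUS_CM, CHIP_THICKNESS_CM
from .physics_data import Material, PhotonSpectrum, get_material, lookup

__all__ = [
    "PhantomStack",
    "BeamConfig",
    "TransportOptions",
    "DoseProfile",
    "equivalent_radius",
    "simulate_depth_dose",
    "perturbation_profile",
    "apply_perturbation",
    "homogeneous_beam_data",
    "run_until_precision",
]

N_BINS = 60
BIN_CM = 0.5

# radiation lengths, g/cm^2 (PDG); lung tissue is water-like
_X0_GCM2 = {"water": 36.08, "pmma": 40.55, "lung": 36.2, "lif": 39.25}


@dataclass(frozen=True)
class PhantomStack:
    """Ordered slabs of (material name, thickness in cm) along the beam."""

    slabs: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.slabs:
            raise ValueError("phantom needs at least one slab")
        for name, t in self.slabs:
            if t <= 0:
                raise ValueError(f"non-positive slab thickness for {name!r}")

    @property
    def total_depth(self) -> float:
        return float(sum(t for _, t in self.slabs))

    @property
    def interfaces(self) -> list[float]:
        """Depths of internal material boundaries, cm."""
        edges = np.cumsum([t for _, t in self.slabs])[:-1]
        return [float(e) for e in edges]

    def material_at(self, depth_cm: float) -> str:
        if depth_cm < 0:
            raise ValueError("depth must be non-negative")
        z = 0.0
        for name, t in self.slabs:
            z += t
            if depth_cm < z:
                return name
        return self.slabs[-1][0]


def equivalent_radius(square_side_cm: float) -> float:
    """Radius of the circular field with the same area as the square field:
    pi R^2 = L^2, so R = L / sqrt(pi)."""
    if square_side_cm <= 0:
        raise ValueError("field side must be positive")
    return square_side_cm / math.sqrt(math.pi)


@dataclass(frozen=True)
class BeamConfig:
    """Beam geometry: point source, SSD, and equal-area circular field."""

    spectrum: PhotonSpectrum
    square_side_cm: float
    ssd_cm: float = 100.0
    nominal_mv: float = 15.0

    def __post_init__(self) -> None:
        if self.ssd_cm <= 0 or self.square_side_cm <= 0:
            raise ValueError("ssd and field side must be positive")

    @property
    def equivalent_radius_cm(self) -> float:
        return equivalent_radius(self.square_side_cm)


@dataclass(frozen=True)
class TransportOptions:
    """Transport controls.  Cutoffs are kinetic energies: photons below
    ``photon_cutoff_kev`` and electrons below ``electron_cutoff_kev`` deposit
    locally.  ``scoring_radius_cm=None`` selects the TLD-chip radius."""

    n_histories: int = 200_000
    seed: int = 1234
    photon_cutoff_kev: float = 1.0
    electron_cutoff_kev: float = 70.0
    electron_transport: str = "kernel"  # kernel | off
    max_step_gcm2: float = 0.05
    primary_only: bool = False
    scoring_radius_cm: float | None = None
    n_batches: int = 20

    def __post_init__(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.photon_cutoff_kev <= 0 or self.electron_cutoff_kev <= 0:
            raise ValueError("cutoffs must be positive")
        if self.electron_transport not in ("kernel", "off"):
            raise ValueError("electron_transport must be 'kernel' or 'off'")
        if self.n_batches < 2:
            raise ValueError("need >= 2 batches for uncertainty estimates")


@dataclass(frozen=True)
class DoseProfile:
    """Central-axis dose per depth bin with batch statistical uncertainty."""

    depth_centers_cm: np.ndarray  # 60 bin centers
    dose: np.ndarray  # mean dose per history, MeV/g
    rel_se: np.ndarray  # relative standard error per bin
    scoring_radius_cm: float
    n_histories: int
    energy_emitted_mev: float
    energy_deposited_mev: float
    # dose in the chip-sized tally region (MeV/g per history), when requested
    chip_dose: float | None = None
    chip_rel_se: float | None = None
    chip_dose_batches: np.ndarray | None = None

    def dose_at(self, depth_cm: float) -> float:
        i = int(depth_cm / BIN_CM)
        if not 0 <= i < self.depth_centers_cm.size:
            raise ValueError(f"depth {depth_cm} outside the tally")
        return float(self.dose[i])


def _build_run_arrays(materials: list[Material]):
    """Per-material lookup tables on the shared log-energy grid."""
    grid = ENERGY_GRID_MEV
    nmat = len(materials)
    ne = grid.size
    mu_tot = np.zeros((nmat, ne))
    p_pe = np.zeros((nmat, ne))
    p_pair = np.zeros((nmat, ne))
    sp = np.zeros((nmat, ne))
    rho = np.zeros(nmat)
    x0 = np.zeros(nmat)
    for i, m in enumerate(materials):
        rho[i] = m.density
        x0[i] = _X0_GCM2[m.name]
        sp_tab = m.stopping_power_table
        for j, e in enumerate(grid):
            e = float(np.clip(e, sp_tab[0, 0], sp_tab[-1, 0]))
            c, pe, pair = mu_components(e, m.name)
            tot = c + pe + pair
            mu_tot[i, j] = tot * m.density  # 1/cm
            p_pe[i, j] = pe / tot
            p_pair[i, j] = pair / tot
            sp[i, j] = lookup(m, e, "stopping_power")
    mu_max = mu_tot.max(axis=0)
    loge0 = math.log(grid[0])
    dloge = (math.log(grid[-1]) - math.log(grid[0])) / (ne - 1)
    return mu_tot, p_pe, p_pair, mu_max, sp, rho, x0, loge0, dloge, ne


def default_scoring_radius(field_radius_cm: float) -> float:
    """Chip-area scoring for small fields; for larger fields a wider cylinder
    inside the laterally flat dose region (ion-chamber-class statistics)."""
    return max(CHIP_RADIUS_CM, min(0.5 * field_radius_cm, 3.0))


def simulate_depth_dose(
    phantom: PhantomStack,
    beam: BeamConfig,
    options: TransportOptions,
    detector_at: float | None = None,
    detector_material: str = "lif",
    tally_at: float | None = None,
) -> DoseProfile:
    """Simulate the central-axis depth-dose profile.

    With ``detector_at`` set, a detector chip layer (thickness 0.09 cm,
    chip-area cross section, ``detector_material``) is inserted on the axis
    with its front face at that depth, and the dose absorbed in the chip is
    reported as ``chip_dose``.  With ``tally_at`` set instead, the dose in
    the same chip-sized region of the undisturbed phantom is reported (the
    denominator of the detector perturbation factor).
    """
    if detector_at is not None and tally_at is not None:
        raise ValueError("pass either detector_at or tally_at, not both")
    mats: list[Material] = []
    names: list[str] = []

    def midx(name: str) -> int:
        if name not in names:
            names.append(name)
            mats.append(get_material(name))
        return names.index(name)

    edges = [0.0]
    mat_idx = []
    for name, t in phantom.slabs:
        mat_idx.append(midx(name))
        edges.append(edges[-1] + t)
    zmax = N_BINS * BIN_CM
    if edges[-1] < zmax:  # pad with the last material to the tally depth
        edges[-1] = zmax

    det_on = detector_at is not None
    tally_on = det_on or tally_at is not None
    if tally_on:
        det_z0 = float(detector_at if det_on else tally_at)
        if not 0.0 <= det_z0 < zmax:
            raise ValueError("detector/tally depth outside the tally range")
        # register the chip material in both paired runs so the Woodcock
        # majorant is identical: with a shared seed the photon histories then
        # stay correlated everywhere outside the chip region, which collapses
        # the variance of the Fcor ratio
        det_mat = midx(detector_material)
    else:
        det_z0, det_mat = 0.0, 0

    (mu_tot, p_pe, p_pair, mu_max, sp, rho, x0,
     loge0, dloge, ne) = _build_run_arrays(mats)

    spec = beam.spectrum
    cdf = np.cumsum(spec.weights)
    cdf /= cdf[-1]

    score_r = (
        options.scoring_radius_cm
        if options.scoring_radius_cm is not None
        else CHIP_RADIUS_CM
    )

    dose_batches, det_tally, e_emit, e_dep = _transport.run_histories(
        options.n_histories, options.seed,
        np.asarray(spec.energy_bins, dtype=float), cdf,
        loge0, dloge, ne,
        mu_tot, p_pe, p_pair, mu_max,
        sp, rho, x0,
        np.asarray(edges), np.asarray(mat_idx, dtype=np.int64),
        det_on, det_z0, det_z0 + CHIP_THICKNESS_CM, CHIP_RADIUS_CM, det_mat,
        tally_on,
        beam.ssd_cm, beam.equivalent_radius_cm,
        options.photon_cutoff_kev * 1e-3,
        options.electron_cutoff_kev * 1e-3,
        options.max_step_gcm2,
        1 if options.electron_transport == "kernel" else 0,
        options.primary_only,
        score_r, N_BINS, BIN_CM, 15.0,
        options.n_batches,
    )

    if dose_batches.sum() <= 0.0:
        raise RuntimeError(
            "no energy scored on the axis; increase n_histories"
        )

    centers = (np.arange(N_BINS) + 0.5) * BIN_CM
    # per-bin voxel mass from the on-axis slab material (MeV -> MeV/g)
    masses = np.array([
        get_material(phantom.material_at(min(c, phantom.total_depth - 1e-9))).density
        for c in centers
    ]) * math.pi * score_r**2 * BIN_CM
    batch_dose = dose_batches / masses[None, :]
    nb = options.n_batches
    mean = batch_dose.mean(axis=0)
    se = batch_dose.std(axis=0, ddof=1) / math.sqrt(nb)
    rel = np.where(mean > 0, se / np.where(mean > 0, mean, 1.0), 0.0)

    chip_dose = chip_rel = None
    chip_batches = None
    if tally_on:
        region_density = (
            get_material(detector_material).density if det_on
            else get_material(
                phantom.material_at(min(det_z0 + CHIP_THICKNESS_CM / 2,
                                        phantom.total_depth - 1e-9))
            ).density
        )
        region_mass = region_density * math.pi * CHIP_RADIUS_CM**2 * CHIP_THICKNESS_CM
        per_batch = det_tally / region_mass
        m = per_batch.mean()
        s = per_batch.std(ddof=1) / math.sqrt(nb)
        chip_dose = m * nb / options.n_histories
        chip_rel = float(s / m) if m > 0 else float("inf")
        chip_batches = per_batch * nb / options.n_histories

    return DoseProfile(
        depth_centers_cm=centers,
        dose=mean * nb / options.n_histories,
        rel_se=rel,
        scoring_radius_cm=score_r,
        n_histories=options.n_histories,
        energy_emitted_mev=e_emit,
        energy_deposited_mev=e_dep,
        chip_dose=chip_dose,
        chip_rel_se=chip_rel,
        chip_dose_batches=chip_batches,
    )


@dataclass(frozen=True)
class PerturbationProfile:
    """Detector perturbation factors Fcor = PDD(with chip)/PDD(without)."""

    depths_cm: np.ndarray
    fcor: np.ndarray
    rel_se: np.ndarray

    def as_dict(self) -> dict[float, float]:
        return {float(d): float(f) for d, f in zip(self.depths_cm, self.fcor)}


def perturbation_profile(
    phantom: PhantomStack,
    beam: BeamConfig,
    depths_cm: list[float],
    options: TransportOptions,
    detector_material: str = "lif",
) -> PerturbationProfile:
    """Paired with/without-chip runs (same seed) at each requested depth.

    Fcor(d) = [dose to the chip at depth d] / [dose in the same chip-sized
    region of the undisturbed phantom]: the ratio of what the detector reads
    to what the medium would have absorbed there.

    The paired runs share the seed and the Woodcock majorant (the chip
    material is registered in both), so photon histories are identical
    outside the chip's sphere of influence; the ratio is formed per
    correlated batch, which gives it a far smaller standard error than the
    two chip tallies individually."""
    fcor = np.empty(len(depths_cm))
    rel = np.empty(len(depths_cm))
    for i, d in enumerate(depths_cm):
        front = d - CHIP_THICKNESS_CM / 2
        with_det = simulate_depth_dose(
            phantom, beam, options,
            detector_at=front, detector_material=detector_material,
        )
        base = simulate_depth_dose(
            phantom, beam, options,
            tally_at=front, detector_material=detector_material,
        )
        a = with_det.chip_dose_batches
        b = base.chip_dose_batches
        nb = a.size
        fcor[i] = a.sum() / b.sum()
        # jackknife over correlated batches (individual batches may tally
        # nothing in the chip-sized region)
        theta = (a.sum() - a) / (b.sum() - b)
        rel[i] = math.sqrt((nb - 1) / nb * ((theta - theta.mean()) ** 2).sum()) / fcor[i]
    return PerturbationProfile(
        depths_cm=np.asarray(depths_cm, dtype=float), fcor=fcor, rel_se=rel
    )


def apply_perturbation(
    measured: dict[float, float], fcor: dict[float, float]
) -> dict[float, float]:
    """Remove the detector perturbation: corrected = measured / Fcor.

    Fcor converts a detector-present value to the detector-free one, so the
    measurement (made with the chip in place) is divided by it."""
    if set(measured) != set(fcor):
        raise ValueError("depth grids of measured doses and Fcor differ")
    return {d: measured[d] / fcor[d] for d in measured}


def run_until_precision(
    phantom: PhantomStack,
    beam: BeamConfig,
    options: TransportOptions,
    target_rel_se: float = 0.005,
    max_histories: int = 20_000_000,
) -> DoseProfile:
    """Double the history count until the maximum-dose bin reaches the target
    relative standard error (mirrors choosing the run length for a required
    statistical variance at the plane of maximum dose)."""
    n = options.n_histories
    while True:
        prof = simulate_depth_dose(phantom, beam, replace(options, n_histories=n))
        imax = int(np.argmax(prof.dose))
        if prof.rel_se[imax] <= target_rel_se or n >= max_histories:
            return prof
        n = min(2 * n, max_histories)


def homogeneous_beam_data(
    beam: BeamConfig,
    options: TransportOptions,
    field_sides_cm: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 5.0, 10.0),
):
    """TMR/TAR beam-data tables from homogeneous water-phantom simulations.

    TMR(d) = PDD(d) * ((SSD+d)/(SSD+dmax))^2 (inverse-square conversion of
    the normalized PDD); TAR is taken equal to TMR (backscatter-free
    approximation).  Extra small-field entries beyond the four study fields
    cover the density-scaled radii the equivalent-TAR method asks for.
    """
    from .comparison import normalize_pdd  # local import to avoid a cycle
    from .hetero_corrections import BeamDataTable

    water = PhantomStack((("water", N_BINS * BIN_CM),))
    radii = []
    tmr_rows = []
    dmax_cm = None
    for ls in field_sides_cm:
        b = replace(beam, square_side_cm=ls)
        opts = replace(
            options,
            scoring_radius_cm=default_scoring_radius(b.equivalent_radius_cm),
        )
        prof = simulate_depth_dose(water, b, opts)
        pdd = normalize_pdd(prof)
        if ls == max(field_sides_cm):
            dmax_cm = pdd.dmax_cm
        d = prof.depth_centers_cm
        tmr = pdd.values / 100.0 * ((beam.ssd_cm + d) / (beam.ssd_cm + pdd.dmax_cm)) ** 2
        radii.append(b.equivalent_radius_cm)
        tmr_rows.append(tmr)
    depths = (np.arange(N_BINS) + 0.5) * BIN_CM
    tmr_arr = np.asarray(tmr_rows)
    return BeamDataTable(
        field_radii_cm=np.asarray(radii),
        depths_cm=depths,
        tmr=tmr_arr,
        tar=tmr_arr.copy(),
        dmax_cm=float(dmax_cm),
    )
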