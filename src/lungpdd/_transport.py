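"""Numba transport kernel for the slab-geometry photon/electron dose engine.

Analog photon transport (Klein-Nishina Compton, photoelectric, pair
production) with Woodcock (delta) tracking through the slab stack plus an
optional on-axis detector chip region.  Secondary electrons are transported
in ``kernel`` mode as stepped straight-line CSDA tracks with Highland
multiple-scattering deflections; this captures longitudinal buildup and the
lateral electronic disequilibrium that depresses small-field dose in
low-density media, at a fraction of condensed-history cost.

All geometry is cylindrically symmetric: z is depth below the phantom
surface (cm), r the distance from the beam axis.  Energy is tallied per
0.5 cm depth bin inside a central scoring cylinder, split over contiguous
history batches for uncertainty estimation.  An optional chip-sized tally
region records the energy absorbed where a TLD would sit (used by the
detector-perturbation workflow, with and without the chip present).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_ME = 0.51099895


@njit(cache=True, inline="always")
def _loglookup(table, e, loge0, dloge, n):
    """Linear interpolation of ``table`` on the shared log-energy grid."""
    x = (math.log(e) - loge0) / dloge
    if x <= 0.0:
        return table[0]
    if x >= n - 1:
        return table[n - 1]
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True, inline="always")
def _material_at(z, r, slab_edges, slab_mat, det_on, det_z0, det_z1, det_r, det_mat):
    if det_on and det_z0 <= z < det_z1 and r < det_r:
        return det_mat
    for i in range(slab_mat.shape[0]):
        if z < slab_edges[i + 1]:
            return slab_mat[i]
    return slab_mat[slab_mat.shape[0] - 1]


@njit(cache=True, inline="always")
def _score_point(de, z, r, score_r, nz, dz, dose_bin,
                 tally_on, tly_z0, tly_z1, tly_r, det_tally, ib):
    if r < score_r and 0.0 <= z < nz * dz:
        dose_bin[int(z / dz)] += de
    if tally_on and tly_z0 <= z < tly_z1 and r < tly_r:
        det_tally[ib] += de


@njit(cache=True, inline="always")
def _score_segment(de, za, zb, rm, score_r, nz, dz, dose_bin,
                   tally_on, tly_z0, tly_z1, tly_r, det_tally, ib):
    """Apportion a track segment's energy over the depth bins it crosses
    (midpoint binning would alias: boundary crossings phase-lock the step
    grid of every electron entering a new slab) and over the detector
    tally region."""
    z0 = za if za < zb else zb
    z1 = zb if za < zb else za
    span = z1 - z0
    if rm < score_r and z1 > 0.0 and z0 < nz * dz:
        lo = z0 if z0 > 0.0 else 0.0
        hi = z1 if z1 < nz * dz else nz * dz - 1e-12
        if span < 1e-12 or hi - lo < 1e-12:
            dose_bin[int(lo / dz)] += de
        else:
            i0 = int(lo / dz)
            i1 = int(hi / dz)
            for k in range(i0, i1 + 1):
                seg_lo = lo if lo > k * dz else k * dz
                seg_hi = hi if hi < (k + 1) * dz else (k + 1) * dz
                if seg_hi > seg_lo:
                    dose_bin[k] += de * (seg_hi - seg_lo) / span
    if tally_on and rm < tly_r and z1 > tly_z0 and z0 < tly_z1:
        if span < 1e-12:
            det_tally[ib] += de
        else:
            seg_lo = z0 if z0 > tly_z0 else tly_z0
            seg_hi = z1 if z1 < tly_z1 else tly_z1
            if seg_hi > seg_lo:
                det_tally[ib] += de * (seg_hi - seg_lo) / span


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, ct, phi):
    """Rotate unit vector u by polar angle acos(ct) about itself."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cphi = math.cos(phi)
    sphi = math.sin(phi)
    if abs(uz) > 0.99999999:
        sign = 1.0 if uz > 0.0 else -1.0
        return st * cphi, sign * st * sphi, sign * ct
    rho = math.sqrt(ux * ux + uy * uy)
    vx = st * (cphi * uz * ux - sphi * uy) / rho + ct * ux
    vy = st * (cphi * uz * uy + sphi * ux) / rho + ct * uy
    vz = -st * cphi * rho + ct * uz
    norm = math.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


@njit(cache=True)
def _transport_electron(
    t0, x, y, z, ux, uy, uz,
    sp, rho, x0_rl,
    loge0, dloge, ne,
    slab_edges, slab_mat, det_on, det_z0, det_z1, det_r, det_mat,
    ecut, estep, score_r, nz, dz, zmax, r_world,
    dose_bin,
    tally_on, tly_z0, tly_z1, tly_r, det_tally, ib,
):
    """Stepped straight-line CSDA electron track; returns energy deposited."""
    t = t0
    deposited = 0.0
    while t > ecut:
        r = math.sqrt(x * x + y * y)
        if z < -1.0 or z > zmax + 1.0 or r > r_world:
            break
        mat = _material_at(z, r, slab_edges, slab_mat,
                           det_on, det_z0, det_z1, det_r, det_mat)
        s_mass = _loglookup(sp[mat], t, loge0, dloge, ne)  # MeV cm^2/g
        dm = estep
        de = s_mass * dm
        if de > t:
            de = t
            dm = de / s_mass
        ds = dm / rho[mat]
        # cap the step at the next z-plane (slab or detector face) so a
        # single step never straddles a density boundary
        if abs(uz) > 1e-9:
            t_plane = 1e30
            for k in range(slab_edges.shape[0]):
                tp = (slab_edges[k] - z) / uz
                if 1e-7 < tp < t_plane:
                    t_plane = tp
            if det_on or tally_on:
                tp = (det_z0 - z) / uz
                if 1e-7 < tp < t_plane:
                    t_plane = tp
                tp = (det_z1 - z) / uz
                if 1e-7 < tp < t_plane:
                    t_plane = tp
            if ds > t_plane:
                ds = t_plane + 1e-6
                dm = ds * rho[mat]
                de = s_mass * dm
                if de > t:
                    de = t
        xm = x + 0.5 * ds * ux
        ym = y + 0.5 * ds * uy
        rm = math.sqrt(xm * xm + ym * ym)
        _score_segment(de, z, z + ds * uz, rm, score_r, nz, dz, dose_bin,
                       tally_on, tly_z0, tly_z1, tly_r, det_tally, ib)
        deposited += de
        x += ds * ux
        y += ds * uy
        z += ds * uz
        t -= de
        if t <= ecut:
            break
        # Highland multiple-scattering deflection over this step
        gamma = t / _ME + 1.0
        pbeta = t * (t + 2.0 * _ME) / (t + _ME)  # p*beta*c in MeV
        xr = dm / x0_rl[mat]
        theta0 = 13.6 / pbeta * math.sqrt(xr) * (1.0 + 0.038 * math.log(xr))
        if theta0 > 0.0:
            # polar angle Rayleigh-distributed for a 2D gaussian kick
            th = theta0 * math.sqrt(-2.0 * math.log(np.random.random()))
            if th > 1.5:
                th = 1.5
            ux, uy, uz = _rotate(ux, uy, uz, math.cos(th),
                                 2.0 * math.pi * np.random.random())
    # residual below cutoff deposited locally
    if t > 0.0:
        r = math.sqrt(x * x + y * y)
        _score_point(t, z, r, score_r, nz, dz, dose_bin,
                     tally_on, tly_z0, tly_z1, tly_r, det_tally, ib)
        deposited += t
    return deposited


@njit(cache=True)
def _sample_compton(e):
    """Rejection sampling of the KN scattered-photon energy fraction.

    Proposal density ~ 1/eps on [1/(1+2a), 1]; accept with weight
    eps*f(eps)/2 where f is the KN differential in eps.  Returns
    (eps, cos_theta_photon)."""
    a = e / _ME
    eps_min = 1.0 / (1.0 + 2.0 * a)
    log_ratio = -math.log(eps_min)
    while True:
        eps = eps_min * math.exp(log_ratio * np.random.random())
        ct = 1.0 - (1.0 / eps - 1.0) / a
        sin2 = 1.0 - ct * ct
        g = eps * eps + 1.0 - eps * sin2
        if 2.0 * np.random.random() <= g:
            return eps, ct


@njit(cache=True)
def run_histories(
    n_hist, seed,
    spectrum_e, spectrum_cdf,
    loge0, dloge, ne,
    mu_tot, p_pe, p_pair, mu_max,
    sp, rho, x0_rl,
    slab_edges, slab_mat,
    det_on, det_z0, det_z1, det_r, det_mat,
    tally_on,
    ssd, field_r,
    pcut, ecut, estep, electron_mode, primary_only,
    score_r, nz, dz, r_world,
    n_batch,
):
    """Run ``n_hist`` photon histories.

    Returns (dose_batches[n_batch, nz], det_tally[n_batch], e_emitted,
    e_deposited); energies in MeV.  ``det_tally`` is filled when
    ``tally_on``: it is the energy absorbed inside the chip-sized region
    [det_z0, det_z1) x (r < det_r), whether or not the chip material is
    actually present (``det_on``)."""
    np.random.seed(seed)
    dose_batches = np.zeros((n_batch, nz))
    det_tally = np.zeros(n_batch)
    zmax = nz * dz
    e_emitted = 0.0
    e_deposited = 0.0
    st_e = np.empty(32)
    st_x = np.empty(32)
    st_y = np.empty(32)
    st_z = np.empty(32)
    st_ux = np.empty(32)
    st_uy = np.empty(32)
    st_uz = np.empty(32)

    for h in range(n_hist):
        ib = h * n_batch // n_hist
        dose_bin = dose_batches[ib]
        u = np.random.random()
        k = np.searchsorted(spectrum_cdf, u)
        if k >= spectrum_e.shape[0]:
            k = spectrum_e.shape[0] - 1
        e0 = spectrum_e[k]
        e_emitted += e0
        # entry point uniform over the field disc at the surface, direction
        # from the point source at z = -ssd on the axis
        rr = field_r * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        x = rr * math.cos(phi)
        y = rr * math.sin(phi)
        z = 0.0
        norm = math.sqrt(rr * rr + ssd * ssd)
        ux = x / norm
        uy = y / norm
        uz = ssd / norm

        nstack = 1
        st_e[0] = e0
        st_x[0] = x
        st_y[0] = y
        st_z[0] = z
        st_ux[0] = ux
        st_uy[0] = uy
        st_uz[0] = uz

        while nstack > 0:
            nstack -= 1
            e = st_e[nstack]
            x = st_x[nstack]
            y = st_y[nstack]
            z = st_z[nstack]
            ux = st_ux[nstack]
            uy = st_uy[nstack]
            uz = st_uz[nstack]

            while e > pcut:
                mumax = _loglookup(mu_max, e, loge0, dloge, ne)
                s = -math.log(np.random.random()) / mumax
                x += s * ux
                y += s * uy
                z += s * uz
                r = math.sqrt(x * x + y * y)
                if z < 0.0 or z > zmax or r > r_world:
                    e = 0.0
                    break  # escaped
                mat = _material_at(z, r, slab_edges, slab_mat,
                                   det_on, det_z0, det_z1, det_r, det_mat)
                mloc = _loglookup(mu_tot[mat], e, loge0, dloge, ne)
                if np.random.random() * mumax > mloc:
                    continue  # virtual collision
                if primary_only:
                    # absorb the whole photon at its first interaction: the
                    # expected tally is then proportional to exp(-mu z)
                    _score_point(e, z, r, score_r, nz, dz, dose_bin,
                                 tally_on, det_z0, det_z1, det_r,
                                 det_tally, ib)
                    e_deposited += e
                    e = 0.0
                    break
                upe = _loglookup(p_pe[mat], e, loge0, dloge, ne)
                upair = _loglookup(p_pair[mat], e, loge0, dloge, ne)
                u = np.random.random()
                if u < upe:
                    # photoelectric
                    if electron_mode == 1:
                        e_deposited += _transport_electron(
                            e, x, y, z, ux, uy, uz,
                            sp, rho, x0_rl, loge0, dloge, ne,
                            slab_edges, slab_mat, det_on, det_z0, det_z1,
                            det_r, det_mat,
                            ecut, estep, score_r, nz, dz, zmax, r_world,
                            dose_bin,
                            tally_on, det_z0, det_z1, det_r, det_tally, ib)
                    else:
                        _score_point(e, z, r, score_r, nz, dz, dose_bin,
                                     tally_on, det_z0, det_z1, det_r,
                                     det_tally, ib)
                        e_deposited += e
                    e = 0.0
                elif u < upe + upair:
                    # pair production: e+/e- share e-2mc2, forward directed;
                    # annihilation photons re-emitted isotropically
                    tk = e - 2.0 * _ME
                    f = np.random.random()
                    for tpart in (f * tk, (1.0 - f) * tk):
                        if tpart <= 0.0:
                            continue
                        if electron_mode == 1:
                            e_deposited += _transport_electron(
                                tpart, x, y, z, ux, uy, uz,
                                sp, rho, x0_rl, loge0, dloge, ne,
                                slab_edges, slab_mat, det_on, det_z0, det_z1,
                                det_r, det_mat,
                                ecut, estep, score_r, nz, dz, zmax, r_world,
                                dose_bin,
                                tally_on, det_z0, det_z1, det_r,
                                det_tally, ib)
                        else:
                            _score_point(tpart, z, r, score_r, nz, dz,
                                         dose_bin, tally_on, det_z0, det_z1,
                                         det_r, det_tally, ib)
                            e_deposited += tpart
                    ctann = 2.0 * np.random.random() - 1.0
                    phann = 2.0 * math.pi * np.random.random()
                    stann = math.sqrt(max(0.0, 1.0 - ctann * ctann))
                    if nstack < 30:
                        st_e[nstack] = _ME
                        st_x[nstack] = x
                        st_y[nstack] = y
                        st_z[nstack] = z
                        st_ux[nstack] = stann * math.cos(phann)
                        st_uy[nstack] = stann * math.sin(phann)
                        st_uz[nstack] = ctann
                        nstack += 1
                        st_e[nstack] = _ME
                        st_x[nstack] = x
                        st_y[nstack] = y
                        st_z[nstack] = z
                        st_ux[nstack] = -stann * math.cos(phann)
                        st_uy[nstack] = -stann * math.sin(phann)
                        st_uz[nstack] = -ctann
                        nstack += 1
                    e = 0.0
                else:
                    # Compton
                    eps, ct = _sample_compton(e)
                    t_el = e * (1.0 - eps)
                    a = e / _ME
                    tan_half = math.sqrt(max(0.0, (1.0 - ct) / (1.0 + ct))) \
                        if ct > -1.0 else 1e10
                    if tan_half > 1e-12:
                        cot_e = (1.0 + a) * tan_half
                        ct_e = cot_e / math.sqrt(1.0 + cot_e * cot_e)
                    else:
                        ct_e = 0.0
                    phi_c = 2.0 * math.pi * np.random.random()
                    if t_el > 0.0:
                        eux, euy, euz = _rotate(ux, uy, uz, ct_e,
                                                phi_c + math.pi)
                        if electron_mode == 1:
                            e_deposited += _transport_electron(
                                t_el, x, y, z, eux, euy, euz,
                                sp, rho, x0_rl, loge0, dloge, ne,
                                slab_edges, slab_mat, det_on, det_z0, det_z1,
                                det_r, det_mat,
                                ecut, estep, score_r, nz, dz, zmax, r_world,
                                dose_bin,
                                tally_on, det_z0, det_z1, det_r,
                                det_tally, ib)
                        else:
                            _score_point(t_el, z, r, score_r, nz, dz,
                                         dose_bin, tally_on, det_z0, det_z1,
                                         det_r, det_tally, ib)
                            e_deposited += t_el
                    ux, uy, uz = _rotate(ux, uy, uz, ct, phi_c)
                    e *= eps
            else:
                # photon fell below the cutoff: deposit locally
                if e > 0.0:
                    r = math.sqrt(x * x + y * y)
                    _score_point(e, z, r, score_r, nz, dz, dose_bin,
                                 tally_on, det_z0, det_z1, det_r,
                                 det_tally, ib)
                    e_deposited += e
                e = 0.0

    return dose_batches, det_tally, e_emitted, e_deposited
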