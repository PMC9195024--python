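"""Numba transport kernel for the slab-geometry photon Monte Carlo.

Analog transport of photons through a stack of homogeneous slabs:
free paths from layerwise total attenuation, interactions sampled among
incoherent (Klein-Nishina on free electrons, rejection-sampled scattered
fraction), photoelectric (local absorption) and pair production (two
back-to-back 0.511 MeV photons). No variance reduction is applied to the
transport. Two collision-kerma tallies are available:

* track-length (expected-value) estimator: every flight segment crossing
  the scoring column deposits E * (mu_tr/rho) * path-length / V_bin;
* collision estimator: the sampled energy transferred to electrons at
  each interaction is deposited in the local bin.

Cross-section tables are passed in as per-layer arrays on a uniform
log-energy grid; lookups are linear in (log E, log mu).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_STACK = 64


@njit(cache=False, inline="always")
def _interp_log(table_row, log_e0, dlog_e, n_e, log_e):
    """Linear interpolation of a log-coefficient row at log energy."""
    f = (log_e - log_e0) / dlog_e
    if f <= 0.0:
        return table_row[0]
    if f >= n_e - 1:
        return table_row[n_e - 1]
    i = int(f)
    t = f - i
    return table_row[i] * (1.0 - t) + table_row[i + 1] * t


@njit(cache=False)
def run_batch(
    n_hist,
    seed,
    # source
    line_e,
    line_cumw,
    src_z,
    axis_z,
    half_field,
    # geometry
    z_edges,
    half_extent,
    half_score,
    bin_w,
    n_bins,
    bin_layer,
    bin_rho,
    # cross-section tables (log10 of per-cm / mass coefficients)
    log_e0,
    dlog_e,
    n_e,
    log_mu_incoh,
    log_mu_pe,
    log_mu_pair,
    log_mutr_mass,
    # options
    e_cut,
    estimator_collision,
    primary_only,
    bin_edep,
):
    """Transport ``n_hist`` photon histories; accumulate into ``bin_edep``.

    Returns (emitted_energy, deposited_energy) in MeV. ``bin_edep`` holds
    raw tally sums: MeV*cm^2/g*cm for the track-length estimator, MeV for
    the collision estimator (normalized by the caller).
    """
    np.random.seed(seed)
    n_layers = z_edges.shape[0] - 1
    total_z = z_edges[n_layers]
    n_lines = line_e.shape[0]

    st_e = np.empty(_STACK)
    st_x = np.empty(_STACK)
    st_y = np.empty(_STACK)
    st_z = np.empty(_STACK)
    st_u = np.empty(_STACK)
    st_v = np.empty(_STACK)
    st_w = np.empty(_STACK)

    emitted = 0.0
    deposited = 0.0

    for _ in range(n_hist):
        # --- source: line energy, divergent direction into the field square
        r = np.random.random()
        e0 = line_e[n_lines - 1]
        for j in range(n_lines):
            if r <= line_cumw[j]:
                e0 = line_e[j]
                break
        xf = (2.0 * np.random.random() - 1.0) * half_field
        yf = (2.0 * np.random.random() - 1.0) * half_field
        dx = xf
        dy = yf
        dz = axis_z - src_z
        norm = np.sqrt(dx * dx + dy * dy + dz * dz)
        u = dx / norm
        v = dy / norm
        w = dz / norm
        # advance from the source through vacuum to the entry surface z=0
        t0 = -src_z / w
        x = u * t0
        y = v * t0
        z = 0.0
        emitted += e0

        n_stack = 1
        st_e[0] = e0
        st_x[0] = x
        st_y[0] = y
        st_z[0] = z
        st_u[0] = u
        st_v[0] = v
        st_w[0] = w

        while n_stack > 0:
            n_stack -= 1
            e = st_e[n_stack]
            x = st_x[n_stack]
            y = st_y[n_stack]
            z = st_z[n_stack]
            u = st_u[n_stack]
            v = st_v[n_stack]
            w = st_w[n_stack]

            alive = True
            tau = -np.log(np.random.random())
            while alive:
                # locate layer (z in [edge[l], edge[l+1]); boundary nudges below)
                layer = 0
                for l in range(n_layers):
                    if z >= z_edges[l]:
                        layer = l
                log_e = np.log(e)
                mu_i = np.exp(_interp_log(log_mu_incoh[layer], log_e0, dlog_e, n_e, log_e))
                mu_p = np.exp(_interp_log(log_mu_pe[layer], log_e0, dlog_e, n_e, log_e))
                mu_pr = np.exp(_interp_log(log_mu_pair[layer], log_e0, dlog_e, n_e, log_e))
                mu_tot = mu_i + mu_p + mu_pr

                # distance to layer boundary along w
                if w > 1e-12:
                    t_z = (z_edges[layer + 1] - z) / w
                elif w < -1e-12:
                    t_z = (z_edges[layer] - z) / w
                else:
                    t_z = 1e30
                # lateral escape distance
                t_lat = 1e30
                if u > 1e-12:
                    t_lat = min(t_lat, (half_extent - x) / u)
                elif u < -1e-12:
                    t_lat = min(t_lat, (-half_extent - x) / u)
                if v > 1e-12:
                    t_lat = min(t_lat, (half_extent - y) / v)
                elif v < -1e-12:
                    t_lat = min(t_lat, (-half_extent - y) / v)
                t_int = tau / mu_tot

                s = t_int
                event = 0  # 0 interact, 1 cross boundary, 2 escape
                if t_z < s:
                    s = t_z
                    event = 1
                if t_lat < s:
                    s = t_lat
                    event = 2

                # --- track-length tally over this segment
                if estimator_collision == 0:
                    ta = 0.0
                    tb = s
                    # clip to |x| <= half_score
                    if u > 1e-12 or u < -1e-12:
                        c1 = (-half_score - x) / u
                        c2 = (half_score - x) / u
                        if c1 > c2:
                            c1, c2 = c2, c1
                        if c1 > ta:
                            ta = c1
                        if c2 < tb:
                            tb = c2
                    elif x < -half_score or x > half_score:
                        tb = ta - 1.0
                    if tb > ta and (v > 1e-12 or v < -1e-12):
                        c1 = (-half_score - y) / v
                        c2 = (half_score - y) / v
                        if c1 > c2:
                            c1, c2 = c2, c1
                        if c1 > ta:
                            ta = c1
                        if c2 < tb:
                            tb = c2
                    elif tb > ta and (y < -half_score or y > half_score):
                        tb = ta - 1.0
                    if tb > ta:
                        mutr = np.exp(
                            _interp_log(log_mutr_mass[layer], log_e0, dlog_e, n_e, log_e)
                        )
                        za = z + w * ta
                        zb = z + w * tb
                        if za > zb:
                            za, zb = zb, za
                        if za < 0.0:
                            za = 0.0
                        if zb > total_z:
                            zb = total_z
                        if zb > za:
                            if w < 1e-9 and w > -1e-9:
                                b = int(z / bin_w)
                                if 0 <= b < n_bins:
                                    bin_edep[b] += e * mutr * (tb - ta)
                            else:
                                inv_w = 1.0 / np.abs(w)
                                b_lo = int(za / bin_w)
                                b_hi = int(zb / bin_w)
                                if b_hi >= n_bins:
                                    b_hi = n_bins - 1
                                for b in range(b_lo, b_hi + 1):
                                    z_lo = b * bin_w
                                    z_hi = z_lo + bin_w
                                    if z_lo < za:
                                        z_lo = za
                                    if z_hi > zb:
                                        z_hi = zb
                                    if z_hi > z_lo:
                                        bin_edep[b] += e * mutr * (z_hi - z_lo) * inv_w

                x += u * s
                y += v * s
                z += w * s

                if event == 2:
                    break  # lateral escape
                if event == 1:
                    tau -= s * mu_tot
                    if w > 0.0 and z >= total_z - 1e-12:
                        break  # transmitted
                    if w < 0.0 and z <= 1e-12:
                        break  # backscattered out
                    # nudge off the boundary into the next layer
                    z += 1e-9 if w > 0.0 else -1e-9
                    continue

                # --- interaction
                r = np.random.random() * mu_tot
                edep_local = 0.0
                if r < mu_i:
                    # incoherent: sample scattered fraction eps by rejection
                    a = e / 0.511
                    eps_min = 1.0 / (1.0 + 2.0 * a)
                    g_max = eps_min + 1.0 / eps_min
                    eps = 1.0
                    cost = 1.0
                    while True:
                        eps = eps_min + (1.0 - eps_min) * np.random.random()
                        cost = 1.0 - (1.0 / eps - 1.0) / a
                        sin2 = 1.0 - cost * cost
                        g = eps + 1.0 / eps - sin2
                        if np.random.random() * g_max <= g:
                            break
                    e_sc = eps * e
                    edep_local = e - e_sc
                    if primary_only == 1:
                        edep_local = e  # terminate history; bank all energy locally
                        alive = False
                    elif e_sc < e_cut:
                        edep_local = e
                        alive = False
                    else:
                        # rotate direction by (cost, random azimuth)
                        sint = np.sqrt(max(1.0 - cost * cost, 0.0))
                        phi = 2.0 * np.pi * np.random.random()
                        cphi = np.cos(phi)
                        sphi = np.sin(phi)
                        rho = np.sqrt(u * u + v * v)
                        if rho > 1e-10:
                            un = u * cost + sint * (u * w * cphi - v * sphi) / rho
                            vn = v * cost + sint * (v * w * cphi + u * sphi) / rho
                            wn = w * cost - rho * sint * cphi
                        else:
                            un = sint * cphi
                            vn = sint * sphi
                            wn = cost if w > 0.0 else -cost
                        nrm = np.sqrt(un * un + vn * vn + wn * wn)
                        u = un / nrm
                        v = vn / nrm
                        w = wn / nrm
                        e = e_sc
                        tau = -np.log(np.random.random())
                elif r < mu_i + mu_p:
                    edep_local = e
                    alive = False
                else:
                    # pair: e+/e- absorbed locally, two annihilation photons
                    edep_local = e if primary_only == 1 else max(e - 1.022, 0.0)
                    alive = False
                    if primary_only == 0 and n_stack + 2 <= _STACK:
                        cz = 2.0 * np.random.random() - 1.0
                        sz = np.sqrt(max(1.0 - cz * cz, 0.0))
                        phi = 2.0 * np.pi * np.random.random()
                        au = sz * np.cos(phi)
                        av = sz * np.sin(phi)
                        aw = cz
                        for sgn in (1.0, -1.0):
                            if 0.511 >= e_cut:
                                st_e[n_stack] = 0.511
                                st_x[n_stack] = x
                                st_y[n_stack] = y
                                st_z[n_stack] = z
                                st_u[n_stack] = sgn * au
                                st_v[n_stack] = sgn * av
                                st_w[n_stack] = sgn * aw
                                n_stack += 1

                deposited += edep_local
                if estimator_collision == 1 and edep_local > 0.0:
                    if -half_score <= x <= half_score and -half_score <= y <= half_score:
                        b = int(z / bin_w)
                        if 0 <= b < n_bins:
                            bin_edep[b] += edep_local

    return emitted, deposited
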