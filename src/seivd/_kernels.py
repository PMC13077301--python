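"""Numba-compiled right-hand sides and the adaptive Dormand-Prince 5(4) stepper.

These kernels are the fast integration path used by :mod:`seivd.models` and
every likelihood evaluation in :mod:`seivd.inference`.  Pure-numpy reference
implementations of the same equations live in :mod:`seivd.models` and the two
paths are cross-checked in the test suite, together with a fixed-step RK4
oracle.

State layouts
-------------
pairwise:  ``[S, E_1 .. E_NE, I, V, D]``            (dimension ``NE + 4``)
community: ``[S_1..S_H, V_1..V_P, D, (E_1..E_NEp, I)_pair1, ...]``
           pair blocks ordered row-major over the true entries of the
           infection mask.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the stepper
OK = 0
STEP_UNDERFLOW = 1

_MIN_STEP = 1e-13
_SAFETY = 0.9
_MAX_FACTOR = 5.0
_MIN_FACTOR = 0.2


@njit(cache=True)
def pairwise_rhs(y, ne, r, phi, k, beta, d_c, hill_n, carrying_k, adsorb_infected):
    """SEIV/SEIVD derivative for the pairwise state layout.

    ``d_c = inf`` disables debris attenuation (SEIV); ``carrying_k = inf``
    disables logistic saturation of host growth.
    """
    dy = np.zeros_like(y)
    s = y[0]
    i_dens = y[1 + ne]
    v = y[2 + ne]
    d = y[3 + ne]

    theta = 1.0
    if np.isfinite(d_c):
        dd = d if d > 0.0 else 0.0
        theta = 1.0 / (1.0 + (dd / d_c) ** hill_n)

    growth = r * s
    if np.isfinite(carrying_k):
        total = s
        for m in range(1 + ne):
            total += y[1 + m]
        growth = r * s * (1.0 - total / carrying_k)

    infection = theta * phi * s * v

    dy[0] = growth - infection
    if ne > 0:
        dy[1] = infection - k * y[1]
        for m in range(2, ne + 1):
            dy[m] = k * (y[m - 1] - y[m])
        dy[1 + ne] = k * (y[ne] - i_dens)
    else:
        dy[1 + ne] = infection - k * i_dens
    dy[2 + ne] = beta * k * i_dens - infection
    if adsorb_infected:
        # optional sink: free phage also attach (and are lost) to E/I cells
        infected_total = i_dens
        for m in range(ne):
            infected_total += y[1 + m]
        dy[2 + ne] -= theta * phi * infected_total * v
    dy[3 + ne] = k * i_dens
    return dy


@njit(cache=True)
def community_rhs(
    y,
    n_hosts,
    n_phages,
    pair_host,
    pair_phage,
    pair_off,
    pair_ne,
    pair_k,
    pair_phi,
    pair_beta,
    host_r,
    host_dc,
    hill_n,
    carrying_k,
    adsorb_infected,
):
    """Community SEIV/SEIVD derivative with a shared debris pool.

    Only susceptible cells are adsorptive by default (no multiple infection);
    ``adsorb_infected`` adds the optional loss of free phage to the exposed
    and infected cells of their own host.
    """
    dy = np.zeros_like(y)
    d = y[n_hosts + n_phages]
    n_pairs = pair_host.shape[0]

    # per-host attenuation factors
    theta = np.ones(n_hosts)
    dd = d if d > 0.0 else 0.0
    for i in range(n_hosts):
        if np.isfinite(host_dc[i]):
            theta[i] = 1.0 / (1.0 + (dd / host_dc[i]) ** hill_n)

    total_cells = 0.0
    if np.isfinite(carrying_k):
        for i in range(n_hosts):
            total_cells += y[i]
        for p in range(n_pairs):
            off = pair_off[p]
            for m in range(pair_ne[p] + 1):
                total_cells += y[off + m]

    for i in range(n_hosts):
        if np.isfinite(carrying_k):
            dy[i] = host_r[i] * y[i] * (1.0 - total_cells / carrying_k)
        else:
            dy[i] = host_r[i] * y[i]

    for p in range(n_pairs):
        i = pair_host[p]
        j = pair_phage[p]
        off = pair_off[p]
        ne = pair_ne[p]
        k = pair_k[p]
        s = y[i]
        v = y[n_hosts + j]
        i_dens = y[off + ne]

        infection = theta[i] * pair_phi[p] * s * v
        dy[i] -= infection
        if ne > 0:
            dy[off] += infection - k * y[off]
            for m in range(1, ne):
                dy[off + m] += k * (y[off + m - 1] - y[off + m])
            dy[off + ne] += k * (y[off + ne - 1] - i_dens)
        else:
            dy[off] += infection - k * i_dens
        dy[n_hosts + j] += pair_beta[p] * k * i_dens - infection
        if adsorb_infected:
            infected_total = 0.0
            for m in range(ne + 1):
                infected_total += y[off + m]
            dy[n_hosts + j] -= theta[i] * pair_phi[p] * infected_total * v
        dy[n_hosts + n_phages] += k * i_dens

    return dy


@njit(cache=True)
def _rhs_dispatch(model, y, ipar, fpar, apar_i, apar_f):
    """Select the RHS for the stepper (0 = pairwise, 1 = community)."""
    if model == 0:
        return pairwise_rhs(
            y, ipar[0], fpar[0], fpar[1], fpar[2], fpar[3], fpar[4], fpar[5], fpar[6], ipar[1]
        )
    return community_rhs(
        y,
        ipar[0],
        ipar[1],
        apar_i[0],
        apar_i[1],
        apar_i[2],
        apar_i[3],
        apar_f[0],
        apar_f[1],
        apar_f[2],
        apar_f[3],
        apar_f[4],
        fpar[0],
        fpar[1],
        ipar[2],
    )


@njit(cache=True)
def dp45(model, y0, t_eval, rtol, atol, ipar, fpar, apar_i, apar_f):
    """Adaptive Dormand-Prince 5(4) integration evaluated on ``t_eval``.

    Steps are shortened to land exactly on every requested output time, so no
    interpolation error enters the returned grid values.  Returns
    ``(out, status, t_fail)``; on step-size underflow the remaining rows of
    ``out`` are left at zero and ``t_fail`` records where integration died.
    """
    n_out = t_eval.shape[0]
    n = y0.shape[0]
    out = np.zeros((n_out, n))
    y = y0.copy()
    t = t_eval[0]
    out[0] = y
    idx = 1
    if idx >= n_out:
        return out, OK, t

    k1 = _rhs_dispatch(model, y, ipar, fpar, apar_i, apar_f)
    # initial step from the scale of the derivative
    scale0 = atol + rtol * np.abs(y)
    d0 = np.sqrt(np.mean((y / scale0) ** 2))
    d1 = np.sqrt(np.mean((k1 / scale0) ** 2))
    h = 1e-6
    if d0 > 1e-5 and d1 > 1e-5:
        h = 0.01 * d0 / d1
    t_end = t_eval[n_out - 1]
    if h > t_end - t:
        h = t_end - t

    while idx < n_out:
        t_next_out = t_eval[idx]
        if t + h > t_next_out:
            h = t_next_out - t
        if h < _MIN_STEP:
            return out, STEP_UNDERFLOW, t

        k2 = _rhs_dispatch(model, y + h * (0.2 * k1), ipar, fpar, apar_i, apar_f)
        k3 = _rhs_dispatch(
            model, y + h * (3.0 / 40.0 * k1 + 9.0 / 40.0 * k2), ipar, fpar, apar_i, apar_f
        )
        k4 = _rhs_dispatch(
            model,
            y + h * (44.0 / 45.0 * k1 - 56.0 / 15.0 * k2 + 32.0 / 9.0 * k3),
            ipar,
            fpar,
            apar_i,
            apar_f,
        )
        k5 = _rhs_dispatch(
            model,
            y
            + h
            * (
                19372.0 / 6561.0 * k1
                - 25360.0 / 2187.0 * k2
                + 64448.0 / 6561.0 * k3
                - 212.0 / 729.0 * k4
            ),
            ipar,
            fpar,
            apar_i,
            apar_f,
        )
        k6 = _rhs_dispatch(
            model,
            y
            + h
            * (
                9017.0 / 3168.0 * k1
                - 355.0 / 33.0 * k2
                + 46732.0 / 5247.0 * k3
                + 49.0 / 176.0 * k4
                - 5103.0 / 18656.0 * k5
            ),
            ipar,
            fpar,
            apar_i,
            apar_f,
        )
        y5 = y + h * (
            35.0 / 384.0 * k1
            + 500.0 / 1113.0 * k3
            + 125.0 / 192.0 * k4
            - 2187.0 / 6784.0 * k5
            + 11.0 / 84.0 * k6
        )
        k7 = _rhs_dispatch(model, y5, ipar, fpar, apar_i, apar_f)
        y4 = y + h * (
            5179.0 / 57600.0 * k1
            + 7571.0 / 16695.0 * k3
            + 393.0 / 640.0 * k4
            - 92097.0 / 339200.0 * k5
            + 187.0 / 2100.0 * k6
            + 1.0 / 40.0 * k7
        )
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y5))
        err = np.sqrt(np.mean(((y5 - y4) / scale) ** 2))

        if err <= 1.0:
            t = t + h
            y = y5
            k1 = k7  # FSAL
            while idx < n_out and t_eval[idx] <= t + 1e-12 * max(1.0, abs(t)):
                out[idx] = y
                idx += 1
        if err > 0.0:
            factor = _SAFETY * err ** -0.2
        else:
            factor = _MAX_FACTOR
        if factor > _MAX_FACTOR:
            factor = _MAX_FACTOR
        if factor < _MIN_FACTOR:
            factor = _MIN_FACTOR
        h = h * factor

    return out, OK, t


@njit(cache=True)
def rk4_fixed(model, y0, t_eval, dt, ipar, fpar, apar_i, apar_f):
    """Classical fixed-step RK4, used as an independent oracle for dp45."""
    n_out = t_eval.shape[0]
    out = np.zeros((n_out, y0.shape[0]))
    y = y0.copy()
    t = t_eval[0]
    out[0] = y
    for idx in range(1, n_out):
        t_target = t_eval[idx]
        while t < t_target - 1e-12:
            h = dt if t + dt <= t_target else t_target - t
            k1 = _rhs_dispatch(model, y, ipar, fpar, apar_i, apar_f)
            k2 = _rhs_dispatch(model, y + 0.5 * h * k1, ipar, fpar, apar_i, apar_f)
            k3 = _rhs_dispatch(model, y + 0.5 * h * k2, ipar, fpar, apar_i, apar_f)
            k4 = _rhs_dispatch(model, y + h * k3, ipar, fpar, apar_i, apar_f)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        out[idx] = y
    return out
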