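"""Compiled numerical kernels (numba) shared by the deterministic and
stochastic integrators.

Scalar gating-rate functions live here so the event loop never leaves
nopython mode; the vectorized public versions in :mod:`hhcrit.hh` are
cross-checked against these in the test suite.

Units: V in mV, t in ms, rates in ms^-1, conductances in mS cm^-2,
currents in uA cm^-2, capacitance in uF cm^-2 (so C/g is in ms).
"""

import numpy as np
from numba import njit

# Voltages (mV) where the alpha_n / alpha_m / beta_m expressions are 0/0;
# inside +-_SING_EPS of them a first-order Taylor expansion is used.
_SING_EPS = 1e-6


@njit(cache=True, inline="always")
def alpha_n_s(v):
    x = v + 50.0
    if abs(x) < _SING_EPS:
        # x/(1-exp(-x/c)) = c + x/2 + O(x^2), c = 5
        return 0.032 * (5.0 + 0.5 * x)
    return 0.032 * x / (1.0 - np.exp(-x / 5.0))


@njit(cache=True, inline="always")
def alpha_m_s(v):
    x = v + 52.0
    if abs(x) < _SING_EPS:
        return 0.32 * (4.0 + 0.5 * x)
    return 0.32 * x / (1.0 - np.exp(-x / 4.0))


@njit(cache=True, inline="always")
def alpha_h_s(v):
    return 0.128 * np.exp(-(v + 48.0) / 18.0)


@njit(cache=True, inline="always")
def beta_n_s(v):
    return 0.5 * np.exp(-(v + 55.0) / 40.0)


@njit(cache=True, inline="always")
def beta_m_s(v):
    x = v + 25.0
    if abs(x) < _SING_EPS:
        # x/(exp(x/c)-1) = c - x/2 + O(x^2), c = 5
        return 0.28 * (5.0 - 0.5 * x)
    return 0.28 * x / (np.exp(x / 5.0) - 1.0)


@njit(cache=True, inline="always")
def beta_h_s(v):
    return 4.0 / (np.exp(-(v + 25.0) / 5.0) + 1.0)


@njit(cache=True)
def rates6(v, out):
    """Fill ``out`` (len 6) with (an, am, ah, bn, bm, bh) at voltage v."""
    out[0] = alpha_n_s(v)
    out[1] = alpha_m_s(v)
    out[2] = alpha_h_s(v)
    out[3] = beta_n_s(v)
    out[4] = beta_m_s(v)
    out[5] = beta_h_s(v)


@njit(cache=True, inline="always")
def _dvdt(v, m, h, n, gna_bar, gk_bar, gl, ena, ek, el, iex, c):
    ina = gna_bar * m * m * m * h * (ena - v)
    ik = gk_bar * n * n * n * n * (ek - v)
    il = gl * (el - v)
    return (ina + ik + il + iex) / c


@njit(cache=True)
def rk4_deterministic(v0, m0, h0, n0, iex, t_ms, dt,
                      gna_bar, gk_bar, gl, ena, ek, el, c):
    """Fixed-step RK4 of the deterministic HH equations.

    Returns (t, V, m, h, n) arrays including the initial state.
    """
    nstep = int(np.round(t_ms / dt))
    tv = np.empty(nstep + 1)
    vv = np.empty(nstep + 1)
    mv = np.empty(nstep + 1)
    hv = np.empty(nstep + 1)
    nv = np.empty(nstep + 1)
    v, m, h, n = v0, m0, h0, n0
    tv[0], vv[0], mv[0], hv[0], nv[0] = 0.0, v, m, h, n
    for i in range(nstep):
        # stage 1
        k1v = _dvdt(v, m, h, n, gna_bar, gk_bar, gl, ena, ek, el, iex, c)
        k1m = alpha_m_s(v) * (1.0 - m) - beta_m_s(v) * m
        k1h = alpha_h_s(v) * (1.0 - h) - beta_h_s(v) * h
        k1n = alpha_n_s(v) * (1.0 - n) - beta_n_s(v) * n
        # stage 2
        v2 = v + 0.5 * dt * k1v
        m2 = m + 0.5 * dt * k1m
        h2 = h + 0.5 * dt * k1h
        n2 = n + 0.5 * dt * k1n
        k2v = _dvdt(v2, m2, h2, n2, gna_bar, gk_bar, gl, ena, ek, el, iex, c)
        k2m = alpha_m_s(v2) * (1.0 - m2) - beta_m_s(v2) * m2
        k2h = alpha_h_s(v2) * (1.0 - h2) - beta_h_s(v2) * h2
        k2n = alpha_n_s(v2) * (1.0 - n2) - beta_n_s(v2) * n2
        # stage 3
        v3 = v + 0.5 * dt * k2v
        m3 = m + 0.5 * dt * k2m
        h3 = h + 0.5 * dt * k2h
        n3 = n + 0.5 * dt * k2n
        k3v = _dvdt(v3, m3, h3, n3, gna_bar, gk_bar, gl, ena, ek, el, iex, c)
        k3m = alpha_m_s(v3) * (1.0 - m3) - beta_m_s(v3) * m3
        k3h = alpha_h_s(v3) * (1.0 - h3) - beta_h_s(v3) * h3
        k3n = alpha_n_s(v3) * (1.0 - n3) - beta_n_s(v3) * n3
        # stage 4
        v4 = v + dt * k3v
        m4 = m + dt * k3m
        h4 = h + dt * k3h
        n4 = n + dt * k3n
        k4v = _dvdt(v4, m4, h4, n4, gna_bar, gk_bar, gl, ena, ek, el, iex, c)
        k4m = alpha_m_s(v4) * (1.0 - m4) - beta_m_s(v4) * m4
        k4h = alpha_h_s(v4) * (1.0 - h4) - beta_h_s(v4) * h4
        k4n = alpha_n_s(v4) * (1.0 - n4) - beta_n_s(v4) * n4
        v = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        m = m + dt / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        h = h + dt / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
        n = n + dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
        if not np.isfinite(v):
            # caller inspects the last finite index
            vv[i + 1:] = np.nan
            tv[i + 1:] = np.nan
            return tv, vv, mv, hv, nv
        tv[i + 1] = (i + 1) * dt
        vv[i + 1] = v
        mv[i + 1] = m
        hv[i + 1] = h
        nv[i + 1] = n
    return tv, vv, mv, hv, nv


@njit(cache=True)
def gillespie_kernel(counts, v0, t_end_ms, iex, sample_dt_ms, n_samples, out,
                     start_idx, t_start_ms, parent, child, kind, mult,
                     gna_bar, gk_bar, gl, ena, ek, el, c, n_na, n_k, seed):
    """Exact event-driven simulation of the channel ensemble.

    The membrane equation is linear while the open-channel counts are
    frozen, so between transition events V relaxes exponentially towards
    V_inf = (g.E + Iex)/G_tot; grid samples falling inside a dwell
    interval are filled from that closed form.

    ``counts`` (len 13: 8 Na states m_i h_j at j*4+i, then 5 K states) is
    updated in place; returns (V, t_ms, n_events, next_sample_idx).
    """
    np.random.seed(seed)
    ntr = parent.shape[0]
    psi = np.empty(ntr)
    r6 = np.empty(6)
    v = v0
    t = t_start_ms
    idx = start_idx
    n_events = 0
    while idx < n_samples:
        rates6(v, r6)
        lam = 0.0
        for tr in range(ntr):
            p = counts[parent[tr]] * mult[tr] * r6[kind[tr]]
            psi[tr] = p
            lam += p
        if lam <= 0.0:
            t1 = t_end_ms
        else:
            r1 = 1.0 - np.random.random()  # in (0, 1]
            t1 = t + (-np.log(r1)) / lam
        # frozen conductances over [t, t1]
        gna = gna_bar * counts[7] / n_na if n_na > 0 else 0.0
        gk = gk_bar * counts[12] / n_k if n_k > 0 else 0.0
        gtot = gna + gk + gl
        vinf = (gna * ena + gk * ek + gl * el + iex) / gtot
        # record grid samples inside the dwell interval
        while idx < n_samples:
            ts = idx * sample_dt_ms
            if ts > t1 or ts > t_end_ms:
                break
            out[idx] = vinf + (v - vinf) * np.exp(-gtot * (ts - t) / c)
            idx += 1
        if t1 >= t_end_ms or lam <= 0.0:
            v = vinf + (v - vinf) * np.exp(-gtot * (t_end_ms - t) / c)
            t = t_end_ms
            break
        v = vinf + (v - vinf) * np.exp(-gtot * (t1 - t) / c)
        t = t1
        if not np.isfinite(v):
            return np.nan, t, n_events, idx
        # which transition fired (inverse-CDF on the propensity vector)
        r2 = np.random.random() * lam
        cum = 0.0
        mu = ntr - 1
        for tr in range(ntr):
            cum += psi[tr]
            if r2 <= cum:
                mu = tr
                break
        counts[parent[mu]] -= 1
        counts[child[mu]] += 1
        n_events += 1
    return v, t, n_events, idx


@njit(cache=True)
def critical_map_kernel(n, u, z, noise_width, phi0, seed, noise_law):
    """Iterate the intermittency map phi <- phi + u*phi**z + eps.

    When the update exceeds 1 the trajectory is reinjected uniformly
    into [0, 1).  noise_law: 0 = Gaussian (sd = w, reflected at the
    fixed point so phi stays nonnegative), 1 = uniform one-sided on
    (0, w), 2 = uniform two-sided on (-w/2, w/2) (clipped at 0).
    """
    np.random.seed(seed)
    out = np.empty(n)
    phi = phi0
    out[0] = phi
    for i in range(1, n):
        if noise_law == 0:
            eps = np.random.normal() * noise_width
        elif noise_law == 1:
            eps = np.random.random() * noise_width
        else:
            eps = (np.random.random() - 0.5) * noise_width
        nxt = phi + u * phi ** z + eps
        if nxt > 1.0:
            nxt = np.random.random()
        elif nxt < 0.0:
            nxt = -nxt if noise_law == 0 else 0.0
        phi = nxt
        out[i] = phi
    return out
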