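"""Deterministic type-I Hodgkin-Huxley model.

Membrane equation (space-clamped, densities per cm^2)::

    C dV/dt = gNa_bar m^3 h (ENa - V) + gK_bar n^4 (EK - V)
              + gL (EL - V) + Iex

with first-order gating kinetics dx/dt = alpha_x(V)(1-x) - beta_x(V)x
for x in {m, h, n}.  The default parameters describe a hippocampal-style
integrator neuron: firing sets in through a saddle-node bifurcation at a
critical current density Ic (type-I excitability), so the firing rate
grows continuously from zero at rheobase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.optimize import brentq

from . import _kernels as _k

__all__ = [
    "ModelParams",
    "GatingState",
    "DeterministicState",
    "BifurcationResult",
    "gating_rate",
    "alpha_n", "alpha_m", "alpha_h", "beta_n", "beta_m", "beta_h",
    "steady_state",
    "ionic_currents",
    "integrate_deterministic",
    "find_fixed_point",
    "find_bifurcation",
]


@dataclass(frozen=True)
class ModelParams:
    """Membrane constants of the type-I parametrization.

    Conductances in mS cm^-2, potentials in mV, capacitance in
    uF cm^-2, channel densities in channels um^-2, area in um^2.
    ``blocked_K`` removes the voltage-gated K+ conductance and its
    channel population entirely (pharmacological blockade analogue).
    """

    C: float = 1.0
    gNa_bar: float = 50.0
    gK_bar: float = 10.0
    gL: float = 0.187
    ENa: float = 50.0
    EK: float = -95.0
    EL: float = -63.563
    rhoNa: float = 60.0
    rhoK: float = 18.0
    A: float = 30.0
    blocked_K: bool = False

    def __post_init__(self):
        if self.C <= 0 or self.A <= 0:
            raise ValueError("C and A must be positive")
        for name in ("gNa_bar", "gK_bar", "gL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_na < 1:
            raise ValueError("sodium channel count must be >= 1")
        if self.n_k < 1 and not self.blocked_K:
            raise ValueError("potassium channel count must be >= 1 "
                             "unless blocked_K")

    @property
    def n_na(self) -> int:
        return int(round(self.rhoNa * self.A))

    @property
    def n_k(self) -> int:
        """K+ channel count; zero when the channels are blocked."""
        return 0 if self.blocked_K else int(round(self.rhoK * self.A))

    @property
    def gK_eff(self) -> float:
        return 0.0 if self.blocked_K else self.gK_bar

    def blocked(self) -> "ModelParams":
        """Copy of the parameters with K+ channels removed."""
        return replace(self, blocked_K=True)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "ModelParams":
        if isinstance(src, (str, bytes)) and "{" in str(src):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(**d)


@dataclass
class GatingState:
    m: float
    h: float
    n: float

    def __post_init__(self):
        for x in (self.m, self.h, self.n):
            if not 0.0 <= x <= 1.0:
                raise ValueError("gating variables must lie in [0, 1]")


@dataclass
class DeterministicState:
    V: float
    gating: GatingState
    t: float = 0.0


# ---------------------------------------------------------------------------
# Gating-rate functions (vectorized; singularities handled by first-order
# Taylor expansion within 1e-6 mV of the singular argument).


def _linexp_pos(v, a, th, c):
    # a*(V-th) / (1 - exp(-(V-th)/c));  0/0 at V = th, limit a*c
    x = np.asarray(v, dtype=float) - th
    near = np.abs(x) < 1e-6
    xs = np.where(near, 1.0, x)
    out = a * xs / (1.0 - np.exp(-xs / c))
    return np.where(near, a * (c + 0.5 * x), out)


def _linexp_neg(v, a, th, c):
    # a*(V-th) / (exp((V-th)/c) - 1);  limit a*c at V = th
    x = np.asarray(v, dtype=float) - th
    near = np.abs(x) < 1e-6
    xs = np.where(near, 1.0, x)
    out = a * xs / (np.exp(xs / c) - 1.0)
    return np.where(near, a * (c - 0.5 * x), out)


def alpha_n(v):
    return _linexp_pos(v, 0.032, -50.0, 5.0)


def alpha_m(v):
    return _linexp_pos(v, 0.32, -52.0, 4.0)


def alpha_h(v):
    v = np.asarray(v, dtype=float)
    return 0.128 * np.exp(-(v + 48.0) / 18.0)


def beta_n(v):
    v = np.asarray(v, dtype=float)
    return 0.5 * np.exp(-(v + 55.0) / 40.0)


def beta_m(v):
    return _linexp_neg(v, 0.28, -25.0, 5.0)


def beta_h(v):
    v = np.asarray(v, dtype=float)
    return 4.0 / (np.exp(-(v + 25.0) / 5.0) + 1.0)


_RATES = {
    "n_alpha": alpha_n, "m_alpha": alpha_m, "h_alpha": alpha_h,
    "n_beta": beta_n, "m_beta": beta_m, "h_beta": beta_h,
}


def gating_rate(gate: str, v):
    """Rate constant (ms^-1) of one gate at voltage v (mV)."""
    if gate not in _RATES:
        raise KeyError(f"unknown gate rate {gate!r}")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("V must be finite")
    out = _RATES[gate](v)
    return float(out) if out.ndim == 0 else out


def steady_state(gate: str, v):
    """Equilibrium open probability x_inf = alpha/(alpha+beta)."""
    if gate not in ("m", "h", "n"):
        raise KeyError(f"unknown gate {gate!r}")
    a = gating_rate(f"{gate}_alpha", v)
    b = gating_rate(f"{gate}_beta", v)
    tot = a + b
    if np.any(np.asarray(tot) == 0.0):
        raise ZeroDivisionError("degenerate rates: alpha + beta = 0")
    return a / tot


def steady_gating(v) -> GatingState:
    return GatingState(m=float(steady_state("m", v)),
                       h=float(steady_state("h", v)),
                       n=float(steady_state("n", v)))


def ionic_currents(v, gating, params: ModelParams):
    """The three ionic current densities (INa, IK, IL) in uA cm^-2.

    Positive values depolarize.  With ``gating`` at steady state this
    is the voltage-clamp current decomposition of the model.
    """
    m, h, n = gating.m, gating.h, gating.n
    ina = params.gNa_bar * m ** 3 * h * (params.ENa - v)
    ik = params.gK_eff * n ** 4 * (params.EK - v)
    il = params.gL * (params.EL - v)
    return ina, ik, il


def _current_balance(v, iex, params: ModelParams) -> float:
    """Total membrane current with gates at steady state (= C dV/dt)."""
    g = steady_gating(v)
    ina, ik, il = ionic_currents(v, g, params)
    return ina + ik + il + iex


def integrate_deterministic(state0: DeterministicState, iex: float,
                            t_ms: float, dt: float = 0.01,
                            params: ModelParams = ModelParams()):
    """RK4 trajectory of the deterministic model.

    Returns a dict of arrays {t, V, m, h, n} (ms / mV).  Raises on
    numerical blow-up, naming the offending step.
    """
    if dt <= 0 or t_ms <= 0:
        raise ValueError("dt and T must be positive")
    g = state0.gating
    tv, vv, mv, hv, nv = _k.rk4_deterministic(
        state0.V, g.m, g.h, g.n, iex, t_ms, dt,
        params.gNa_bar, params.gK_eff, params.gL,
        params.ENa, params.EK, params.EL, params.C)
    if not np.all(np.isfinite(vv)):
        step = int(np.argmax(~np.isfinite(vv)))
        raise FloatingPointError(
            f"integration blew up (non-finite V) at step {step}")
    return {"t": tv, "V": vv, "m": mv, "h": hv, "n": nv}


def find_fixed_point(iex: float, params: ModelParams = ModelParams(),
                     v_lo: float = -95.0, v_hi: float = -30.0) -> float:
    """Stable resting potential Vr(Iex) of the deterministic model.

    Finds the most hyperpolarized root of the steady-state current
    balance with negative slope (stability) by bracketing + brentq,
    refined until |F(Vr)| < 1e-10.
    """
    f = lambda v: _current_balance(v, iex, params)
    grid = np.linspace(v_lo, v_hi, 400)
    fg = np.array([f(v) for v in grid])
    for i in range(len(grid) - 1):
        if fg[i] > 0.0 >= fg[i + 1]:  # downward crossing => stable
            root = brentq(f, grid[i], grid[i + 1], xtol=1e-13)
            if abs(f(root)) < 1e-10:
                return float(root)
    raise ValueError(
        f"no stable fixed point in [{v_lo}, {v_hi}] for Iex={iex} "
        "(above the spiking bifurcation?)")


@dataclass
class BifurcationResult:
    """Saddle-node (rheobase) summary of the deterministic model."""
    Ic: float                      # critical current density, uA cm^-2
    Vc: float                      # membrane potential at the bifurcation, mV
    iex_grid: np.ndarray = field(repr=False)
    vr_grid: np.ndarray = field(repr=False)

    def Vr(self, iex):
        """Resting potential on the subthreshold branch (interpolated)."""
        return np.interp(iex, self.iex_grid, self.vr_grid)


def _spikes_repetitively(iex: float, params: ModelParams,
                         t_ms: float = 600.0, transient_ms: float = 100.0,
                         dt: float = 0.01) -> bool:
    """True if the deterministic model fires repetitively at this Iex.

    Criterion: at least two upward crossings of 0 mV inside a 500 ms
    window after a 100 ms transient, starting from a subthreshold state.
    """
    v0 = -63.0
    st = DeterministicState(V=v0, gating=steady_gating(v0))
    tr = integrate_deterministic(st, iex, t_ms, dt=dt, params=params)
    v = tr["V"][tr["t"] >= transient_ms]
    up = np.flatnonzero((v[:-1] < 0.0) & (v[1:] >= 0.0))
    return up.size >= 2


def find_bifurcation(params: ModelParams = ModelParams(),
                     i_lo: float = 0.0, i_hi: float = 2.0,
                     tol: float = 1e-4, n_vr: int = 25) -> BifurcationResult:
    """Locate the spiking bifurcation (Ic, Vc) by bisection on Iex.

    The lower bracket must admit a stable fixed point and no repetitive
    firing; the upper must fire repetitively.  Vc is the resting
    potential at the last subcritical current.
    """
    try:
        find_fixed_point(i_lo, params)
        lo_ok = not _spikes_repetitively(i_lo, params)
    except ValueError:
        lo_ok = False
    if not lo_ok or not _spikes_repetitively(i_hi, params):
        raise ValueError("invalid bisection bracket for the rheobase search")
    lo, hi = i_lo, i_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        try:
            find_fixed_point(mid, params)
            stable = not _spikes_repetitively(mid, params)
        except ValueError:
            stable = False
        if stable:
            lo = mid
        else:
            hi = mid
    ic = 0.5 * (lo + hi)
    iex_grid = np.linspace(min(i_lo, -0.2), lo, n_vr)
    vr_grid = np.array([find_fixed_point(i, params) for i in iex_grid])
    vc = float(vr_grid[-1])
    return BifurcationResult(Ic=float(ic), Vc=vc,
                             iex_grid=iex_grid, vr_grid=vr_grid)
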