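"""Single-channel Markov state machinery.

Each Na+ channel carries three independent activation gates (m) and one
inactivation gate (h), each K+ channel four activation gates (n); a
channel conducts only with all gates open (states m3h1 and n4).  Channels
are not tracked individually -- only the occupancy of the 13 aggregate
states (8 Na+, 5 K+) evolves, through 28 possible one-gate transitions
whose rates are the single-gate rate constants times the number of gates
able to move (e.g. 3*alpha_m for m0 -> m1, 4*beta_n for n4 -> n3).

State indexing used throughout: Na state (i open m-gates, j open h-gates)
sits at index ``4*j + i`` (0..7, conducting state 7), K state n_k at
``8 + k`` (8..12, conducting state 12).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hh import ModelParams, steady_state, gating_rate

__all__ = [
    "NA_STATE_NAMES", "K_STATE_NAMES",
    "ChannelStateCounts", "TransitionTable", "PropensityVector",
    "build_transition_table", "propensities", "sample_dwell",
    "select_transition", "apply_transition", "initial_counts",
]

# rate-kind codes shared with the compiled kernel
RATE_AN, RATE_AM, RATE_AH, RATE_BN, RATE_BM, RATE_BH = range(6)
_RATE_NAMES = ("n_alpha", "m_alpha", "h_alpha", "n_beta", "m_beta", "h_beta")

NA_STATE_NAMES = tuple(f"m{i}h{j}" for j in (0, 1) for i in range(4))
K_STATE_NAMES = tuple(f"n{k}" for k in range(5))
STATE_NAMES = NA_STATE_NAMES + K_STATE_NAMES
NA_OPEN, K_OPEN = 7, 12


def _na_idx(i: int, j: int) -> int:
    return 4 * j + i


@dataclass
class ChannelStateCounts:
    """Occupancy of the 8 Na+ and 5 K+ aggregate states."""
    na: np.ndarray  # shape (8,), int
    k: np.ndarray   # shape (5,), int

    def __post_init__(self):
        self.na = np.asarray(self.na, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        if self.na.shape != (8,) or self.k.shape != (5,):
            raise ValueError("expected 8 Na and 5 K state counts")
        if (self.na < 0).any() or (self.k < 0).any():
            raise ValueError("negative channel count")

    @property
    def n_na(self) -> int:
        return int(self.na.sum())

    @property
    def n_k(self) -> int:
        return int(self.k.sum())

    @property
    def open_na(self) -> int:
        return int(self.na[7])          # m3h1

    @property
    def open_k(self) -> int:
        return int(self.k[4])           # n4

    def as_vector(self) -> np.ndarray:
        """Length-13 vector in kernel order."""
        return np.concatenate([self.na, self.k])

    @classmethod
    def from_vector(cls, vec) -> "ChannelStateCounts":
        vec = np.asarray(vec)
        return cls(na=vec[:8].copy(), k=vec[8:].copy())

    def copy(self) -> "ChannelStateCounts":
        return ChannelStateCounts(self.na.copy(), self.k.copy())


@dataclass(frozen=True)
class TransitionTable:
    """The one-gate transition scheme in a fixed canonical order.

    Order: Na m-moves on the h0 row (3 forward, 3 backward), the same on
    the h1 row, the 8 h-moves (4 up, 4 down), then the K moves (4
    forward, 4 backward).  28 entries with K+ present, 20 when blocked.
    """
    parent: np.ndarray
    child: np.ndarray
    kind: np.ndarray    # index into (an, am, ah, bn, bm, bh)
    mult: np.ndarray    # combinatorial gate multiplicity
    blocked_K: bool = False
    names: tuple = field(default=(), compare=False)

    def __len__(self):
        return len(self.parent)

    def rate(self, mu: int, v: float) -> float:
        """Full propensity factor rate(V)*multiplicity of entry mu."""
        return float(self.mult[mu]) * float(
            gating_rate(_RATE_NAMES[self.kind[mu]], v))


def build_transition_table(blocked_K: bool = False) -> TransitionTable:
    rows = []  # (parent, child, kind, mult)
    for j in (0, 1):
        for i in range(3):      # m forward: (3-i) * alpha_m
            rows.append((_na_idx(i, j), _na_idx(i + 1, j), RATE_AM, 3 - i))
        for i in range(1, 4):   # m backward: i * beta_m
            rows.append((_na_idx(i, j), _na_idx(i - 1, j), RATE_BM, i))
    for i in range(4):          # h opening
        rows.append((_na_idx(i, 0), _na_idx(i, 1), RATE_AH, 1))
    for i in range(4):          # h closing
        rows.append((_na_idx(i, 1), _na_idx(i, 0), RATE_BH, 1))
    if not blocked_K:
        for k in range(4):      # n forward: (4-k) * alpha_n
            rows.append((8 + k, 8 + k + 1, RATE_AN, 4 - k))
        for k in range(1, 5):   # n backward: k * beta_n
            rows.append((8 + k, 8 + k - 1, RATE_BN, k))
    parent, child, kind, mult = (np.array(c, dtype=np.int64)
                                 for c in zip(*rows))
    names = tuple(f"{STATE_NAMES[p]}->{STATE_NAMES[c]}"
                  for p, c in zip(parent, child))
    return TransitionTable(parent=parent, child=child, kind=kind, mult=mult,
                           blocked_K=blocked_K, names=names)


@dataclass
class PropensityVector:
    psi: np.ndarray   # per-transition event rates, ms^-1
    lam: float        # total rate

    def __post_init__(self):
        if (self.psi < 0).any():
            raise ValueError("negative propensity")


def propensities(counts: ChannelStateCounts, v: float,
                 table: TransitionTable) -> PropensityVector:
    """Per-transition rates psi_mu = N_parent * multiplicity * rate(V)."""
    vec = counts.as_vector()
    if (vec < 0).any():
        raise ValueError("corrupted state: negative count")
    rates = np.array([gating_rate(nm, v) for nm in _RATE_NAMES])
    psi = vec[table.parent] * table.mult * rates[table.kind]
    return PropensityVector(psi=psi, lam=float(psi.sum()))


def sample_dwell(lam: float, rng: np.random.Generator) -> float:
    """Exponential dwell time ttr = ln(1/r1)/lam, r1 ~ U(0,1]."""
    if lam <= 0:
        raise ValueError("frozen system: total rate is not positive")
    r1 = 1.0 - rng.random()   # (0, 1]
    return float(-np.log(r1) / lam)


def select_transition(psi: PropensityVector, rng=None, r2=None) -> int:
    """Index mu of the transition that fired.

    mu is the unique index with cumsum(psi)[mu-1] < r2 <= cumsum(psi)[mu]
    for r2 ~ U(0, lam] (right-inclusive); empirical selection frequencies
    converge to psi_mu / lam.
    """
    lam = psi.lam
    if lam <= 0:
        raise ValueError("frozen system: total rate is not positive")
    if r2 is None:
        r2 = (1.0 - rng.random()) * lam
    if not 0.0 <= r2 <= lam * (1 + 1e-12):
        raise ValueError("r2 outside [0, lam]")
    cum = np.cumsum(psi.psi)
    mu = int(np.searchsorted(cum, r2, side="left"))
    return min(mu, len(cum) - 1)


def apply_transition(counts: ChannelStateCounts, mu: int,
                     table: TransitionTable) -> ChannelStateCounts:
    """Move one channel along transition mu (returns a new counts object)."""
    vec = counts.as_vector()
    p, c = table.parent[mu], table.child[mu]
    if vec[p] < 1:
        raise RuntimeError(
            f"impossible event: transition {table.names[mu]} from an empty "
            "parent state (propensity bookkeeping bug)")
    vec[p] -= 1
    vec[c] += 1
    return ChannelStateCounts.from_vector(vec)


def equilibrium_probs(v0: float):
    """Binomial-product state probabilities at clamped voltage v0.

    Gates are independent at fixed V, so Na states follow
    Binom(3, m_inf) x Bern(h_inf) and K states Binom(4, n_inf).
    """
    from scipy.stats import binom
    m, h, n = (steady_state(x, v0) for x in ("m", "h", "n"))
    pm = binom.pmf(np.arange(4), 3, m)
    p_na = np.concatenate([pm * (1 - h), pm * h])
    p_k = binom.pmf(np.arange(5), 4, n)
    return p_na, p_k


def initial_counts(v0: float, params: ModelParams,
                   rng: np.random.Generator) -> ChannelStateCounts:
    """Assign each channel independently to its equilibrium state at v0."""
    p_na, p_k = equilibrium_probs(v0)
    na = np.bincount(rng.choice(8, size=params.n_na, p=p_na), minlength=8)
    if params.n_k > 0:
        k = np.bincount(rng.choice(5, size=params.n_k, p=p_k), minlength=5)
    else:
        k = np.zeros(5, dtype=np.int64)
    return ChannelStateCounts(na=na, k=k)
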