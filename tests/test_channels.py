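"""Markov channel machinery: transition table, propensities, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hhcrit as hc
from hhcrit.channels import (NA_OPEN, K_OPEN, STATE_NAMES,
                             ChannelStateCounts, equilibrium_probs)
from hhcrit.hh import ModelParams


@pytest.fixture(scope="module")
def table():
    return hc.build_transition_table()


@pytest.fixture(scope="module")
def table_blocked():
    return hc.build_transition_table(blocked_K=True)


class TestTransitionTable:
    def test_counts(self, table, table_blocked):
        assert len(table) == 28           # 20 Na + 8 K
        assert len(table_blocked) == 20

    def test_every_state_has_an_exit(self, table):
        assert set(table.parent) == set(range(13))

    def test_single_gate_moves(self, table):
        # parent and child differ in exactly one gate index by one
        for p, c in zip(table.parent, table.child):
            if p < 8:    # Na state (i, j) at 4j + i
                pi, pj, ci, cj = p % 4, p // 4, c % 4, c // 4
                assert abs(pi - ci) + abs(pj - cj) == 1
            else:
                assert abs(p - c) == 1 and c >= 8

    def test_scheme_multiplicities(self, table):
        named = dict(zip(table.names, table.mult))
        assert named["m0h0->m1h0"] == 3 and named["m2h0->m3h0"] == 1
        assert named["m3h1->m2h1"] == 3 and named["m1h0->m0h0"] == 1
        assert named["n0->n1"] == 4 and named["n4->n3"] == 4
        assert named["m0h0->m0h1"] == 1 and named["m0h1->m0h0"] == 1

    def test_deterministic_order(self, table):
        assert table.names == hc.build_transition_table().names


def _counts(na=None, k=None):
    return ChannelStateCounts(na=na if na is not None else np.zeros(8, int),
                              k=k if k is not None else np.zeros(5, int))


class TestPropensities:
    def test_all_closed_has_three_exits(self, table):
        na = np.zeros(8, int); na[0] = 1800
        k = np.zeros(5, int); k[0] = 540
        psi = hc.propensities(_counts(na, k), -63.0, table)
        assert np.count_nonzero(psi.psi) == 3

    def test_single_channel_value(self, table):
        na = np.zeros(8, int); na[0] = 1
        psi = hc.propensities(_counts(na=na), -63.0, table)
        # m0h0 -> m1h0 at 3*alpha_m(-63) ~ 0.721 ms^-1
        i = table.names.index("m0h0->m1h0")
        assert psi.psi[i] == pytest.approx(0.7213, abs=2e-3)

    def test_linearity_in_counts(self, table, rng):
        na = rng.integers(0, 100, 8)
        k = rng.integers(0, 100, 5)
        p1 = hc.propensities(_counts(na, k), -60.0, table)
        p2 = hc.propensities(_counts(2 * na, 2 * k), -60.0, table)
        assert p2.lam == pytest.approx(2 * p1.lam, rel=1e-12)

    def test_two_bookkeepings_agree(self, table, rng):
        # per-transition sum vs per-state (count x escape-rate) sum
        na = rng.integers(0, 50, 8)
        k = rng.integers(0, 50, 5)
        v = -58.0
        lam = hc.propensities(_counts(na, k), v, table).lam
        per_state = 0.0
        vec = np.concatenate([na, k])
        for s in range(13):
            esc = sum(table.rate(mu, v)
                      for mu in range(len(table)) if table.parent[mu] == s)
            per_state += vec[s] * esc
        assert lam == pytest.approx(per_state, rel=1e-12)


class TestSampling:
    def test_dwell_closed_form(self):
        class R:     # rng stub: rng.random() -> 1 - r1
            def __init__(self, r1): self.r1 = r1
            def random(self): return 1.0 - self.r1
        assert hc.sample_dwell(1.0, R(np.exp(-1.0))) == pytest.approx(1.0)
        assert hc.sample_dwell(5.0, R(1.0)) == 0.0

    def test_dwell_mean(self, rng):
        lam = 2.0
        t = np.array([hc.sample_dwell(lam, rng) for _ in range(100_000)])
        se = 1 / lam / np.sqrt(t.size)
        assert abs(t.mean() - 1 / lam) < 3 * se

    def test_dwell_requires_positive_rate(self, rng):
        with pytest.raises(ValueError):
            hc.sample_dwell(0.0, rng)

    def test_select_boundary_inclusive(self):
        psi = hc.PropensityVector(psi=np.array([1.0, 1.0]), lam=2.0)
        assert hc.select_transition(psi, r2=1.0) == 0
        assert hc.select_transition(psi, r2=1.0 + 1e-12) == 1

    def test_select_single_channel(self):
        psi = np.zeros(28); psi[5] = 0.7
        pv = hc.PropensityVector(psi=psi, lam=0.7)
        assert hc.select_transition(pv, r2=0.3) == 5

    def test_select_frequencies(self, rng):
        pv = hc.PropensityVector(psi=np.array([1.0, 3.0]), lam=4.0)
        picks = np.array([hc.select_transition(pv, rng=rng)
                          for _ in range(100_000)])
        f2 = np.mean(picks == 1)
        se = np.sqrt(0.75 * 0.25 / picks.size)
        assert abs(f2 - 0.75) < 3 * se

    def test_select_rejects_out_of_range(self):
        pv = hc.PropensityVector(psi=np.array([1.0]), lam=1.0)
        with pytest.raises(ValueError):
            hc.select_transition(pv, r2=1.5)


class TestApply:
    def test_move_and_reverse(self, table):
        na = np.zeros(8, int); na[0] = 5
        c0 = _counts(na=na, k=np.array([540, 0, 0, 0, 0]))
        i = table.names.index("m0h0->m1h0")
        c1 = hc.apply_transition(c0, i, table)
        assert c1.na[0] == 4 and c1.na[1] == 1
        j = table.names.index("m1h0->m0h0")
        c2 = hc.apply_transition(c1, j, table)
        assert np.array_equal(c2.as_vector(), c0.as_vector())

    def test_empty_parent_is_an_error(self, table):
        c = _counts(na=np.array([0, 1, 0, 0, 0, 0, 0, 0]),
                    k=np.array([1, 0, 0, 0, 0]))
        with pytest.raises(RuntimeError):
            hc.apply_transition(c, table.names.index("m0h0->m1h0"), table)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 20))
    def test_conservation_random_walk(self, table, seed):
        rng = np.random.default_rng(seed)
        c = hc.initial_counts(-63.0, ModelParams(), rng)
        n_na, n_k = c.n_na, c.n_k
        for _ in range(200):
            psi = hc.propensities(c, -60.0, table)
            mu = hc.select_transition(psi, rng=rng)
            c = hc.apply_transition(c, mu, table)
            assert c.n_na == n_na and c.n_k == n_k


class TestInitialCounts:
    def test_totals_from_densities(self, rng):
        p = ModelParams()
        c = hc.initial_counts(-63.0, p, rng)
        assert c.n_na == 1800 and c.n_k == 540

    def test_hyperpolarized_limit(self, rng):
        c = hc.initial_counts(-150.0, ModelParams(), rng)
        # m_inf ~ 0, h_inf ~ 1, n_inf ~ 0: mass in m0h1 and n0
        assert c.na[4] > 0.98 * 1800       # m0h1
        assert c.k[0] > 0.97 * 540         # n0

    def test_open_fraction_expectation(self, rng):
        v0 = -40.0
        p = ModelParams()
        expect = (hc.steady_state("m", v0) ** 3 * hc.steady_state("h", v0))
        draws = [hc.initial_counts(v0, p, rng).open_na
                 for _ in range(2000)]
        mean = np.mean(draws) / p.n_na
        se = np.sqrt(expect * (1 - expect) / (p.n_na * len(draws)))
        assert abs(mean - expect) < 4 * se


def test_clamped_voltage_occupancy_matches_binomial_product(table, rng):
    """Long-run state occupancy at fixed V equals the product of the
    independent-gate equilibria (detailed balance of the scheme)."""
    v = -60.0
    p = ModelParams(A=2.0)  # 120 Na / 36 K channels: fast mixing
    c = hc.initial_counts(v, p, rng)
    occ = np.zeros(13)
    t_tot = 0.0
    for _ in range(60_000):
        psi = hc.propensities(c, v, table)
        dt = hc.sample_dwell(psi.lam, rng)
        occ += c.as_vector() * dt
        t_tot += dt
        c = hc.apply_transition(c, hc.select_transition(psi, rng=rng), table)
    occ /= t_tot
    p_na, p_k = equilibrium_probs(v)
    exp = np.concatenate([p_na * p.n_na, p_k * p.n_k])
    # 3 Monte-Carlo sigmas using binomial per-state scatter + correlation fudge
    for s in range(13):
        n_tot = p.n_na if s < 8 else p.n_k
        pr = exp[s] / n_tot
        sd = np.sqrt(n_tot * pr * (1 - pr))
        assert abs(occ[s] - exp[s]) < max(3.5 * sd, 1.0), STATE_NAMES[s]
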