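"""Unit and property tests of the generic delayed-SSA engine."""

import numpy as np
import pytest
from scipy import stats

from txpause.delayed_ssa import (EXHAUSTED, ConfigurationError,
                                 DelayDistribution, DelayedReaction, SimState,
                                 draw_delay, simulate, step)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


class TestDrawDelay:
    def test_point_mass_is_exact(self, rng):
        dist = DelayDistribution.point(5.0)
        assert all(draw_delay(dist, rng) == 5.0 for _ in range(100))

    def test_exponential_mean_47(self, rng):
        # his-pause duration: exponential with mean 47 s
        draws = np.array([draw_delay(DelayDistribution.exponential(47.0), rng)
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(47.0, abs=0.5)

    def test_truncated_normal_mean_and_support(self, rng):
        # open-complex delay: N(40, 4^2), kept non-negative by resampling
        dist = DelayDistribution.normal(40.0, 4.0)
        draws = np.array([draw_delay(dist, rng) for _ in range(100_000)])
        assert draws.min() >= 0.0
        assert draws.mean() == pytest.approx(40.0, abs=0.05)

    @pytest.mark.parametrize("kind,params", [
        ("point", (-1.0,)),
        ("normal", (40.0, -1.0)),
        ("gamma", (1.0,)),
    ])
    def test_invalid_parameters_rejected(self, kind, params):
        with pytest.raises(ConfigurationError):
            DelayDistribution(kind, params)


class TestStep:
    def test_delayed_product_released_at_fire_time_plus_tau(self, rng):
        # A -> B + C(tau=5): B appears at the firing time, C exactly 5 s later
        rxn = DelayedReaction("r", reactants={"A": 1}, products={"B": 1},
                              delayed_products=[("C", 1, DelayDistribution.point(5.0))],
                              rate=1.0)
        state = SimState({"A": 1, "B": 0, "C": 0}, rng=rng)
        assert step(state, [rxn]) is None
        t_fire = state.time
        assert state.counts == {"A": 0, "B": 1, "C": 0}
        assert step(state, [rxn]) is None  # the release
        assert state.time == pytest.approx(t_fire + 5.0)
        assert state.counts["C"] == 1

    def test_exhausted_leaves_state_unchanged(self, rng):
        rxn = DelayedReaction("r", reactants={"A": 1}, rate=1.0)
        state = SimState({"A": 0}, rng=rng)
        before = dict(state.counts)
        assert step(state, [rxn]) == EXHAUSTED
        assert state.counts == before and state.time == 0.0

    def test_pure_decay_matches_exponential_oracle(self):
        # X -> 0 at rate d: E[X(t)] = n0 * exp(-d t)
        n0, d, t_probe = 30, 0.7, 1.0
        rxn = DelayedReaction("decay", reactants={"X": 1}, rate=d)
        survivors = [simulate([rxn], {"X": n0}, t_end=t_probe,
                              sample_interval=t_probe, seed=s).column("X")[-1]
                     for s in range(4_000)]
        mean = np.mean(survivors)
        expected = n0 * np.exp(-d * t_probe)
        se = np.std(survivors, ddof=1) / np.sqrt(len(survivors))
        assert abs(mean - expected) < 3 * se


class TestSimulate:
    def test_sample_grid_arithmetic(self, rng):
        traj = simulate([], {"A": 2}, t_end=10.0, sample_interval=1.0)
        assert traj.times.shape == (11,)
        assert (traj.column("A") == 2).all()

    def test_deterministic_under_seed(self):
        rxns = [DelayedReaction("b", products={"X": 1}, rate=2.0),
                DelayedReaction("d", reactants={"X": 1}, rate=0.5)]
        t1 = simulate(rxns, {"X": 0}, 200.0, seed=7)
        t2 = simulate(rxns, {"X": 0}, 200.0, seed=7)
        assert (t1.counts == t2.counts).all()

    def test_counts_never_negative(self):
        rxns = [DelayedReaction("b", products={"X": 1}, rate=5.0),
                DelayedReaction("d", reactants={"X": 2}, rate=1.0)]
        traj = simulate(rxns, {"X": 0}, 300.0, seed=3)
        assert (traj.counts >= 0).all()

    def test_birth_death_stationary_mean(self):
        # constant birth k, per-capita death d: stationary mean k/d
        k, d = 2.0, 0.1
        rxns = [DelayedReaction("b", products={"X": 1}, rate=k),
                DelayedReaction("d", reactants={"X": 1}, rate=d)]
        means = []
        for s in range(20):
            traj = simulate(rxns, {"X": 0}, 2_000.0, seed=s)
            means.append(traj.column("X")[500:].mean())
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - k / d) < 3 * se

    def test_delayed_release_conservation(self):
        # every enqueued delayed product is released, none early
        tau = 10.0
        rxns = [DelayedReaction(
            "make", products={}, rate=1.0,
            delayed_products=[("C", 1, DelayDistribution.point(tau))])]
        traj = simulate(rxns, {"C": 0}, 100.0, seed=11, observables=["C"])
        c = traj.column("C")
        assert c[int(tau) - 1] == 0  # nothing before the first possible release
        assert (np.diff(c) >= 0).all()

    def test_matches_reference_direct_ssa_distribution(self):
        """Delay-free event statistics agree with an independent direct-method
        SSA on a 3-species toy network (KS test at alpha = 0.01)."""
        # network: A + B -> C (k1), C -> A (k2); record time of 5th firing
        k1, k2 = 0.3, 1.0

        def reference_final_counts(seed):
            # independent, hand-rolled direct SSA
            rng = np.random.default_rng(seed)
            a, b, c = 10, 8, 0
            t = 0.0
            while t < 5.0:
                p1 = k1 * a * b
                p2 = k2 * c
                tot = p1 + p2
                if tot == 0:
                    break
                t += rng.exponential(1 / tot)
                if t >= 5.0:
                    break
                if rng.random() * tot < p1:
                    a, b, c = a - 1, b - 1, c + 1
                else:
                    a, b, c = a + 1, b, c - 1
            return c

        rxns = [DelayedReaction("f", reactants={"A": 1, "B": 1},
                                products={"C": 1}, rate=k1),
                DelayedReaction("r", reactants={"C": 1}, products={"A": 1},
                                rate=k2)]
        ours = [simulate(rxns, {"A": 10, "B": 8, "C": 0}, 5.0,
                         sample_interval=5.0, seed=s).column("C")[-1]
                for s in range(2_000)]
        theirs = [reference_final_counts(10_000 + s) for s in range(2_000)]
        assert stats.ks_2samp(ours, theirs).pvalue > 0.01


def test_trajectory_tsv_roundtrip(tmp_path):
    rxns = [DelayedReaction("b", products={"X": 1}, rate=1.0)]
    traj = simulate(rxns, {"X": 0}, 20.0, seed=5)
    path = tmp_path / "traj.tsv"
    traj.write_tsv(path, {"model": "demo"})
    lines = path.read_text().splitlines()
    assert lines[0] == "time\tX"
    assert len(lines) == 22
    import json
    meta = json.loads(path.with_suffix(".tsv.json").read_text())
    assert meta["seed"] == 5 and "config_hash" in meta


def test_mass_action_falling_factorial():
    rxn = DelayedReaction("dimer", reactants={"X": 2}, rate=0.5)
    state = SimState({"X": 4})
    assert rxn.propensity(state) == pytest.approx(0.5 * 4 * 3)
    state.counts["X"] = 1
    assert rxn.propensity(state) == 0.0
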