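"""Model construction: rates, codon sequences, reaction network semantics."""

import numpy as np
import pytest
from scipy import stats

from txpause.delayed_ssa import (ConfigurationError, DelayedReaction, SimState,
                                 simulate, step)
from txpause.expression_model import (ModelParameters, PauseSite,
                                      build_reaction_system, codon_class_map,
                                      full_system, generate_codon_sequence,
                                      load_codon_table, make_gene_template,
                                      make_model, pause_rate,
                                      simulate_pause_entry)


class TestPauseRate:
    @pytest.mark.parametrize("ka,eff,expected", [
        (150.0, 0.8, 600.0),
        (150.0, 0.5, 150.0),
        (30.0, 0.8, 120.0),
        (999.0, 0.0, 0.0),
    ])
    def test_values(self, ka, eff, expected):
        assert pause_rate(ka, eff) == pytest.approx(expected)

    def test_competition_recovers_efficiency(self):
        for eff in (0.1, 0.5, 0.8, 0.95):
            k = pause_rate(150.0, eff)
            assert k / (k + 150.0) == pytest.approx(eff)

    def test_efficiency_one_rejected(self):
        with pytest.raises(ConfigurationError):
            pause_rate(150.0, 1.0)


class TestCodonSequences:
    def test_degenerate_table(self):
        seq = generate_codon_sequence(5, {"AAA": 1.0},
                                      np.random.default_rng(0))
        assert seq == ("AAA",) * 5

    def test_empty_sequence(self):
        assert generate_codon_sequence(0, {"AAA": 1.0},
                                       np.random.default_rng(0)) == ()

    def test_frequencies_match_table(self):
        table = load_codon_table()
        rng = np.random.default_rng(1)
        seq = generate_codon_sequence(100_000, table, rng)
        codons = sorted(table)
        counts = np.array([seq.count(c) for c in codons])
        expected = np.array([table[c] for c in codons])
        expected = expected / expected.sum() * len(seq)
        assert stats.chisquare(counts, expected).pvalue > 0.001

    def test_all_zero_frequencies_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_codon_sequence(3, {"AAA": 0.0}, np.random.default_rng(0))

    def test_class_map_covers_table_by_abundance(self):
        table = load_codon_table()
        cmap = codon_class_map(table)
        assert set(cmap) == set(table)
        # the most abundant codon is fast, the rarest slow
        top = max(table, key=table.get)
        bottom = min(table, key=table.get)
        assert cmap[top] == "A" and cmap[bottom] == "C"


class TestMakeModel:
    def test_standard_models(self):
        rng = np.random.default_rng(0)
        tpl_a, _ = make_model("A", rng=rng)
        assert tpl_a.pause_sites == ()
        tpl_b, _ = make_model("B", rng=rng)
        (site,) = tpl_b.pause_sites
        assert (site.position, site.efficiency, site.mean_duration) == \
            (500, 0.8, 47.0)
        tpl_c, _ = make_model("C", rng=rng)
        assert tpl_c.pause_sites[0].position == 250
        tpl_d, _ = make_model("D", rng=rng)
        assert tpl_d.pause_sites[0].position == 750
        tpl_e, _ = make_model("E", rng=rng)
        assert tpl_e.pause_sites[0].mean_duration == 23.5
        tpl_f, _ = make_model("F", rng=rng)
        assert tpl_f.pause_sites[0].mean_duration == 94.0

    def test_unknown_label(self):
        with pytest.raises(ConfigurationError):
            make_model("G")

    def test_gene_of_1000_nt_translates_333_codons(self):
        tpl, _ = make_model("A", rng=np.random.default_rng(0))
        assert tpl.length == 1000 and tpl.n_codons == 333

    def test_pause_site_outside_template_rejected(self):
        with pytest.raises(ConfigurationError):
            make_gene_template(length=100, pause_sites=(PauseSite(101),),
                               rng=np.random.default_rng(0))

    def test_pause_rate_arrays_substitute_site(self):
        tpl, params = make_model("B", rng=np.random.default_rng(0))
        kp = tpl.pause_entry_rates(params)
        krel = tpl.pause_release_rates(params)
        assert kp[499] == pytest.approx(0.55)
        assert kp[500] == pytest.approx(600.0)
        assert krel[500] == pytest.approx(1 / 47.0)
        assert krel[501] == pytest.approx(1 / 3.0)


class TestPauseEntry:
    def test_default_site_pauses_eighty_percent(self):
        site = PauseSite(500)
        frac = simulate_pause_entry(ModelParameters(), site, 10_000,
                                    np.random.default_rng(2))
        assert frac == pytest.approx(0.8, abs=0.015)

    def test_half_efficiency_site(self):
        site = PauseSite(500, efficiency=0.5)
        frac = simulate_pause_entry(ModelParameters(), site, 10_000,
                                    np.random.default_rng(3))
        assert frac == pytest.approx(0.5, abs=0.02)


def _quiet_params(**kw):
    """Parameters with all elongation side-channels off (pure stepping)."""
    defaults = dict(k_p=0.0, k_ar=0.0, k_ed=0.0, k_pre=0.0, k_pyr=0.0,
                    k_tt=0.0, n_rnap=1, n_rib=1, k_tl=0.0)
    defaults.update(kw)
    return ModelParameters(**defaults)


class TestReactionSystem:
    def test_single_elongating_rnap_occupies_25_positions(self):
        """Run the object-level network until the lone RNAP is mid-template,
        then count unavailable template positions."""
        L = 100
        params = _quiet_params(k_tc=50.0)
        tpl = make_gene_template(length=L, rng=np.random.default_rng(0))
        reactions, initial = build_reaction_system(tpl, params,
                                                   translation=False)
        state = SimState(dict(initial), rng=np.random.default_rng(8))
        live = list(reactions)
        mid = range(40, 60)
        for _ in range(100_000):
            step(state, live)
            if any(state.counts.get(f"O{n}", 0) or state.counts.get(f"A{n}", 0)
                   for n in mid):
                break
        else:  # pragma: no cover
            pytest.fail("RNAP never reached mid-template")
        unavailable = sum(1 for n in range(1, L + 1)
                          if state.counts.get(f"U{n}", 0) == 0)
        assert unavailable == 25

    def test_transit_time_matches_stage_sum_oracle(self):
        """Mean promoter-clearance-to-termination time equals the sum of
        exponential stage means in the no-pause, no-arrest limit."""
        L = 60
        params = _quiet_params(k_tc=1e6)
        tpl = make_gene_template(length=L, rng=np.random.default_rng(0))
        expected = (sum(1 / params.k_a(n) for n in range(1, L + 1))
                    + (L - 1) / params.k_m + 1 / params.k_f)
        durations = []
        for s in range(200):
            reactions, initial = build_reaction_system(tpl, params,
                                                       translation=False)
            state = SimState(dict(initial), rng=np.random.default_rng(s))
            live = list(reactions)
            t_clear = None
            for _ in range(10_000):
                step(state, live)
                if t_clear is None and state.counts.get("O1", 0):
                    t_clear = state.time
                if state.counts.get("mRNA", 0):
                    durations.append(state.time - t_clear)
                    break
        mean = np.mean(durations)
        se = np.std(durations, ddof=1) / np.sqrt(len(durations))
        assert abs(mean - expected) < 3 * se

    def test_mrna_lifetime_is_40_seconds(self):
        """Constant production k plus first-order degradation k_dr = 0.025:
        stationary mean k / k_dr, i.e. a 40 s mean lifetime."""
        k = 0.5
        kdr = ModelParameters().k_dr
        rxns = [DelayedReaction("make", products={"mRNA": 1}, rate=k),
                DelayedReaction("deg", reactants={"mRNA": 1}, rate=kdr)]
        means = [simulate(rxns, {"mRNA": 0}, 4_000.0, seed=s)
                 .column("mRNA")[1000:].mean() for s in range(12)]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - k / kdr) < 3 * se
        assert 1 / kdr == pytest.approx(40.0)

    def test_rnap_pool_conserved(self):
        """Free + template-bound RNAPs stay constant through binding,
        elongation and termination."""
        L = 60
        params = ModelParameters(k_tc=2.0, n_rnap=3, n_rib=1, k_tl=0.0,
                                 k_tt=0.0)
        tpl = make_gene_template(length=L, rng=np.random.default_rng(0))
        reactions, initial = build_reaction_system(tpl, params,
                                                   translation=False)
        state = SimState(dict(initial), rng=np.random.default_rng(4))
        live = list(reactions)
        prefixes = ("O", "A")
        for k_ev in range(20_000):
            step(state, live)
            if k_ev % 500 == 0:
                on_template = sum(
                    c for sp, c in state.counts.items()
                    if sp[0] in prefixes and sp[1:].isdigit()
                    or sp.startswith(("Op", "Oar", "Ocorr")))
                pending_oc = sum(1 for e in state.waiting if e[2] == "RpPro")
                total = (state.counts["Rp"] + state.counts.get("RpPro", 0)
                         + pending_oc + on_template)
                assert total == params.n_rnap

    def test_pause_efficiency_emerges_in_network(self):
        """An RNAP crossing a site built for eps = 0.8 enters the paused
        state in ~80% of passages (binomial error), and the sampled pause
        durations average the configured mean."""
        L = 40
        site = PauseSite(20, efficiency=0.8, mean_duration=5.0)
        params = _quiet_params(k_tc=1e6, k_pre=0.0)
        tpl = make_gene_template(length=L, pause_sites=(site,),
                                 rng=np.random.default_rng(0))
        n_pass, n_paused, durations = 300, 0, []
        for s in range(n_pass):
            reactions, initial = build_reaction_system(tpl, params,
                                                       translation=False)
            state = SimState(dict(initial), rng=np.random.default_rng(s))
            live = list(reactions)
            t_pause = None
            for _ in range(5_000):
                step(state, live)
                if state.counts.get("Op20", 0) and t_pause is None:
                    t_pause = state.time
                    n_paused += 1
                if t_pause is not None and state.counts.get("O20", 0):
                    durations.append(state.time - t_pause)
                    break
                if state.counts.get("A20", 0):
                    break
        p_hat = n_paused / n_pass
        assert abs(p_hat - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n_pass)
        mean_dur = np.mean(durations)
        se = np.std(durations, ddof=1) / np.sqrt(len(durations))
        assert abs(mean_dur - 5.0) < 3 * se

    def test_translation_produces_protein_and_conserves_ribosomes(self):
        params = ModelParameters(k_tc=0.5, n_rnap=2, n_rib=10, k_tt=0.0)
        tpl = make_gene_template(length=30, rng=np.random.default_rng(0))
        rxns, init = full_system(tpl, params)
        traj = simulate(rxns, init, t_end=2_000.0,
                        observables=["RNA", "mRNA", "P", "E", "Rib"], seed=6)
        assert traj.column("E")[-1] > 0
        assert (np.diff(traj.column("E")) >= 0).all()
        assert (traj.column("Rib") <= params.n_rib).all()
        assert (traj.column("Rib") >= 0).all()
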