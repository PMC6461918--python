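"""Meiosis model, founder construction, GBLUP prediction, breeding loops."""

import numpy as np
import pytest

from conftest import small_config
from moob.core import BreedingValues
from moob.sim import (
    StrategyConfig,
    apply_strategy,
    fit_gblup,
    make_base_population,
    make_founders,
    meiosis,
    predict_gebv,
    run_breeding,
    run_experiment,
    _chromosome_blocks,
    _gamete,
)


class TestMeiosis:
    def test_identical_inbred_parents_clone_through(self):
        n = 20
        genome = np.stack([np.ones(n, np.int8), np.ones(n, np.int8)])
        chroms = np.ones(n)
        pos = np.linspace(0, 1, n)
        child = meiosis(genome, genome, chroms, pos, rng=3)
        np.testing.assert_array_equal(child, genome)

    def test_zero_length_chromosome_gives_intact_haplotype(self):
        hap = np.stack([np.zeros(10, np.int8), np.ones(10, np.int8)])
        blocks = _chromosome_blocks(np.ones(10), np.full(10, 0.3))
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = _gamete(hap, blocks, rng)
            assert g.sum() in (0, 10)  # one parental haplotype, intact

    def test_haldane_recombination_fraction_at_10cm(self):
        # two markers 0.1 Morgans apart; expect r = (1 - e^{-0.2}) / 2
        hap = np.stack([np.array([0, 0], np.int8), np.array([1, 1], np.int8)])
        blocks = _chromosome_blocks(np.ones(2), np.array([0.0, 0.1]))
        rng = np.random.default_rng(42)
        n = 10_000
        rec = 0
        for _ in range(n):
            g = _gamete(hap, blocks, rng)
            rec += int(g[0] != g[1])
        r_hat = rec / n
        r = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(r * (1 - r) / n)
        assert abs(r_hat - r) < 3 * se

    def test_every_allele_traces_to_a_parent(self):
        # provenance tagging: give every parental allele a unique label
        rng = np.random.default_rng(1)
        n = 30
        pa = np.arange(2 * n, dtype=np.int32).reshape(2, n)
        pb = np.arange(2 * n, 4 * n, dtype=np.int32).reshape(2, n)
        chroms = np.repeat([1, 2], n // 2)
        pos = np.tile(np.linspace(0, 1, n // 2), 2)
        child = meiosis(pa, pb, chroms, pos, rng=rng)
        for l in range(n):
            assert child[0, l] in pa[:, l]
            assert child[1, l] in pb[:, l]


class TestFounders:
    def test_without_burnin_population_is_f1_copies(self):
        cfg = small_config(burnin_random_mating=0)
        state = make_founders(cfg, seed=0)
        # every individual carries one all-0 and one all-1 haplotype
        assert (state.haplotypes[:, 0, :] == 0).all()
        assert (state.haplotypes[:, 1, :] == 1).all()

    def test_all_alleles_from_two_founders(self, small_founders):
        assert set(np.unique(small_founders.haplotypes)) <= {0, 1}

    def test_realized_heritability_near_half(self):
        cfg = small_config(pop_size=100, n_markers_per_chrom=200,
                           n_qtl_per_chrom=40, n_opposite_sign=20)
        ratios = []
        for seed in range(3):
            st = make_founders(cfg, seed)
            g, p = st.true_bv.values, st.phenotypes
            ratios.append(g.var(axis=0, ddof=1) / p.var(axis=0, ddof=1))
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.1)

    def test_traits_negatively_correlated_in_founders(self):
        cfg = small_config(pop_size=100, n_markers_per_chrom=200,
                           n_qtl_per_chrom=40, n_opposite_sign=20)
        corrs = [
            np.corrcoef(make_founders(cfg, s).true_bv.values.T)[0, 1]
            for s in range(3)
        ]
        assert all(c < 0 for c in corrs)

    def test_opposite_sign_qtl_oppose(self, small_founders):
        beta = small_founders.architecture.effects.beta
        opp = small_founders.architecture.opposite_indices
        assert (np.sign(beta[opp, 0]) == -np.sign(beta[opp, 1])).all()


class TestGblup:
    def test_noiseless_limit_recovers_true_values(self, small_founders):
        state = small_founders.clone()
        state.phenotypes = state.true_bv.values.copy()  # no noise
        gebv, _ = predict_gebv(state, h2_assumed=0.999)
        for t in range(2):
            r = np.corrcoef(gebv.values[:, t], state.true_bv.values[:, t])[0, 1]
            assert r > 0.99

    def test_h2_to_zero_shrinks_gebv(self, small_founders):
        D = small_founders.dosages()
        Y = small_founders.phenotypes
        g_small, _ = fit_gblup(D, Y, h2_assumed=1e-4)
        g_mid, _ = fit_gblup(D, Y, h2_assumed=0.5)
        assert np.abs(g_small).max() < 1e-2 * np.abs(g_mid).max()

    def test_holdout_accuracy_positive(self):
        cfg = small_config(pop_size=80, n_markers_per_chrom=150,
                           n_qtl_per_chrom=30, n_opposite_sign=15)
        state = make_founders(cfg, seed=3)
        D, Y, g = state.dosages(), state.phenotypes, state.true_bv.values
        _, model = fit_gblup(D[:40], Y[:40], h2_assumed=0.5)
        pred = model.predict(D[40:])
        for t in range(2):
            assert np.corrcoef(pred[:, t], g[40:, t])[0, 1] > 0

    def test_stored_model_consistent_with_training_gebv(self, small_founders):
        D = small_founders.dosages()
        gebv, model = fit_gblup(D, small_founders.phenotypes, 0.5)
        np.testing.assert_allclose(model.predict(D), gebv, atol=1e-8)


class TestApplyStrategy:
    @pytest.fixture()
    def scored_state(self, small_founders):
        state = small_founders.clone()
        state.gebv = BreedingValues(state.phenotypes.copy(), ["t1", "t2"])
        return state

    def test_degenerate_index_equals_tandem_on_trait_one(self, scored_state):
        tandem = apply_strategy(scored_state, StrategyConfig("tandem"), cycle=1)
        index = apply_strategy(
            scored_state,
            StrategyConfig("index", index_weights=(1.0, 0.0)),
            cycle=1,
        )
        np.testing.assert_array_equal(tandem.support, index.support)

    def test_culling_with_minimal_threshold_keeps_everyone(self, scored_state):
        cv = apply_strategy(
            scored_state, StrategyConfig("culling", culling_quantile=0.0), 1
        )
        m = scored_state.n_individuals
        np.testing.assert_allclose(cv.c, np.full(m, 1 / m))

    def test_tandem_full_fraction_is_uniform(self, scored_state):
        cv = apply_strategy(
            scored_state, StrategyConfig("tandem", selection_fraction=1.0), 1
        )
        m = scored_state.n_individuals
        np.testing.assert_allclose(cv.c, np.full(m, 1 / m))

    def test_nondominated_weights_are_valid(self, scored_state):
        cv = apply_strategy(scored_state, StrategyConfig("nondominated"), 1)
        assert cv.c.sum() == pytest.approx(1.0)
        assert (cv.c >= 0).all()

    def test_moob_pure_coancestry_weight_picks_minimum(self, scored_state):
        from moob.core import compute_relationship, standardize
        from moob.frontier import trace_frontier

        cv = apply_strategy(
            scored_state,
            StrategyConfig(
                "moob_pp_eq1",
                decision_weights=(1.0, 0.0, 0.0),
                frontier_resolution=9,
            ),
            1,
        )
        A = compute_relationship(scored_state.genotypes())
        bv = standardize(
            BreedingValues(scored_state.gebv.values, ["t1", "t2"])
        )
        front = trace_frontier(bv, A, resolution=9)
        min_coan = front.objective_matrix()[:, 2].min()
        assert 0.5 * cv.c @ A.A @ cv.c == pytest.approx(min_coan, abs=1e-6)


class TestBreedingLoops:
    def test_no_selection_means_no_systematic_response(self):
        cfg = small_config(pop_size=24)
        scfg = StrategyConfig("tandem", selection_fraction=1.0)
        deltas = []
        for rep in range(6):
            base = make_base_population(cfg, seed=100 + rep)
            res = run_breeding(base, cfg, scfg, seed=rep, mode="ps", n_cycles=2)
            tr = res.trajectory
            deltas.append(tr["mean_trait1"].iloc[-1] - tr["mean_trait1"].iloc[0])
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se + 1e-9

    def test_truncation_selection_gives_positive_response(self):
        cfg = small_config(pop_size=40)
        scfg = StrategyConfig("tandem", selection_fraction=0.5)
        resp = []
        for rep in range(6):
            base = make_base_population(cfg, seed=200 + rep)
            res = run_breeding(base, cfg, scfg, seed=rep, mode="ps", n_cycles=1)
            tr = res.trajectory
            resp.append(tr["mean_trait1"].iloc[-1] - tr["mean_trait1"].iloc[0])
        resp = np.array(resp)
        se = resp.std(ddof=1) / np.sqrt(len(resp))
        assert resp.mean() > 3 * se

    def test_trajectory_schema(self, small_founders):
        cfg = small_config()
        base = make_base_population(cfg, seed=5)
        res = run_breeding(base, cfg, StrategyConfig("index"), seed=1, n_cycles=2)
        tr = res.trajectory
        assert len(tr) == 3  # completed cycles + 1
        assert list(tr.columns) == [
            "cycle", "inbreeding",
            "mean_trait1", "var_trait1", "gain_trait1",
            "mean_trait2", "var_trait2", "gain_trait2",
        ]

    def test_determinism_and_seed_sensitivity(self):
        cfg = small_config()
        base = make_base_population(cfg, seed=9)
        scfg = StrategyConfig("index")
        r1 = run_breeding(base, cfg, scfg, seed=4, n_cycles=2)
        r2 = run_breeding(base, cfg, scfg, seed=4, n_cycles=2)
        r3 = run_breeding(base, cfg, scfg, seed=5, n_cycles=2)
        assert r1.trajectory.equals(r2.trajectory)
        assert not r1.trajectory.equals(r3.trajectory)

    def test_moob_preserves_more_genetic_variance_than_tandem(self):
        cfg = small_config(pop_size=30)
        var_t, var_m = [], []
        for rep in range(3):
            base = make_base_population(cfg, seed=300 + rep)
            rt = run_breeding(
                base, cfg, StrategyConfig("tandem", selection_fraction=0.2),
                seed=rep, n_cycles=4,
            )
            rm = run_breeding(
                base, cfg,
                StrategyConfig("moob_pp_eq1", frontier_resolution=7),
                seed=rep, n_cycles=4,
            )
            var_t.append(rt.trajectory[["var_trait1", "var_trait2"]].iloc[-1].sum())
            var_m.append(rm.trajectory[["var_trait1", "var_trait2"]].iloc[-1].sum())
        assert np.mean(var_m) > np.mean(var_t)

    def test_genomic_mating_strategy_runs(self):
        cfg = small_config(pop_size=24)
        base = make_base_population(cfg, seed=17)
        scfg = StrategyConfig(
            "genomic_mating",
            n_crosses=6,
            gm_search_opts={"pop_size": 12, "generations": 8},
        )
        res = run_breeding(base, cfg, scfg, seed=3, n_cycles=2)
        assert len(res.trajectory) == 3

    def test_experiment_shares_base_population_and_summarizes(self):
        cfg = small_config(pop_size=24)
        result = run_experiment(
            cfg, ["tandem", "index"], n_reps=2, seed=1, n_cycles=2
        )
        # identical cycle-0 state across strategies within a replicate
        t0 = result.runs["tandem"][0].trajectory.iloc[0]
        i0 = result.runs["index"][0].trajectory.iloc[0]
        assert t0["mean_trait1"] == i0["mean_trait1"]
        assert set(result.summary["strategy"]) == {"tandem", "index"}
        assert len(result.final_combined_gains("tandem")) == 2
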