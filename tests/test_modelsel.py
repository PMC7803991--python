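"""Metrics, the 2R2_MAE selection score, search, retention, ensembling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gcnqsar as g
from gcnqsar.modelsel import CandidateResult, best_candidate


def _cand(tier, r2, mae=0.5, **kw):
    return CandidateResult(
        config=g.GCNConfig(n_conv_layers=min(tier, 4)),
        tier=tier, epochs=50, valid_mae=mae, valid_r2=r2,
        valid_trmae=g.compute_2r2_mae(r2, mae), search_seed=0, **kw,
    )


class TestMetrics:
    def test_mae_worked_examples(self):
        assert g.compute_mae([1.0], [1.0]) == 0.0
        assert g.compute_mae([1.5], [0.5]) == 1.0
        assert g.compute_mae([7.0, 6.5], [7.2, 6.1]) == pytest.approx(0.3)

    def test_rmse_worked_examples(self):
        assert g.compute_rmse([2.0, 3.0], [2.0, 3.0]) == 0.0
        assert g.compute_rmse([1.0, -1.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_r2_worked_examples(self):
        assert g.compute_r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)
        assert g.compute_r2([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(0.0)
        assert g.compute_r2([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_selection_score_worked_examples(self):
        assert g.compute_2r2_mae(1.0, 0.0) == pytest.approx(2.0)
        assert g.compute_2r2_mae(0.67, 0.86) == pytest.approx(0.48)
        assert g.compute_2r2_mae(0.54, 0.84) == pytest.approx(0.24)
        # the higher-R2 config wins despite the slightly worse MAE
        assert g.compute_2r2_mae(0.67, 0.86) > g.compute_2r2_mae(0.54, 0.84)

    def test_length_mismatch_is_a_contract_error(self):
        with pytest.raises(ValueError):
            g.compute_mae([1.0, 2.0], [1.0])

    def test_constant_observations_make_r2_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            g.compute_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_mae_rmse_inequality_on_fuzzed_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            y, f = rng.normal(size=n), rng.normal(size=n)
            mae, rmse = g.compute_mae(y, f), g.compute_rmse(y, f)
            assert mae <= rmse + 1e-12
            assert rmse <= np.sqrt(n) * mae + 1e-12

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=25),
        st.lists(st.floats(-50, 50), min_size=25, max_size=25),
    )
    def test_mae_rmse_inequality_property(self, y, f):
        y = np.asarray(y)
        f = np.asarray(f[: len(y)])
        mae, rmse = g.compute_mae(y, f), g.compute_rmse(y, f)
        assert mae <= rmse + 1e-9
        assert rmse <= np.sqrt(len(y)) * mae + 1e-9

    def test_selection_score_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            r2, mae = rng.uniform(0, 1), rng.uniform(0, 1.5)
            d = rng.uniform(0.01, 0.5)
            assert g.compute_2r2_mae(r2 + d, mae) > g.compute_2r2_mae(r2, mae)
            assert g.compute_2r2_mae(r2, mae + d) < g.compute_2r2_mae(r2, mae)


class TestSelectionOracle:
    def test_best_candidate_matches_brute_force_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            cands = [
                _cand(1, float(rng.uniform(0, 1)), float(rng.uniform(0.2, 1.0)))
                for _ in range(int(rng.integers(1, 12)))
            ]
            pick = best_candidate(cands)
            brute_best = cands[0]
            for c in cands[1:]:
                if c.valid_trmae > brute_best.valid_trmae:
                    brute_best = c
            assert pick is brute_best

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            best_candidate([])


class TestTierRules:
    def test_tier1_with_one_good_repeat_triggers_no_research(self):
        cands = [_cand(1, r2) for r2 in (0.5, 0.3, 0.2, 0.1)]
        decision = g.apply_tier_rules(cands)
        assert decision.research_tiers == []
        assert len(decision.retained) == 4

    def test_tier1_all_below_threshold_flags_research(self):
        cands = [_cand(1, r2) for r2 in (0.44, 0.3, 0.2, 0.1)]
        decision = g.apply_tier_rules(cands)
        assert decision.research_tiers == [1]

    def test_tier2_threshold_is_applied_both_ways(self):
        cands = [_cand(2, 0.39), _cand(2, 0.40)]
        decision = g.apply_tier_rules(cands)
        assert [c.valid_r2 for c in decision.retained] == [0.40]

    @pytest.mark.parametrize("shallow,deep,kept", [(0.52, 0.55, True), (0.56, 0.55, False)])
    def test_deeper_tier_must_beat_every_shallower_candidate(self, shallow, deep, kept):
        cands = [_cand(1, shallow), _cand(3, deep)]
        decision = g.apply_tier_rules(cands)
        assert (deep in [c.valid_r2 for c in decision.retained]) is kept


class TestReproducibilityFilter:
    def test_paper_style_collapse_is_dropped(self):
        cand = _cand(1, 0.53)
        assert g.filter_reproducible([(cand, 0.16)], delta=0.15) == []

    def test_small_fluctuation_is_kept(self):
        cand = _cand(1, 0.53)
        assert g.filter_reproducible([(cand, 0.50)], delta=0.15) == [cand]

    def test_vacuous_delta_keeps_everything(self):
        cands = [(_cand(1, 0.9), 0.0), (_cand(2, 0.5), -0.4)]
        assert len(g.filter_reproducible(cands, delta=1.0)) == 2


class TestEnsemble:
    def test_mean_of_two_members(self, tiny_models, tiny_sets):
        graphs, _ = tiny_sets["test"]
        preds = [m.predict(graphs) for m in tiny_models[:2]]
        ens = g.ensemble_predict(tiny_models[:2], graphs)
        assert np.allclose(ens, (preds[0] + preds[1]) / 2)

    def test_single_model_is_identity(self, tiny_models, tiny_sets):
        graphs, _ = tiny_sets["test"]
        assert np.allclose(
            g.ensemble_predict(tiny_models[:1], graphs), tiny_models[0].predict(graphs)
        )

    def test_ensemble_mae_and_mse_never_exceed_member_means(self, tiny_models, tiny_sets):
        graphs, y = tiny_sets["test"]
        preds = [m.predict(graphs) for m in tiny_models]
        ens = g.ensemble_predict(tiny_models, graphs)
        member_mae = np.mean([g.compute_mae(y, f) for f in preds])
        member_mse = np.mean([g.compute_rmse(y, f) ** 2 for f in preds])
        assert g.compute_mae(y, ens) <= member_mae + 1e-12
        assert g.compute_rmse(y, ens) ** 2 <= member_mse + 1e-12

    def test_empty_ensemble_is_an_error(self, tiny_sets):
        with pytest.raises(ValueError):
            g.ensemble_predict([], tiny_sets["test"][0])


class TestSearch:
    SPACE = g.SearchSpace(
        conv_size=(16, 64), dense_size=(16, 64), epoch=(8, 25), batch_size=(20, 80)
    )

    def test_single_iteration_returns_one_candidate_per_repeat(self, tiny_sets):
        cands = g.search_hyperparameters(
            tiny_sets["train"], tiny_sets["valid"], self.SPACE,
            tiers=(1,), n_iter=1, n_repeats=2, backend="random", seed=3,
        )
        assert len(cands) == 2
        assert all(c.tier == 1 for c in cands)

    def test_random_backend_is_deterministic_in_the_master_seed(self, tiny_sets):
        run = lambda: g.search_hyperparameters(
            tiny_sets["train"], tiny_sets["valid"], self.SPACE,
            tiers=(1,), n_iter=2, n_repeats=1, backend="random", seed=11,
        )
        a, b = run(), run()
        assert [c.config for c in a] == [c.config for c in b]
        assert [c.valid_mae for c in a] == [c.valid_mae for c in b]

    def test_gp_backend_runs_and_scores_candidates(self, tiny_sets):
        cands = g.search_hyperparameters(
            tiny_sets["train"], tiny_sets["valid"], self.SPACE,
            tiers=(2,), n_iter=4, n_repeats=1, backend="gp_ei", seed=5,
        )
        assert len(cands) == 1
        c = cands[0]
        assert c.config.n_conv_layers == 2
        assert c.valid_trmae == pytest.approx(
            g.compute_2r2_mae(c.valid_r2, c.valid_mae), abs=1e-9
        )
        assert self.SPACE.conv_size[0] <= c.config.conv_size <= self.SPACE.conv_size[1]

    def test_search_beats_a_fixed_default_config(self):
        """The searched candidate should outperform an arbitrary fixed
        configuration on validation R² in most repeats."""
        from conftest import featurized

        spec = g.SARSpec(n=400, seed=7, noise_sd=0.2)
        curated, _ = g.build_dataset(g.generate_activity_table(spec))
        split = g.split_dataset(curated, seed=11)
        train = featurized(split.train)
        valid = featurized(split.valid)
        default_cfg = g.GCNConfig(seed=0)
        _, trace = g.train_fixed_epochs(train, valid, default_cfg, 40)
        default_r2 = trace.valid_r2[-1]
        cands = g.search_hyperparameters(
            train, valid, g.SearchSpace.desk(),
            tiers=(1,), n_iter=10, n_repeats=5, backend="gp_ei", seed=23,
        )
        wins = sum(c.valid_r2 > default_r2 for c in cands)
        assert wins >= 4

    def test_unknown_backend_is_an_error(self, tiny_sets):
        with pytest.raises(ValueError):
            g.search_hyperparameters(
                tiny_sets["train"], tiny_sets["valid"], self.SPACE, backend="grid"
            )
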