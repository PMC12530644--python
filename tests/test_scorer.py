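import numpy as np
import pytest

import msilike as m
from msilike.features import record_features
from msilike.scorer import trimmed_mean


class TestTrimmedMean:
    def test_middle_six_of_ten(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        assert trimmed_mean(vals) == pytest.approx(0.55)

    def test_constant(self):
        assert trimmed_mean([0.42] * 10) == pytest.approx(0.42)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.random(10)
        assert trimmed_mean(vals) == pytest.approx(
            trimmed_mean(rng.permutation(vals)))

    def test_generalizes_by_floor_rule(self):
        # n=5 drops floor(1) per tail; n=4 drops none
        assert trimmed_mean([0, 0, 10, 20, 100]) == pytest.approx(10)
        assert trimmed_mean([1, 2, 3, 4]) == pytest.approx(2.5)

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            v = rng.random(10)
            t = trimmed_mean(v)
            assert v.min() <= t <= v.max()


class TestTrainEnsemble:
    def test_ten_submodels_and_class_ratio_weight(
            self, recovery_cohort, freq_table, class_map):
        spec = m.FeatureSpec(name="clin", blocks=("clinical",))
        fm = m.build_feature_matrix(recovery_cohort, spec)
        model = m.train_ensemble(fm, m.TrainingConfig())
        assert len(model.submodels) == 10
        assert model.imbalance_weight == pytest.approx(164 / 24)

    def test_retrain_is_deterministic(self, recovery_cohort):
        spec = m.FeatureSpec(name="clin", blocks=("clinical",))
        fm = m.build_feature_matrix(recovery_cohort, spec)
        cfg = m.TrainingConfig.from_base_seed(7, n_seeds=3)
        a = m.train_ensemble(fm, cfg)
        b = m.train_ensemble(fm, cfg)
        sa = m.predict_scores(a, fm.X)
        sb = m.predict_scores(b, fm.X)
        assert np.array_equal(sa, sb)

    def test_single_class_rejected(self, recovery_cohort):
        spec = m.FeatureSpec(name="clin", blocks=("clinical",))
        mss_only = m.Cohort(
            [r for r in recovery_cohort if r.msi_label == "MSS"])
        fm = m.build_feature_matrix(mss_only, spec)
        with pytest.raises(m.ValidationError, match="both classes"):
            m.train_ensemble(fm, m.TrainingConfig())

    def test_config_invariants(self):
        with pytest.raises(m.ValidationError):
            m.TrainingConfig(n_seeds=2, seed_list=(0, 1))
        with pytest.raises(m.ValidationError):
            m.TrainingConfig(n_seeds=5, seed_list=(0, 1))


class TestClassify:
    @pytest.mark.parametrize("score,expected", [
        (0.31, "MSI-H-like"),
        (0.30, "MSI-H-like"),  # inclusive boundary
        (0.29, "other"),
    ])
    def test_threshold_boundary(self, score, expected):
        assert m.classify(score) == expected

    def test_bad_threshold_rejected(self):
        with pytest.raises(m.ValidationError):
            m.classify(0.5, threshold=1.5)

    def test_lowering_threshold_never_decreases_calls(self):
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        thresholds = np.linspace(0.95, 0.05, 19)
        counts = [
            sum(m.classify(s, t) == "MSI-H-like" for s in scores)
            for t in thresholds
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestCalibrateThreshold:
    def test_selects_top_fraction(self):
        scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        t = m.calibrate_threshold(scores, 0.2)
        assert sum(s >= t for s in scores) == 2

    def test_target_one_takes_everything(self):
        scores = [0.2, 0.5, 0.9]
        t = m.calibrate_threshold(scores, 1.0)
        assert t <= min(scores)

    def test_constant_scores_pick_closer_side(self):
        # all-positive (prevalence 1) vs all-negative (prevalence 0)
        assert m.calibrate_threshold([0.5] * 10, 0.9) == pytest.approx(0.5)
        t = m.calibrate_threshold([0.5] * 10, 0.1)
        assert sum(s >= t for s in [0.5] * 10) == 0

    def test_empty_rejected(self):
        with pytest.raises(m.ValidationError):
            m.calibrate_threshold([], 0.5)


class TestDispatch:
    def test_full_record_routes_to_most_complete(self, toy_registry,
                                                 recovery_cohort):
        record = recovery_cohort.records[0]
        _, name = m.dispatch_and_score(toy_registry, record)
        assert name == "clin+mut+til"

    def test_clinical_only_record_falls_back(self, toy_registry,
                                             recovery_cohort):
        from dataclasses import replace
        from msilike.core_data import MutationProfile, TILProfile
        record = replace(
            recovery_cohort.records[0],
            til=TILProfile({}), mutations=MutationProfile(genes=None),
        )
        _, name = m.dispatch_and_score(toy_registry, record)
        assert name == "clin"

    def test_clinical_plus_mutations_routes_first_satisfiable(
            self, toy_registry, recovery_cohort):
        from dataclasses import replace
        from msilike.core_data import TILProfile
        record = replace(recovery_cohort.records[0], til=TILProfile({}))
        _, name = m.dispatch_and_score(toy_registry, record)
        assert name == "clin+mut"

    def test_all_missing_is_unscorable(self, toy_registry):
        from msilike.core_data import (
            ClinicalFeatures, MutationProfile, PatientRecord, TILProfile)
        record = PatientRecord(
            "empty", ClinicalFeatures(), TILProfile({}),
            MutationProfile(genes=None))
        with pytest.raises(m.UnscorableError):
            m.dispatch_and_score(toy_registry, record)

    def test_score_in_unit_interval(self, toy_registry, recovery_cohort):
        for record in recovery_cohort.records[:10]:
            score, _ = m.dispatch_and_score(toy_registry, record)
            assert 0.0 <= score <= 1.0


class TestLattice:
    def test_default_lattice_has_44_distinct_specs(self):
        specs = m.default_lattice_specs()
        assert len(specs) == 44
        assert len({s.name for s in specs}) == 44
        assert len({s.blocks for s in specs}) == 44

    def test_toy_lattice_ordered_by_completeness(self, toy_registry):
        sizes = [len(mod.spec.blocks) for mod in toy_registry.models]
        assert sizes == sorted(sizes, reverse=True)
        assert len(toy_registry) == 3

    def test_registry_round_trip_preserves_predictions(
            self, toy_registry, recovery_cohort, tmp_path):
        m.save_registry(toy_registry, tmp_path / "reg")
        loaded = m.load_registry(tmp_path / "reg")
        assert loaded.threshold == toy_registry.threshold
        record = recovery_cohort.records[5]
        s0, n0 = m.dispatch_and_score(toy_registry, record)
        s1, n1 = m.dispatch_and_score(loaded, record)
        assert n0 == n1
        assert s0 == pytest.approx(s1, abs=1e-9)


class TestPredictScore:
    def test_matches_manual_trim_of_submodel_outputs(
            self, toy_registry, recovery_cohort, freq_table, class_map):
        model = toy_registry.get("clin+mut+til")
        record = recovery_cohort.records[3]
        feats = record_features(record, model.spec, freq_table, class_map)
        score = m.predict_score(model, feats)
        import numpy as np
        row = np.array([[np.nan if feats[c] is None else feats[c]
                         for c in model.columns]])
        probs = sorted(
            float(sm.predict_proba(row)[0, 1]) for sm in model.submodels)
        k = int(np.floor(0.2 * len(probs)))
        assert score == pytest.approx(
            np.mean(probs[k:len(probs) - k]), abs=1e-9)

    def test_missing_required_feature_is_dispatch_error(self, toy_registry):
        from msilike.scorer import DispatchError
        model = toy_registry.get("clin")
        with pytest.raises(DispatchError):
            m.predict_score(model, {"age_years": 50.0})
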