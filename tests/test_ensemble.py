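import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import multilink as ml
from multilink.ensemble import OccurrenceProfile
from multilink.sda import SDAHyperparams


def _design(n0=8, n1=8, p=40, d=3.0, planted=(0, 5, 11), seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n0 + n1, p))
    y = np.array([0] * n0 + [1] * n1)
    for j in planted:
        X[y == 1, j] += d
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), y] = 1.0
    return ml.DesignMatrix(
        X=X, Y=Y, feature_map=[(0, j + 1) for j in range(p)], labels=y, mode="columns"
    )


class TestRunEnsemble:
    def test_loo_member_accounting(self):
        """A 16-subject cohort yields 16 leave-one-out members, each trained
        on 15 subjects."""
        design = _design(8, 8)
        prof = ml.run_ensemble(design, SDAHyperparams(alpha=3, gamma=10.0))
        assert prof.n_members == 16
        assert prof.n_subjects == 16
        assert prof.skipped_folds == 0

    def test_counts_invariants(self):
        design = _design(8, 8, seed=1)
        hp = SDAHyperparams(alpha=4, gamma=1.0)
        prof = ml.run_ensemble(design, hp)
        assert prof.counts.min() >= 0
        assert prof.counts.max() <= prof.n_members
        assert (prof.counts > 0).sum() <= hp.alpha * prof.n_members

    def test_strong_planted_features_in_every_member(self):
        design = _design(8, 8, d=4.0, seed=2)
        prof = ml.run_ensemble(design, SDAHyperparams(alpha=3, gamma=30.0))
        assert (prof.counts[[0, 5, 11]] == prof.n_members).all()

    def test_pure_noise_counts_spread_under_bootstrap(self):
        """Without any group effect, bootstrap members disagree: no feature
        is selected by close to all of them."""
        ratios = []
        for seed in range(5):
            design = _design(8, 8, d=0.0, planted=(), p=60, seed=10 + seed)
            prof = ml.run_ensemble(
                design,
                SDAHyperparams(alpha=5, gamma=1.0),
                resampling="bootstrap",
                n_bootstrap=16,
                random_state=seed,
            )
            ratios.append(prof.counts.max() / prof.n_members)
        assert np.median(ratios) < 0.8

    def test_degenerate_group_rejected(self):
        design = _design(1, 5, planted=())
        with pytest.raises(ml.DataError, match="group of size 1"):
            ml.run_ensemble(design, SDAHyperparams(alpha=2, gamma=0.1))

    def test_bootstrap_requires_seed_and_positive_b(self):
        design = _design()
        with pytest.raises(ml.DataError, match="B >= 1"):
            ml.run_ensemble(
                design, SDAHyperparams(alpha=2, gamma=0.1), resampling="bootstrap",
                n_bootstrap=0, random_state=0,
            )
        with pytest.raises(ml.ConfigError, match="random_state"):
            ml.run_ensemble(
                design, SDAHyperparams(alpha=2, gamma=0.1), resampling="bootstrap"
            )


class TestStabilitySelect:
    def _profile(self, counts, n_members, n_subjects=None):
        return OccurrenceProfile(
            counts=np.array(counts),
            n_members=n_members,
            alpha=5,
            gamma=0.1,
            n_subjects=n_subjects if n_subjects is not None else n_members,
        )

    def test_half_n_thresholding(self):
        res = ml.stability_select(self._profile([16, 9, 7, 0], 16), "half_n")
        assert res.threshold == 8
        assert res.selected.tolist() == [0, 1]

    def test_threshold_one_keeps_everything_ever_chosen(self):
        res = ml.stability_select(self._profile([16, 9, 7, 0], 16), 1)
        assert res.selected.tolist() == [0, 1, 2]

    def test_threshold_all_members_keeps_unanimous_only(self):
        res = ml.stability_select(self._profile([16, 9, 7, 0], 16), 16)
        assert res.selected.tolist() == [0]

    def test_over_restrictive_threshold_warns_empty(self):
        with pytest.warns(UserWarning, match="exceeds"):
            res = ml.stability_select(self._profile([16, 9], 16), 20)
        assert len(res.selected) == 0

    def test_half_n_rounds_up_for_odd_n(self):
        res = ml.stability_select(self._profile([5, 4, 3], 7, n_subjects=7), "half_n")
        assert res.threshold == 4

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 16), min_size=1, max_size=40),
        threshold=st.integers(1, 16),
    )
    def test_selection_invariant(self, counts, threshold):
        """selected is exactly { j : counts_j >= threshold } and shrinks as
        the threshold grows."""
        prof = self._profile(counts, 16)
        res = ml.stability_select(prof, threshold)
        expected = [j for j, c in enumerate(counts) if c >= threshold]
        assert res.selected.tolist() == expected
        if threshold < 16:
            larger = ml.stability_select(prof, threshold + 1)
            assert set(larger.selected.tolist()) <= set(res.selected.tolist())


class TestTuneParameters:
    def test_single_pair_grid_is_identity(self):
        design = _design(6, 6, seed=3)
        rep = ml.tune_parameters(design, [3], [1.0], seed=0, max_iterations=60)
        assert (rep.chosen_alpha, rep.chosen_gamma) == (3, 1.0)
        assert len(rep.grid) == 1

    def test_plateau_breaks_to_fewest_connections(self):
        """On a perfectly separable cohort every alpha classifies equally
        well; the tie must resolve to the sparsest model."""
        design = _design(6, 6, d=8.0, planted=(0,), p=20, seed=4)
        rep = ml.tune_parameters(design, [1, 3, 5], [10.0], seed=0, max_iterations=60)
        assert rep.misclassification.min() == rep.misclassification[0]
        assert rep.chosen_alpha == 1

    def test_planted_cohort_keeps_alpha_small(self, planted_design):
        design, truth = planted_design
        rep = ml.tune_parameters(design, [5, 13, 50], [30.0], seed=0, max_iterations=80)
        assert rep.chosen_alpha <= 15
        assert rep.validation_error <= 0.1

    def test_alpha_above_p_rejected(self):
        design = _design()
        with pytest.raises(ml.DataError, match="alpha"):
            ml.tune_parameters(design, [9999], [0.1], seed=0)

    def test_small_groups_refused(self):
        design = _design(2, 6, planted=())
        with pytest.raises(ml.DataError, match="3 subjects per group"):
            ml.tune_parameters(design, [2], [0.1], seed=0)


class TestRunMLA:
    CFG = dict(alpha=13, gamma=30.0, resampling="bootstrap", n_bootstrap=30)

    def test_planted_cohort_recovered_exactly(self):
        cohort, truth = ml.generate_cohort(ml.planted_effect_spec(seed=0))
        out = ml.run_mla(cohort, ml.MLAConfig(seed=0, **self.CFG))
        assert sorted(e for e in out.edge_selection.edges) == truth.planted_edges

    def test_multivariate_pair_detected(self):
        """Both edges of a jointly-discriminative pair survive stability
        selection even though each is marginally weak."""
        cohort, truth = ml.generate_cohort(ml.multivariate_pair_spec(seed=0))
        cfg = ml.MLAConfig(alpha=13, gamma=0.1, resampling="bootstrap",
                           n_bootstrap=cohort.n_subjects, seed=0)
        out = ml.run_mla(cohort, cfg)
        sel = set(out.stability.selected.tolist())
        assert set(truth.multivariate_features.tolist()) <= sel

    def test_determinism(self):
        cohort, _ = ml.generate_cohort(ml.planted_effect_spec(seed=3, n_nodes=12))
        cfg = ml.MLAConfig(seed=7, **self.CFG)
        out1 = ml.run_mla(cohort, cfg)
        out2 = ml.run_mla(cohort, cfg)
        assert out1.edge_selection.edges == out2.edge_selection.edges
        np.testing.assert_array_equal(
            out1.stability.profile.counts, out2.stability.profile.counts
        )

    def test_failure_names_stage(self):
        cohort, _ = ml.generate_cohort(ml.planted_effect_spec(seed=1, n_nodes=12))
        cfg = ml.MLAConfig(alpha=9999, gamma=0.1, seed=0)
        with pytest.raises(ml.DataError, match=r"\[stage: fit\]"):
            ml.run_mla(cohort, cfg)

    def test_estimator_interface(self):
        design = _design(8, 8, d=4.0, seed=5)
        est = ml.MultiLinkAnalysis(alpha=3, gamma=30.0, random_state=0)
        est.fit(design.X, design.labels)
        assert set(est.get_support().tolist()) == {0, 5, 11}
        assert est.transform(design.X).shape == (16, 3)
        mask = est.get_support(indices=False)
        assert mask.sum() == 3

    def test_alpha_nesting_on_one_cohort(self):
        """Growing alpha only adds stability-selected features."""
        cohort, _ = ml.generate_cohort(ml.planted_effect_spec(seed=2))
        design = ml.vectorize(cohort)
        sels = []
        for a in [5, 13, 21]:
            prof = ml.run_ensemble(
                design, SDAHyperparams(alpha=a, gamma=30.0),
                resampling="bootstrap", n_bootstrap=30, random_state=2,
            )
            sels.append(set(ml.stability_select(prof, "half_n").selected.tolist()))
        assert sels[0] <= sels[1] <= sels[2]
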