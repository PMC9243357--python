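"""Majority voting, ensemble prediction, metrics and statistical comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crsrad.ensemble import EnsembleModel, ensemble_predict, majority_vote, volumetric_baseline
from crsrad.metrics import compare_metric_distributions, compute_metrics, holm_adjust, rank_auc
from crsrad.model import CVConfig, FittedModel
from crsrad.preprocessing import StandardizationParams
from crsrad.tables import FeatureTable

from oracles import pairwise_auc


def _member(weight, tau, name="f"):
    params = StandardizationParams((name,), np.zeros(1), np.ones(1))
    return FittedModel((name,), params, np.array([weight]), 0.0, 0.1, tau)


class TestMajorityVote:
    def test_simple_majorities(self):
        assert majority_vote([1, 1, 1, 0, 0]) == 1
        assert majority_vote([0, 0, 0, 0, 0]) == 0

    def test_all_patterns_match_counting_oracle(self):
        for votes in itertools.product([0, 1], repeat=5):
            expected = int(sum(votes) >= 3)
            assert majority_vote(list(votes)) == expected

    def test_even_votes_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            majority_vote([0, 1, 1, 0])


class TestEnsemblePrediction:
    def _table(self, values, labels):
        idx = pd.Index([f"P{i}" for i in range(len(values))], name="patient_id")
        return FeatureTable(
            pd.DataFrame({"f": values}, index=idx), pd.Series(labels, index=idx)
        )

    def test_identical_members_equal_single_model(self):
        table = self._table([-2.0, -1.0, 1.0, 2.0], [0, 0, 1, 1])
        member = _member(1.0, 0.5)
        ens = EnsembleModel([member] * 5)
        pred = ensemble_predict(ens, table)
        single = (member.predict_proba(table.features) >= member.tau).astype(int)
        np.testing.assert_array_equal(pred["predicted_class"].to_numpy(), single)

    def test_majority_beats_minority_probabilities(self):
        """3 vs 2 votes decide the class regardless of probability magnitudes."""
        table = self._table([1.0], [1])
        # three members vote 1 with weak confidence, two vote 0 with strength
        members = [_member(0.1, 0.5)] * 3 + [_member(-5.0, 0.5)] * 2
        ens = EnsembleModel(members)
        pred = ensemble_predict(ens, table)
        assert pred["predicted_class"].iloc[0] == 1
        assert pred["ensemble_score"].iloc[0] < 0.5  # mean probability disagrees

    def test_class_depends_only_on_votes_not_scores(self):
        """Shifting member probabilities without crossing thresholds leaves
        the predicted class unchanged."""
        rng = np.random.default_rng(0)
        values = rng.standard_normal(12)
        table = self._table(values, rng.integers(0, 2, 12))
        base = [_member(1.0, 0.5), _member(0.8, 0.4), _member(1.2, 0.6),
                _member(0.9, 0.5), _member(1.1, 0.5)]
        sharp = [_member(m.beta[0] * 3, _sharpen(m.tau, 3)) for m in base]
        c1, s1 = EnsembleModel(base).predict(table.features)
        c2, s2 = EnsembleModel(sharp).predict(table.features)
        np.testing.assert_array_equal(c1, c2)
        assert not np.allclose(s1, s2)

    def test_missing_feature_named_in_error(self):
        table = self._table([1.0], [1])
        ens = EnsembleModel([_member(1.0, 0.5, name="g")] * 5)
        with pytest.raises(KeyError, match="g"):
            ensemble_predict(ens, table)

    def test_even_ensemble_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            EnsembleModel([_member(1.0, 0.5)] * 4)


def _sharpen(tau, k):
    """Threshold consistent with scaling logits by k (sigmoid-space)."""
    logit = np.log(tau / (1 - tau))
    return 1 / (1 + np.exp(-k * logit))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = compute_metrics(y, y.astype(float), y)
        for name in ("auc", "accuracy", "sensitivity", "specificity", "gmean", "ppv", "npv"):
            assert m[name] == 1.0

    def test_always_negative_on_imbalanced_cohort(self):
        y = np.array([1] * 21 + [0] * 79)  # 21% positives
        pred = np.zeros(100, dtype=int)
        with pytest.warns(UserWarning, match="PPV"):
            m = compute_metrics(pred, None, y)
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["gmean"] == 0.0
        assert m["npv"] == pytest.approx(0.79)
        assert np.isnan(m["ppv"])

    def test_gmean_identity(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        m = compute_metrics(pred, rng.uniform(size=50), y)
        assert m["gmean"] == pytest.approx(
            np.sqrt(m["sensitivity"] * m["specificity"]), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_auc_matches_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(size=20), 1)  # ties likely
        labels = rng.integers(0, 2, 20)
        if len(np.unique(labels)) < 2:
            pytest.skip("degenerate draw")
        assert rank_auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12
        )


class TestStatisticalComparisons:
    def test_identical_paired_distributions_give_p_one(self):
        a = np.array([0.7, 0.8, 0.75])
        with pytest.warns(UserWarning, match="zero"):
            assert compare_metric_distributions(a, a.copy(), paired=True) == 1.0

    def test_exact_rank_sum_enumeration(self):
        """{1,2,3} vs {4,5,6}: U = 0; two-sided exact p = 2/C(6,3) = 0.1."""
        p = compare_metric_distributions([1, 2, 3], [4, 5, 6], paired=False)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_holm_hand_computation(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])
        assert holm_adjust([0.03, 0.01, 0.04]) == pytest.approx([0.06, 0.03, 0.06])


class TestVolumetricBaseline:
    def test_uninformative_volume_is_null(self):
        rng = np.random.default_rng(2)
        idx = pd.Index([f"P{i}" for i in range(60)], name="patient_id")
        vols = pd.Series(rng.lognormal(3.5, 0.8, 60), index=idx, name="volume_cm3")
        labels = pd.Series(rng.integers(0, 2, 60), index=idx)
        res = volumetric_baseline(vols, labels, CVConfig(n_repetitions=3, base_seed=2))
        assert 0.3 < res.metrics["auc"].mean() < 0.7

    def test_responder_volume_shift_detected(self):
        """Responders' volumes drawn at the study's median ratio ~0.44."""
        rng = np.random.default_rng(3)
        n = 80
        labels = pd.Series(
            (rng.uniform(size=n) < 0.4).astype(int),
            index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
        )
        vols = pd.Series(
            np.where(labels == 1, rng.lognormal(np.log(36.9), 0.9, n),
                     rng.lognormal(np.log(84.6), 0.9, n)),
            index=labels.index,
            name="volume_cm3",
        )
        res = volumetric_baseline(vols, labels, CVConfig(n_repetitions=3, base_seed=3))
        assert res.metrics["auc"].mean() > 0.6

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        idx = pd.Index([f"P{i}" for i in range(40)], name="patient_id")
        vols = pd.Series(rng.lognormal(3, 1, 40), index=idx, name="v")
        labels = pd.Series([0, 1] * 20, index=idx)
        cfg = CVConfig(n_repetitions=2, base_seed=5)
        a = volumetric_baseline(vols, labels, cfg)
        b = volumetric_baseline(vols, labels, cfg)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_nonpositive_volume_rejected(self):
        idx = pd.Index(["P0", "P1"], name="patient_id")
        with pytest.raises(ValueError):
            volumetric_baseline(
                pd.Series([0.0, 1.0], index=idx), pd.Series([0, 1], index=idx)
            )
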