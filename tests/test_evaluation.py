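import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecgluco import evaluation as ev
from ecgluco.features import FEATURE_NAMES


def mann_whitney_auc(scores, labels):
    """Brute-force pair-counting oracle: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def label_frame(n, frac_pos=0.5, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < frac_pos).astype(int)
    y[:2] = [0, 1]  # both classes guaranteed
    df = pd.DataFrame({"beat_id": range(n), "subject_id": 0, "label": y})
    for name in FEATURE_NAMES:
        df[name] = rng.standard_normal(n)
    return df


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = ev.roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert auc == 1.0

    def test_perfect_inversion(self):
        _, auc = ev.roc_auc([0.3, 0.7], [1, 0])
        assert auc == 0.0

    def test_hand_counted_example(self):
        _, auc = ev.roc_auc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_roc_endpoints(self):
        roc, _ = ev.roc_auc(np.random.default_rng(0).random(50),
                            np.r_[np.ones(25), np.zeros(25)])
        assert (roc["fpr"].iloc[0], roc["tpr"].iloc[0]) == (0.0, 0.0)
        assert (roc["fpr"].iloc[-1], roc["tpr"].iloc[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc([0.1, 0.9], [1, 1])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(10, 200),
        seed=st.integers(0, 10_000),
        ties=st.booleans(),
    )
    def test_matches_mann_whitney_oracle(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        scores = rng.random(n)
        if ties:
            scores = np.round(scores, 1)  # force heavy ties
        _, auc = ev.roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        _, a = ev.roc_auc(scores, labels)
        _, b = ev.roc_auc(np.exp(5 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestSensSpec:
    def test_perfect_scores(self):
        s, sp = ev.sens_spec([1, 1, 0, 0], [1, 1, 0, 0], threshold=0.5)
        assert (s, sp) == (100.0, 100.0)

    def test_degenerate_scorer(self):
        s, sp = ev.sens_spec([0, 0, 0, 0], [1, 1, 0, 0], threshold=0.5)
        assert (s, sp) == (0.0, 100.0)

    def test_hand_confusion_matrix(self):
        s, sp = ev.sens_spec(
            [0.9, 0.6, 0.4, 0.6, 0.2], [1, 1, 1, 0, 0], threshold=0.5
        )
        assert s == pytest.approx(200 / 3, abs=1e-9)
        assert sp == pytest.approx(50.0)

    def test_threshold_sweep_traces_roc(self, rng):
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        roc, _ = ev.roc_auc(scores, labels)
        for _, row in roc.iloc[1:].iterrows():  # skip the sentinel threshold
            s, sp = ev.sens_spec(scores, labels, threshold=row["threshold"])
            assert s / 100 == pytest.approx(row["tpr"], abs=1e-9)
            assert 1 - sp / 100 == pytest.approx(row["fpr"], abs=1e-9)


class TestSplits:
    def test_paper_split_arithmetic(self):
        df = label_frame(51_518)
        train, test = ev.split_80_20(df, seed=0)
        assert len(train) == 41_214
        assert len(test) == 10_304

    def test_small_balanced_split(self):
        df = label_frame(10)
        train, test = ev.split_80_20(df, seed=1)
        assert (len(train), len(test)) == (8, 2)

    def test_deterministic_membership(self):
        df = label_frame(200)
        a = ev.split_80_20(df, seed=5)[0]["beat_id"].to_numpy()
        b = ev.split_80_20(df, seed=5)[0]["beat_id"].to_numpy()
        assert np.array_equal(a, b)

    def test_stratification_within_one_sample(self):
        df = label_frame(1000, frac_pos=0.3, seed=2)
        train, test = ev.split_80_20(df, seed=2)
        for part in (train, test):
            frac = part["label"].mean()
            n_pos_expected = df["label"].mean() * len(part)
            assert abs(part["label"].sum() - n_pos_expected) <= 1

    def test_subject_grouped_split_keeps_subjects_whole(self):
        df = label_frame(300, seed=3)
        df["subject_id"] = np.arange(300) // 15
        df["label"] = (df["subject_id"] % 2).astype(int)  # label constant per subject
        train, test = ev.split_by_subject(df, seed=3)
        assert set(train["subject_id"]) & set(test["subject_id"]) == set()
        assert set(test["label"]) == {0, 1}


class TestKFold:
    def test_fold_sizes_and_mean(self):
        df = label_frame(1000)

        def fit_score(train, test):
            return np.random.default_rng(0).random(len(test))

        sizes = []
        orig = fit_score

        def spy(train, test):
            sizes.append(len(test))
            return orig(train, test)

        aucs, mean = ev.kfold_cv(df, spy, k=10, seed=0)
        assert sizes == [100] * 10
        assert len(aucs) == 10
        assert mean == pytest.approx(np.mean(aucs), abs=1e-12)

    def test_k_too_small_rejected(self):
        with pytest.raises(ValueError):
            ev.kfold_cv(label_frame(100), lambda a, b: np.zeros(len(b)), k=1)


class TestComparison:
    def _report(self, auc, name):
        roc = pd.DataFrame({"threshold": [1, 0], "fpr": [0, 1], "tpr": [0, 1]})
        return ev.EvaluationReport(
            auc=auc, sensitivity=0.0, specificity=0.0, threshold=0.5,
            roc=roc, model_name=name,
        )

    def test_printed_relative_improvement(self):
        # the two published AUCs reproduce the published 53% headline
        assert round(ev.relative_improvement(94.53, 61.68)) == 53

    def test_identical_aucs_zero_improvement(self):
        table = ev.compare_models([self._report(0.8, "a"), self._report(0.8, "b")])
        assert np.allclose(table["rel_improvement_pct"], 0.0)

    def test_three_reports_sorted_descending(self):
        table = ev.compare_models(
            [self._report(0.7, "a"), self._report(0.9, "b"), self._report(0.8, "c")]
        )
        assert list(table["model"]) == ["b", "c", "a"]
        assert table["auc_pct"].is_monotonic_decreasing

    def test_mismatched_test_sets_rejected(self):
        a, b = self._report(0.8, "a"), self._report(0.7, "b")
        a.test_set_id, b.test_set_id = "x", "y"
        with pytest.raises(ValueError):
            ev.compare_models([a, b])
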