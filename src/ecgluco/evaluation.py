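"""ROC/AUC, sensitivity/specificity, splits, k-fold CV and model
comparison reports.

AUC is computed by trapezoidal integration of the ROC traced over the
unique score thresholds, which for tied scores coincides with the
normalized Mann-Whitney U statistic (probability that a random positive
outscores a random negative, counting ties as half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold, train_test_split


@dataclass
class EvaluationReport:
    """Scores of one model on one test set.

    ``auc`` is a fraction in [0, 1]; sensitivity and specificity are
    percentages at the stated operating threshold.
    """

    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    roc: pd.DataFrame  # columns: threshold, fpr, tpr
    model_name: str = "model"
    config: dict = field(default_factory=dict)
    fold_aucs: list[float] | None = None
    n_test: int = 0
    test_set_id: str | None = None

    @property
    def auc_pct(self) -> float:
        return 100.0 * self.auc

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "auc": self.auc,
            "auc_pct": self.auc_pct,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "threshold": self.threshold,
            "n_test": self.n_test,
            "fold_aucs": self.fold_aucs,
            "config": self.config,
        }

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        self.roc.to_csv(path.with_suffix(".roc.csv"), index=False)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points over the unique-score threshold sweep, plus AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, thresholds = _skm.roc_curve(labels, scores)
    auc = float(_skm.auc(fpr, tpr))
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return roc, auc


def sens_spec(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float]:
    """Sensitivity and specificity (percent) at a fixed score threshold.

    A sample is called positive when its score is >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = scores >= threshold
    pos = labels == 1
    sensitivity = 100.0 * np.mean(pred[pos])
    specificity = 100.0 * np.mean(~pred[~pos])
    return float(sensitivity), float(specificity)


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Operating threshold maximizing Youden's J = TPR - FPR."""
    roc, _ = roc_auc(scores, labels)
    j = roc["tpr"] - roc["fpr"]
    return float(roc["threshold"].iloc[int(np.argmax(j.to_numpy()))])


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float | str = 0.5,
    model_name: str = "model",
    config: dict | None = None,
) -> EvaluationReport:
    """Bundle ROC/AUC and the operating point into a report.

    ``threshold`` may be a number or ``"youden"``.
    """
    roc, auc = roc_auc(scores, labels)
    thr = youden_threshold(scores, labels) if threshold == "youden" else float(threshold)
    sens, spec = sens_spec(scores, labels, threshold=thr)
    return EvaluationReport(
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        threshold=thr,
        roc=roc,
        model_name=model_name,
        config=config or {},
        n_test=len(labels),
    )


def split_80_20(
    matrix: pd.DataFrame, seed: int = 0, train_fraction: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffled stratified row-level split; train size = floor(f * n)."""
    if len(matrix) < 5:
        raise ValueError("need at least 5 rows to split")
    n_train = int(np.floor(train_fraction * len(matrix)))
    train, test = train_test_split(
        matrix,
        train_size=n_train,
        stratify=matrix["label"],
        random_state=seed,
        shuffle=True,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def split_by_subject(
    matrix: pd.DataFrame, seed: int = 0, train_fraction: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-grouped stratified split: all beats of a subject land on
    one side.  Beat-level splitting lets a high-capacity model recognise
    training subjects in the test set; use this variant whenever
    generalization to unseen subjects is the question.
    """
    if "subject_id" not in matrix.columns:
        raise ValueError("matrix has no subject_id column")
    subj = matrix.groupby("subject_id")["label"].first()
    rng = np.random.default_rng(seed)
    train_subjects: list = []
    for lbl in sorted(subj.unique()):
        ids = subj[subj == lbl].index.to_numpy()
        rng.shuffle(ids)
        k = int(round(train_fraction * len(ids)))
        train_subjects.extend(ids[:k])
    in_train = matrix["subject_id"].isin(train_subjects)
    return (
        matrix[in_train].reset_index(drop=True),
        matrix[~in_train].reset_index(drop=True),
    )


def kfold_cv(
    matrix: pd.DataFrame,
    fit_score,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Stratified k-fold AUCs of a ``fit_score(train_df, test_df) ->
    scores`` callable, plus their mean."""
    if k < 2:
        raise ValueError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y = matrix["label"].to_numpy()
    aucs: list[float] = []
    for train_idx, test_idx in skf.split(matrix, y):
        train = matrix.iloc[train_idx].reset_index(drop=True)
        test = matrix.iloc[test_idx].reset_index(drop=True)
        if len(np.unique(test["label"])) < 2 or len(np.unique(train["label"])) < 2:
            raise ValueError("a fold is missing a class; reduce k")
        scores = fit_score(train, test)
        _, auc = roc_auc(scores, test["label"].to_numpy())
        aucs.append(auc)
    return aucs, float(np.mean(aucs))


def relative_improvement(auc_a: float, auc_b: float) -> float:
    """Percent relative AUC improvement of model a over model b."""
    return 100.0 * (auc_a - auc_b) / auc_b


def compare_models(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Descending-AUC comparison table with improvement over the runner-up
    baseline (best non-top model)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    ids = {r.test_set_id for r in reports if r.test_set_id is not None}
    if len(ids) > 1:
        raise ValueError("reports were evaluated on different test sets")
    rows = sorted(reports, key=lambda r: r.auc, reverse=True)
    best = rows[0]
    table = pd.DataFrame(
        {
            "model": [r.model_name for r in rows],
            "auc_pct": [r.auc_pct for r in rows],
            "sensitivity_pct": [r.sensitivity for r in rows],
            "specificity_pct": [r.specificity for r in rows],
            "rel_improvement_pct": [
                relative_improvement(best.auc, r.auc) if r is not best else 0.0
                for r in rows
            ],
        }
    )
    return table


def plot_roc(report: EvaluationReport, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.roc["fpr"], report.roc["tpr"],
            label=f"{report.model_name} (AUC {report.auc_pct:.2f}%)")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
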