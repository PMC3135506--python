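"""Two-level nested cross-validation for methylation classifiers.

The outer loop holds out 1/6 of the samples (whole cases, so a patient's
tumor/normal pair never straddles the split); the remaining 40 samples go
through an inner 10-fold cross-validation that picks the classifier and
the number of loci by normalized correct rate (balanced accuracy).  The
winning model is refit on all 40 training samples and scored on the 8
held-out samples; confusion counts are pooled over the six outer folds.
Feature selection (2-way tissue + case ANOVA ranking) is recomputed inside
every training split, so no held-out sample ever influences the loci a
model sees — the audit trail records the selected sets per fold so this
can be asserted.

The classifier menu is deliberately small and deterministic: 1- and
3-nearest-neighbor on Euclidean distance, nearest centroid with equal
priors (midpoint ties go to the first class), and linear discriminant
analysis with pooled covariance and equal priors (ridge fallback when the
pooled covariance is singular).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .anova import paired_design_anova
from .preprocess import BetaMatrix

__all__ = [
    "CvConfig",
    "CvReport",
    "make_nested_folds",
    "select_features_anova",
    "classify",
    "confusion_metrics",
    "nested_cv",
    "CLASSIFIERS",
]

log = logging.getLogger(__name__)

CLASSIFIERS = ("knn1", "knn3", "centroid", "lda")
POSITIVE_CLASS = "tumor"


@dataclass
class CvConfig:
    outer_folds: int = 6
    inner_folds: int = 10
    classifiers: tuple[str, ...] = CLASSIFIERS
    n_variables: tuple[int, ...] = tuple(range(1, 51))
    forced_loci: tuple[str, ...] = ()
    seed: int = 0


@dataclass
class CvReport:
    per_size: pd.DataFrame  # index n_variables; accuracy/sen/spec/ppv/npv in %, chosen classifier
    confusion: dict[int, dict[str, int]]
    chosen_classifier: str
    inner_rates: pd.DataFrame  # normalized correct rate per (classifier, n_variables)
    fold_audit: dict = field(default_factory=dict)


def make_nested_folds(samples: pd.DataFrame, config: CvConfig) -> list[dict]:
    """Case-level outer/inner partitions: 48 samples -> 6 x 8 held out, 10 x 4 inner.

    Whole cases move together so a subject's paired sample cannot leak
    across a split.  Raises when the case count does not divide evenly,
    suggesting the nearest feasible fold counts.
    """
    cases = samples["case_id"].unique()
    n_cases = len(cases)
    for name, k in (("outer", config.outer_folds),):
        if n_cases % k:
            feasible = [d for d in range(2, n_cases + 1) if n_cases % d == 0]
            raise ValueError(
                f"{n_cases} cases not divisible into {k} {name} folds; feasible: {feasible}"
            )
    inner_cases = n_cases - n_cases // config.outer_folds
    if inner_cases % config.inner_folds:
        feasible = [d for d in range(2, inner_cases + 1) if inner_cases % d == 0]
        raise ValueError(
            f"{inner_cases} training cases not divisible into {config.inner_folds} inner folds; "
            f"feasible: {feasible}"
        )
    rng = np.random.default_rng(config.seed)
    shuffled = rng.permutation(cases)
    outer_groups = np.array_split(shuffled, config.outer_folds)
    by_case = samples.groupby("case_id").groups

    folds = []
    for i, test_cases in enumerate(outer_groups):
        train_cases = np.array([c for c in shuffled if c not in set(test_cases)])
        inner_shuffled = rng.permutation(train_cases)
        inner_groups = np.array_split(inner_shuffled, config.inner_folds)
        fold = {
            "outer_index": i,
            "test_samples": [s for c in test_cases for s in by_case[c]],
            "train_samples": [s for c in train_cases for s in by_case[c]],
            "inner": [
                {
                    "val_samples": [s for c in g for s in by_case[c]],
                    "fit_samples": [
                        s for c in train_cases if c not in set(g) for s in by_case[c]
                    ],
                }
                for g in inner_groups
            ],
        }
        folds.append(fold)
    return folds


def select_features_anova(
    train_beta: pd.DataFrame,
    train_samples: pd.DataFrame,
    k: int,
    forced: tuple[str, ...] = (),
) -> list[str]:
    """Top-k loci by tissue-factor p from a 2-way tissue + case ANOVA.

    Forced loci come first; the remainder is filled by ascending tissue p
    (computed on the training samples only).
    """
    if k < len(forced):
        raise ValueError("k must be at least the number of forced loci")
    if k > train_beta.shape[0]:
        raise ValueError(f"k={k} exceeds {train_beta.shape[0]} available loci")
    Y = train_beta.to_numpy(dtype=float)
    _, _, tests = paired_design_anova(Y, train_samples.loc[train_beta.columns], ("tissue", "case"))
    p = tests["tissue"][1]
    order = np.argsort(p, kind="stable")
    chosen = list(forced)
    for i in order:
        if len(chosen) == k:
            break
        locus = train_beta.index[i]
        if locus not in chosen:
            chosen.append(locus)
    return chosen


def _knn(train_X, train_y, test_X, k: int) -> np.ndarray:
    d = cdist(test_X, train_X)
    # stable argsort: equidistant neighbors resolve by training order
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    votes = train_y[nn]
    out = []
    for row in votes:
        vals, counts = np.unique(row, return_counts=True)
        top = counts.max()
        # majority; ties broken by first occurrence among the neighbors
        winners = set(vals[counts == top])
        out.append(next(v for v in row if v in winners))
    return np.array(out)


def _centroid(train_X, train_y, test_X, classes) -> np.ndarray:
    centroids = np.stack([train_X[train_y == c].mean(axis=0) for c in classes])
    d = cdist(test_X, centroids)
    # ties (midpoint) go to the first listed class: argmin takes first minimum
    return classes[np.argmin(d, axis=1)]


def _lda(train_X, train_y, test_X, classes) -> np.ndarray:
    means = np.stack([train_X[train_y == c].mean(axis=0) for c in classes])
    n, p = train_X.shape
    resid = train_X - means[np.searchsorted(classes, train_y)]
    dof = max(n - len(classes), 1)
    cov = resid.T @ resid / dof
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        log.warning("singular pooled covariance: adding ridge 1e-6")
        cov_inv = np.linalg.inv(cov + 1e-6 * np.eye(p))
    # equal priors: discriminant = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2
    scores = test_X @ cov_inv @ means.T - 0.5 * np.einsum("ij,jk,ik->i", means, cov_inv, means)
    return classes[np.argmax(scores, axis=1)]


def classify(train_X, train_y, test_X, method: str) -> np.ndarray:
    """Predict labels with one of the menu classifiers (deterministic ties)."""
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)  # sorted; "first class" = first in this order
    if len(classes) < 2:
        raise ValueError("need at least one training sample per class")
    if method == "knn1":
        return _knn(train_X, train_y, test_X, 1)
    if method == "knn3":
        return _knn(train_X, train_y, test_X, 3)
    if method == "centroid":
        return _centroid(train_X, train_y, test_X, classes)
    if method == "lda":
        return _lda(train_X, train_y, test_X, classes)
    raise ValueError(f"unknown classifier {method!r}")


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, PPV and NPV in percent.

    Ratios with a zero denominator are reported as None (missing), not 0.
    """
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("counts must be >= 0 with a positive total")

    def pct(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "accuracy": pct(tp + tn, tp + fp + tn + fn),
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }


def _normalized_correct_rate(y_true, y_pred) -> float:
    """Mean of per-class correct rates (balanced accuracy)."""
    rates = []
    for c in np.unique(y_true):
        mask = y_true == c
        rates.append(np.mean(y_pred[mask] == c))
    return float(np.mean(rates))


def nested_cv(
    beta: BetaMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    config: CvConfig | None = None,
) -> CvReport:
    """Run the full 6 x 10 nested cross-validation.

    The inner loop scores every (classifier, n_variables) pair by mean
    normalized correct rate over the 10 inner folds; ties prefer the
    smaller model, then menu order.  For the per-size report rows, the best
    classifier *at that size* is refit on the outer-training samples and
    scored on the held-out samples; confusion counts are pooled over outer
    folds.  The overall chosen classifier is the inner-loop winner across
    all sizes.
    """
    config = config or CvConfig()
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    missing_forced = set(config.forced_loci) - set(values.index)
    if missing_forced:
        raise ValueError(f"forced loci not in data: {sorted(missing_forced)}")
    folds = make_nested_folds(samples, config)
    labels = samples["tissue"]

    sizes = list(config.n_variables)
    inner_scores = np.zeros((len(config.classifiers), len(sizes)))
    confusion = {k: {"tp": 0, "fp": 0, "tn": 0, "fn": 0} for k in sizes}
    chosen_at_size: dict[int, list[str]] = {k: [] for k in sizes}
    audit: dict = {"outer": []}

    for fold in folds:
        fold_rates = np.zeros((len(config.classifiers), len(sizes)))
        inner_audit = []
        for inner in fold["inner"]:
            fit_s, val_s = inner["fit_samples"], inner["val_samples"]
            ranked = select_features_anova(
                values[fit_s], samples.loc[fit_s], max(sizes), config.forced_loci
            )
            inner_audit.append({"fit_samples": fit_s, "selected": ranked})
            y_fit = labels.loc[fit_s].to_numpy()
            y_val = labels.loc[val_s].to_numpy()
            Xf_all = values.loc[ranked, fit_s].to_numpy().T
            Xv_all = values.loc[ranked, val_s].to_numpy().T
            for j, k in enumerate(sizes):
                for i, clf in enumerate(config.classifiers):
                    pred = classify(Xf_all[:, :k], y_fit, Xv_all[:, :k], clf)
                    fold_rates[i, j] += _normalized_correct_rate(y_val, pred)
        fold_rates /= len(fold["inner"])
        inner_scores += fold_rates

        # refit per size on the 40 outer-training samples, score the held-out 8
        train_s, test_s = fold["train_samples"], fold["test_samples"]
        ranked = select_features_anova(
            values[train_s], samples.loc[train_s], max(sizes), config.forced_loci
        )
        y_train = labels.loc[train_s].to_numpy()
        y_test = labels.loc[test_s].to_numpy()
        Xtr_all = values.loc[ranked, train_s].to_numpy().T
        Xte_all = values.loc[ranked, test_s].to_numpy().T
        for j, k in enumerate(sizes):
            best_i = int(np.argmax(fold_rates[:, j]))  # menu order breaks ties
            clf = config.classifiers[best_i]
            chosen_at_size[k].append(clf)
            pred = classify(Xtr_all[:, :k], y_train, Xte_all[:, :k], clf)
            pos = y_test == POSITIVE_CLASS
            pred_pos = pred == POSITIVE_CLASS
            confusion[k]["tp"] += int((pos & pred_pos).sum())
            confusion[k]["fn"] += int((pos & ~pred_pos).sum())
            confusion[k]["fp"] += int((~pos & pred_pos).sum())
            confusion[k]["tn"] += int((~pos & ~pred_pos).sum())
        audit["outer"].append(
            {"test_samples": test_s, "train_samples": train_s,
             "selected": ranked, "inner": inner_audit}
        )

    inner_scores /= len(folds)
    rates = pd.DataFrame(inner_scores, index=list(config.classifiers), columns=sizes)
    # overall winner: best mean rate; ties -> smaller size, then menu order
    flat_best = max(
        ((rates.loc[c, k], -k, -ci) for ci, c in enumerate(config.classifiers) for k in sizes),
    )
    chosen_classifier = config.classifiers[-flat_best[2]]

    rows = []
    for k in sizes:
        m = confusion_metrics(**confusion[k])
        m["n_variables"] = k
        m["classifier"] = max(set(chosen_at_size[k]), key=chosen_at_size[k].count)
        rows.append(m)
    per_size = pd.DataFrame(rows).set_index("n_variables")
    return CvReport(
        per_size=per_size,
        confusion=confusion,
        chosen_classifier=chosen_classifier,
        inner_rates=rates,
        fold_audit=audit,
    )
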