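"""Endpoint labeling, cohort splitting and ROC/AUC model evaluation.

Progression is dichotomized at a 3-year (36-month) cutoff: an event at or
before the cutoff labels the patient 1; event-free follow-up beyond the
cutoff labels 0; patients censored event-free before the cutoff are excluded
by default (their class is unknowable), with an opt-in ``censored="zero"``
policy that labels them 0 instead.

AUC is the Mann-Whitney concordance probability with ties counted 1/2; its
95% confidence interval uses the DeLong variance estimator with a normal
approximation (a seeded bootstrap alternative is available), clipped to
[0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import RadScoreModel, lasso_select, score_table

logger = logging.getLogger(__name__)

CUTOFF_MONTHS = 36.0


def label_progression(
    progressed: bool, time_months: float, cutoff_months: float = CUTOFF_MONTHS
) -> int | None:
    """Binary progression label at the cutoff; None = excluded (censored early)."""
    if time_months < 0:
        raise ValueError(f"negative follow-up time: {time_months}")
    if progressed and time_months <= cutoff_months:
        return 1
    if time_months > cutoff_months:
        return 0
    return None  # event-free but censored before the cutoff


def apply_labels(
    clinical: pd.DataFrame,
    cutoff_months: float = CUTOFF_MONTHS,
    censored: str = "exclude",
) -> pd.DataFrame:
    """Attach dichotomized labels to a clinical table.

    Expects columns ``progressed`` (bool/0-1) and ``followup_months``; rows
    whose label is undefined are dropped (``censored="exclude"``, default)
    or labeled 0 (``censored="zero"``).
    """
    if censored not in ("exclude", "zero"):
        raise ValueError(f"unknown censored policy {censored!r}")
    labels = [
        label_progression(bool(p), float(t), cutoff_months)
        for p, t in zip(clinical["progressed"], clinical["followup_months"])
    ]
    out = clinical.copy()
    out["label"] = labels
    n_undef = out["label"].isna().sum()
    if n_undef:
        logger.info("%d patient(s) censored before the %.0f-month cutoff (%s)",
                    n_undef, cutoff_months, censored)
    if censored == "exclude":
        out = out[out["label"].notna()].copy()
    else:
        out["label"] = out["label"].fillna(0)
    out["label"] = out["label"].astype(int)
    return out


def split_cohort(patients: list, n_train: int, seed: int) -> tuple[list, list]:
    """Uniform random split (no stratification) into training/validation."""
    n = len(patients)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = [patients[i] for i in sorted(order[:n_train])]
    val = [patients[i] for i in sorted(order[n_train:])]
    return train, val


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    method: str = "delong"


def _midrank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2, via midranks."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_variance(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    """DeLong variance of a single AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # V10_i = P(score_neg < pos_i) + 0.5 P(=); V01_j symmetric
    v10 = np.array([(np.sum(neg < x) + 0.5 * np.sum(neg == x)) / n for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m for x in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """AUC with a 95% (by default) confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    auc = _midrank_auc(scores, labels)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if ci_method == "delong":
        se = float(np.sqrt(_delong_variance(scores, labels, auc)))
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(labels == 1)
        idx_neg = np.flatnonzero(labels == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [rng.choice(idx_pos, n_pos), rng.choice(idx_neg, n_neg)]
            )
            reps[b] = _midrank_auc(scores[take], labels[take])
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo = float(np.clip(min(lo, auc), 0.0, 1.0))
    hi = float(np.clip(max(hi, auc), 0.0, 1.0))
    return ROCResult(auc, lo, hi, n_pos, n_neg, ci_method)


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR, threshold) coordinates of the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    thresholds = np.unique(s)[::-1]
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((1 - y).sum()), 1)
    rows = [(0.0, 0.0, np.inf)]
    for t in thresholds:
        pred = s >= t
        rows.append(((pred & (y == 0)).sum() / n_neg, (pred & (y == 1)).sum() / n_pos, t))
    return pd.DataFrame(rows, columns=["fpr", "tpr", "threshold"])


def group_difference_tests(
    feature_matrix: pd.DataFrame, labels, alpha: float = 0.05, fdr: bool = False
) -> pd.DataFrame:
    """Two-sided two-sample t test per feature column.

    Degenerate columns (zero variance in both groups) get t = 0, p = 1 when
    the group means are equal, else p = 0.  ``fdr=True`` adds
    Benjamini-Hochberg adjusted p-values and flags on those instead.
    """
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 patients per class")
    a = feature_matrix.loc[y == 1]
    b = feature_matrix.loc[y == 0]
    t, p = stats.ttest_ind(a.values, b.values, axis=0, equal_var=True)
    t, p = np.asarray(t, dtype=float), np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        same = np.isclose(a.values.mean(axis=0), b.values.mean(axis=0))
        t[degenerate & same] = 0.0
        p[degenerate & same] = 1.0
        t[degenerate & ~same] = np.inf
        p[degenerate & ~same] = 0.0
    out = pd.DataFrame({"feature": feature_matrix.columns, "t": t, "p": p})
    if fdr:
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(adj)
        q[order] = np.clip(adj, 0, 1)
        out["p_adjusted"] = q
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def evaluate_models(
    train_features: pd.DataFrame,
    train_labels,
    val_features: pd.DataFrame,
    val_labels,
    feature_sets: dict[str, list[str]] | None = None,
    folds: int = 10,
    seed: int = 0,
    ci_method: str = "delong",
) -> dict[str, dict]:
    """Fit and compare single-modality and combined radiomic models.

    For each feature set: Lasso-select on the training cohort, score both
    cohorts with the resulting Rad-score, and report training/validation
    ROC results.  An empty selection degenerates to the intercept-only model
    (all scores equal, AUC 0.5).
    """
    if feature_sets is None:
        cols = list(train_features.columns)
        feature_sets = {
            "CET1-only": [c for c in cols if c.startswith("CET1-w_")],
            "T2-only": [c for c in cols if c.startswith("T2-w_")],
            "combined": cols,
        }
    y_tr = np.asarray(train_labels, dtype=int)
    y_va = np.asarray(val_labels, dtype=int)
    results: dict[str, dict] = {}
    for name, cols in feature_sets.items():
        sel = lasso_select(train_features[cols], y_tr, folds=folds, seed=seed)
        s_tr = score_table(sel.model, train_features).values
        s_va = score_table(sel.model, val_features).values
        results[name] = {
            "selected": sel.selected,
            "model": sel.model,
            "training": roc_auc(s_tr, y_tr, ci_method=ci_method, seed=seed),
            "validation": roc_auc(s_va, y_va, ci_method=ci_method, seed=seed),
        }
    return results
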