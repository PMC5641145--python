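"""Lasso logistic signature selection and the Rad-score linear model.

``lasso_select`` standardizes the feature matrix, runs stratified k-fold
cross-validation of L1-penalized logistic regression over a log-spaced
penalty path, picks the penalty minimizing held-out binomial deviance
(optionally the one-standard-error rule), and returns the surviving
features as a linear Rad-score model expressed on the original feature
scale.

``published_model`` freezes the eight-coefficient Rad-score reported for
progression prediction in advanced nasopharyngeal carcinoma; its
coefficients apply to raw feature values (no standardization block).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)


@dataclass
class RadScoreModel:
    """Linear score: intercept + sum(coefficient * feature value).

    ``standardization`` optionally maps each feature through
    ``(x - mean) / sd`` before applying its coefficient.
    """

    intercept: float
    coefficients: dict[str, float]
    standardization: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if any(c == 0.0 for c in self.coefficients.values()):
            raise ValueError("coefficients must not contain zero entries")

    def score(self, features: dict[str, float]) -> float:
        return rad_score(self, features)

    def to_json(self) -> str:
        obj = {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "standardization": (
                {k: list(v) for k, v in self.standardization.items()}
                if self.standardization
                else None
            ),
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RadScoreModel":
        obj = json.loads(text)
        std = obj.get("standardization")
        return cls(
            intercept=float(obj["intercept"]),
            coefficients={k: float(v) for k, v in obj["coefficients"].items()},
            standardization=(
                {k: (float(v[0]), float(v[1])) for k, v in std.items()} if std else None
            ),
        )


def rad_score(model: RadScoreModel, features: dict[str, float]) -> float:
    """Score one patient; every model feature must be present (no imputation)."""
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in features:
            raise KeyError(f"missing feature required by the model: {name!r}")
        x = float(features[name])
        if model.standardization and name in model.standardization:
            mu, sd = model.standardization[name]
            x = (x - mu) / sd
        total += coef * x
    return float(total)


#: The frozen published 8-feature Rad-score (raw feature scale, no
#: standardization).  Subband indices: 0 = original image, 1..8 = wavelet
#: subbands LLL..HHH.
_PUBLISHED_COEFFICIENTS = {
    "CET1-w_5_fos_median": 0.0330481732,
    "CET1-w_1_GLCM_correlation": -6.4931353700,
    "CET1-w_4_GLRLM_LRHGLE": -0.0008289514,
    "CET1-w_5_GLRLM_RP": 9.7275394149,
    "T2-w_Max3D": 0.0106439280,
    "T2-w_4_fos_mean": -0.1787872430,
    "T2-w_7_fos_mean": -0.4498668025,
    "T2-w_5_GLCM_sum_average": 0.1613474592,
}
_PUBLISHED_INTERCEPT = 65.1061061821


def published_model() -> RadScoreModel:
    """The frozen 8-coefficient progression Rad-score (4 CET1-w + 4 T2-w terms)."""
    return RadScoreModel(
        intercept=_PUBLISHED_INTERCEPT,
        coefficients=dict(_PUBLISHED_COEFFICIENTS),
        standardization=None,
    )


@dataclass
class SelectionResult:
    lambda_path: np.ndarray
    chosen_lambda: float
    cv_folds: int
    cv_deviance: np.ndarray  # summed held-out deviance per lambda
    selected: list[str]
    model: RadScoreModel
    seed: int
    dropped_constant: list[str] = field(default_factory=list)


def _stratified_folds(ids: np.ndarray, y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold labels keyed by patient id.

    Patients are sorted by id, shuffled by the seeded RNG, and dealt
    round-robin within each class, so fold membership depends on (ids, seed)
    but never on input row order.
    """
    order = np.argsort(ids, kind="stable")
    rng = np.random.default_rng(seed)
    perm = order[rng.permutation(len(ids))]
    fold = np.empty(len(ids), dtype=int)
    for cls in np.unique(y):
        members = [i for i in perm if y[i] == cls]
        for k, i in enumerate(members):
            fold[i] = k % folds
    return fold


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def _fit_l1(x: np.ndarray, y: np.ndarray, lam: float, lambda_max: float):
    """(intercept, coefs) of L1 logistic at penalty ``lam`` on standardized x.

    At or above the analytic lambda_max the solution is exactly the
    intercept-only model (KKT), solved in closed form; liblinear handles the
    interior (intercept_scaling keeps its intercept penalization negligible).
    """
    n = len(y)
    if lam >= lambda_max * (1.0 - 1e-12):
        pbar = y.mean()
        return float(np.log(pbar / (1 - pbar))), np.zeros(x.shape[1])
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n * lam),
        solver="liblinear",
        intercept_scaling=100.0,
        max_iter=2000,
        tol=1e-6,
    )
    clf.fit(x, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def lasso_select(
    features: pd.DataFrame,
    labels,
    folds: int = 10,
    seed: int = 0,
    ids=None,
    lambda_rule: str = "min",
    n_lambda: int = 40,
    lambda_min_ratio: float | None = None,
    lambda_path=None,
) -> SelectionResult:
    """Cross-validated Lasso logistic feature selection.

    Features are standardized to zero mean / unit sd internally; the
    returned model is re-expressed on the original feature scale.  The
    penalty path is log-spaced from the analytic lambda_max (all
    coefficients zero) downward; ``lambda_rule`` is ``"min"`` (minimum mean
    held-out deviance) or ``"1se"``.
    """
    x_df = pd.DataFrame(features)
    y = np.asarray(labels, dtype=float)
    if x_df.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain both classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 patients per class")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if ids is None:
        ids = np.arange(len(y))
    ids = np.asarray(ids)

    sds = x_df.values.std(axis=0)
    means = x_df.values.mean(axis=0)
    constant = sds <= 1e-12 * np.maximum(1.0, np.abs(means))
    dropped = list(x_df.columns[constant])
    if dropped:
        logger.warning("dropping %d constant feature column(s)", len(dropped))
        x_df = x_df.loc[:, ~constant]
    names = list(x_df.columns)
    xv = x_df.values.astype(float)
    mu = xv.mean(axis=0)
    sd = xv.std(axis=0)
    xs = (xv - mu) / sd
    n, p = xs.shape

    lambda_max = float(np.abs(xs.T @ (y - y.mean())).max() / n)
    if lambda_path is None:
        ratio = lambda_min_ratio if lambda_min_ratio is not None else (0.01 if n < p else 1e-4)
        path = np.geomspace(lambda_max, lambda_max * ratio, n_lambda)
    else:
        path = np.sort(np.asarray(lambda_path, dtype=float))[::-1]

    fold_of = _stratified_folds(ids, y, folds, seed)
    fold_dev = np.zeros((folds, len(path)))  # per-patient mean deviance per fold
    used = np.zeros(folds, dtype=bool)
    for k in range(folds):
        tr, te = fold_of != k, fold_of == k
        if te.sum() == 0 or len(np.unique(y[tr])) < 2:
            continue
        used[k] = True
        lam_max_k = float(np.abs(xs[tr].T @ (y[tr] - y[tr].mean())).max() / tr.sum())
        for li, lam in enumerate(path):
            b0, b = _fit_l1(xs[tr], y[tr], lam, lam_max_k)
            eta = b0 + xs[te] @ b
            fold_dev[k, li] = _deviance(y[te], 1.0 / (1.0 + np.exp(-eta))) / te.sum()

    cvm = fold_dev[used].mean(axis=0)
    cv_dev = cvm
    i_min = int(np.argmin(cvm))  # path is descending: ties pick the sparser model
    if lambda_rule == "1se":
        se_min = fold_dev[used, i_min].std(ddof=1) / np.sqrt(used.sum())
        chosen_i = int(np.flatnonzero(cvm <= cvm[i_min] + se_min)[0])
    elif lambda_rule == "min":
        chosen_i = i_min
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    chosen = float(path[chosen_i])

    b0, b = _fit_l1(xs, y, chosen, lambda_max)
    nz = np.flatnonzero(b != 0.0)
    # back-transform to the original feature scale
    coefs = {names[j]: float(b[j] / sd[j]) for j in nz}
    intercept = float(b0 - sum(b[j] * mu[j] / sd[j] for j in nz))
    model = RadScoreModel(intercept=intercept, coefficients=coefs, standardization=None)
    return SelectionResult(
        lambda_path=path,
        chosen_lambda=chosen,
        cv_folds=folds,
        cv_deviance=cv_dev,
        selected=[names[j] for j in nz],
        model=model,
        seed=seed,
        dropped_constant=dropped,
    )


def score_table(model: RadScoreModel, table: pd.DataFrame) -> pd.Series:
    """Rad-score for every row of a feature table (columns = feature names)."""
    missing = [c for c in model.coefficients if c not in table.columns]
    if missing:
        raise KeyError(f"feature table is missing model features: {missing}")
    scores = pd.Series(model.intercept, index=table.index, dtype=float, name="rad_score")
    for name, coef in model.coefficients.items():
        x = table[name].astype(float)
        if model.standardization and name in model.standardization:
            mu, sd = model.standardization[name]
            x = (x - mu) / sd
        scores = scores + coef * x
    scores.name = "rad_score"
    return scores
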