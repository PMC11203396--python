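"""Signature scores, response classifiers, and cross-cohort benchmarking.

The IOSelect immune score is the ratio of the mean normalized log2 expression
of ten response-associated stromal genes to the mean of eight
resistance-associated genes, capturing the balance of immune-activating and
immune-suppressive signals in the tumor microenvironment. It is combined with
z-scored tumor mutation burden (TMB) in a logistic classifier. Comparator
scores: the cytolytic score (geometric mean of GZMA and PRF1 on the linear TPM
scale) and VIGex (mean of within-cohort z-scored expression of a fixed 12-gene
panel).

A compact model is derived by bootstrap-LASSO stability selection: L1-penalized
logistic regressions on repeated 90% subsamples, with the penalty chosen per
resample by 10-fold cross-validation under the one-standard-error rule, keeping
features selected in at least 75% of resamples.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import RESPONDER, CohortData

logger = logging.getLogger(__name__)

#: response-associated stromal genes (score numerator)
IOSELECT_UP = ["CXCL9", "CXCL13", "IFNG", "KLRD1", "GBP1P1",
               "CRTAM", "FASLG", "GBP5", "CD8A", "PRF1"]
#: resistance-associated stromal genes (score denominator)
IOSELECT_DOWN = ["FCER1A", "PID1", "CH25H", "NPR3", "PREX2",
                 "NPR1", "FAM134B", "SDPR"]
#: VIGex 12-gene panel
VIGEX_GENES = ["CXCL9", "CXCL10", "CXCL11", "IFNG", "PRF1", "IL7R",
               "GZMA", "GZMB", "PDCD1", "CTLA4", "CD274", "FOXP3"]
#: compact model reported by the discovery analysis; re-derivable via
#: lasso_stability_select on suitable training data
COMPACT_FEATURES = ["tmb", "IFNG", "FCER1A"]

_SEPARATION_COEF = 30.0


@dataclass
class ResponseModel:
    """A fitted logistic response classifier plus its preprocessing state."""

    model_id: str
    feature_names: list[str]
    coefficients: dict[str, float]              # includes "intercept"
    standardization: dict[str, tuple[float, float]]  # feature -> (mean, sd)
    score_genes: dict[str, list[str]] = field(default_factory=dict)
    lasso_lambda: float | None = None
    provenance: dict = field(default_factory=dict)

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        X = np.empty((len(features), len(self.feature_names)))
        for j, name in enumerate(self.feature_names):
            x = features[name].to_numpy(float)
            if name in self.standardization:
                mu, sd = self.standardization[name]
                x = (x - mu) / sd
            X[:, j] = x
        return X

    def decision(self, features: pd.DataFrame) -> np.ndarray:
        X = self.transform(features)
        beta = np.array([self.coefficients[n] for n in self.feature_names])
        return self.coefficients["intercept"] + X @ beta

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        z = self.decision(features)
        return pd.Series(1.0 / (1.0 + np.exp(-z)), index=features.index, name=self.model_id)

    def to_json(self, path) -> None:
        payload = {
            "model_id": self.model_id,
            "feature_names": self.feature_names,
            "coefficients": self.coefficients,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "score_genes": self.score_genes,
            "lasso_lambda": self.lasso_lambda,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ResponseModel":
        with open(path) as fh:
            d = json.load(fh)
        d["standardization"] = {k: tuple(v) for k, v in d["standardization"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# signature scores
# ---------------------------------------------------------------------------

def _present(expr: pd.DataFrame, genes: list[str], what: str) -> list[str]:
    present = [g for g in genes if g in expr.index]
    if len(present) < 0.75 * len(genes):
        raise ValueError(
            f"more than 25% of {what} genes absent from expression matrix "
            f"(missing: {sorted(set(genes) - set(present))})"
        )
    return present


def ioselect_score(
    expr: pd.DataFrame,
    up_set: list[str] | None = None,
    down_set: list[str] | None = None,
) -> pd.Series:
    """Per-sample ratio of mean up-set to mean down-set normalized log2
    expression. Samples with a nonpositive down-set mean get NaN with a
    warning (possible near-zero normalized values)."""
    up = _present(expr, up_set or IOSELECT_UP, "up-set")
    down = _present(expr, down_set or IOSELECT_DOWN, "down-set")
    num = expr.loc[up].mean(axis=0)
    den = expr.loc[down].mean(axis=0)
    bad = den <= 0
    if bad.any():
        logger.warning("nonpositive down-set mean for samples: %s", list(expr.columns[bad]))
    score = num / den.where(~bad)
    return score.rename("ioselect")


def cytolytic_score(tpm: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Geometric mean of GZMA and PRF1 on the linear TPM scale."""
    for g in ("GZMA", "PRF1"):
        if g not in tpm.index:
            raise ValueError(f"gene {g!r} absent from expression matrix")
    prod = (tpm.loc["GZMA"] + pseudocount) * (tpm.loc["PRF1"] + pseudocount)
    return np.sqrt(prod).rename("cytolytic")


def vigex_score(expr: pd.DataFrame, genes: list[str] | None = None) -> pd.Series:
    """Mean of per-gene z-scored (within-cohort) expression over the 12-gene
    panel; constant genes are dropped with a warning."""
    genes = genes or VIGEX_GENES
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"VIGex genes absent from expression matrix: {missing}")
    sub = expr.loc[genes].to_numpy(float)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("constant VIGex genes dropped: %s", [g for g, k in zip(genes, keep) if not k])
    z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.Series(z.mean(axis=0), index=expr.columns, name="vigex")


def zscore(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(x - mean) / sd with sample SD (n-1); returns the parameters so test
    cohorts can be standardized with training-set statistics."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (x - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def response_to_binary(labels) -> np.ndarray:
    return (np.asarray(labels) == RESPONDER).astype(int)


def fit_logistic(
    features: pd.DataFrame,
    labels: np.ndarray,
    model_id: str = "logistic",
    standardize: bool = True,
    score_genes: dict[str, list[str]] | None = None,
    provenance: dict | None = None,
) -> ResponseModel:
    """Unpenalized maximum-likelihood logistic regression.

    Features are z-scored with training statistics (stored in the model) when
    ``standardize`` is on. Perfect separation is flagged in ``provenance``
    rather than raised: the capped-iteration fit is returned and AUC remains
    well defined.
    """
    y = np.asarray(labels, int)
    if features.isna().any().any():
        raise ValueError("missing feature values")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")

    standardization: dict[str, tuple[float, float]] = {}
    X = features.to_numpy(float).copy()
    if standardize:
        for j, name in enumerate(features.columns):
            X[:, j], mu, sd = zscore(X[:, j])
            standardization[name] = (mu, sd)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        clf.fit(X, y)

    prov = dict(provenance or {})
    scores = clf.decision_function(X)
    separated = scores[y == 1].min() > scores[y == 0].max()
    if separated or np.abs(clf.coef_).max() > _SEPARATION_COEF:
        prov["separation_flag"] = True
        logger.warning("possible perfect separation in model %s", model_id)

    coefs = {name: float(b) for name, b in zip(features.columns, clf.coef_[0])}
    coefs["intercept"] = float(clf.intercept_[0])
    return ResponseModel(
        model_id=model_id,
        feature_names=list(features.columns),
        coefficients=coefs,
        standardization=standardization,
        score_genes=score_genes or {},
        provenance=prov,
    )


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int, eps: float = 1e-3) -> np.ndarray:
    """glmnet-style grid: lambda_max = max |X'(y - ybar)| / n, descending."""
    n = len(y)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def _l1_fit(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # objective (1/n) sum(loss) + lam * |beta|_1  <=>  sklearn C = 1 / (n * lam)
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (len(y) * lam), solver="liblinear", max_iter=200, tol=1e-3
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def _binomial_deviance(clf: LogisticRegression, X: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    return float(-2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _cv_one_se_lambda(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    cv_folds: int,
    rng_seed: int,
    rule: str = "sd",
) -> float:
    """Largest lambda whose CV deviance is within one SD (default) or one SE
    of the minimum.

    ``rule="sd"`` takes the one-SD band literally (the SD of the per-fold
    deviances at the minimum); ``rule="se"`` divides by sqrt(folds), the
    common cross-validation one-standard-error convention. The SD band is
    wider and hence selects a sparser model.
    """
    folds = min(cv_folds, int(np.bincount(y).min()))
    folds = max(folds, 2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    dev = np.zeros((folds, len(lambdas)))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        for k, lam in enumerate(lambdas):
            clf = _l1_fit(X[tr], y[tr], lam)
            dev[f, k] = _binomial_deviance(clf, X[va], y[va])
    mean = dev.mean(axis=0)
    spread = dev.std(axis=0, ddof=1)
    if rule == "se":
        spread = spread / np.sqrt(folds)
    k_min = int(np.argmin(mean))
    limit = mean[k_min] + spread[k_min]
    # lambdas are descending: the first index within the limit is the largest
    k_sel = int(np.flatnonzero(mean <= limit)[0])
    return float(lambdas[k_sel])


def lasso_stability_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_boot: int = 100,
    frac: float = 0.9,
    min_freq: float = 0.75,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 15,
    resample: str = "subsample",
    rule: str = "sd",
) -> tuple[list[str], pd.Series]:
    """Bootstrap-LASSO stability selection.

    For each of ``n_boot`` resamples of ``ceil(frac * n)`` samples (default:
    subsampling without replacement; ``resample="bootstrap"`` draws with
    replacement), an L1 logistic path is fit, the penalty chosen by
    ``cv_folds``-fold CV as the largest lambda within one SD (``rule="sd"``,
    default) or one SE (``rule="se"``) of the minimum deviance, and the
    nonzero-coefficient features recorded. Returns (features with frequency >= ``min_freq``,
    per-feature selection frequencies). Resamples lacking both classes are
    redrawn (bounded retries).
    """
    y = np.asarray(labels, int)
    X = features.to_numpy(float)
    n = len(y)
    m = ceil(frac * n)
    rng = np.random.default_rng(seed)
    counts = pd.Series(0.0, index=features.columns)

    for b in range(n_boot):
        for _attempt in range(20):
            idx = (
                rng.choice(n, size=m, replace=True)
                if resample == "bootstrap"
                else rng.permutation(n)[:m]
            )
            if 0 < y[idx].sum() < m:
                break
        else:
            raise RuntimeError("could not draw a resample containing both classes")
        Xb, yb = X[idx], y[idx]
        lambdas = _lambda_grid(Xb, yb, n_lambda)
        lam = _cv_one_se_lambda(
            Xb, yb, lambdas, cv_folds, rng_seed=int(rng.integers(2**31)), rule=rule
        )
        clf = _l1_fit(Xb, yb, lam)
        counts[np.abs(clf.coef_[0]) > 0] += 1.0

    freq = counts / n_boot
    # min_freq = 0 means "everything ever selected", not "everything"
    selected = freq.index[(freq >= min_freq) & (freq > 0)].tolist()
    return selected, freq


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: probability a random positive outranks a random
    negative, ties counted 1/2."""
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compare_models_paired(
    auc_a: pd.Series, auc_b: pd.Series
) -> tuple[float, float, bool]:
    """Paired t-test on per-cohort AUC differences.

    Returns (mean difference, two-sided p, degenerate flag). Zero-variance
    differences make the t statistic undefined; the flag is set and p is 1.0
    when the difference is identically 0, NaN otherwise.
    """
    if set(auc_a.index) != set(auc_b.index):
        raise ValueError("mismatched cohort sets")
    if len(auc_a) < 2:
        raise ValueError("need at least 2 cohorts")
    diffs = (auc_a - auc_b.loc[auc_a.index]).to_numpy(float)
    mean_diff = float(diffs.mean())
    if np.allclose(diffs.std(ddof=1), 0.0):
        return mean_diff, (1.0 if np.allclose(diffs, 0.0) else float("nan")), True
    t = sps.ttest_rel(auc_a.to_numpy(float), auc_b.loc[auc_a.index].to_numpy(float))
    return mean_diff, float(t.pvalue), False


def ioselect_tmb_features(
    cohort: CohortData,
    up_set: list[str] | None = None,
    down_set: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample (ioselect, tmb) feature table for one normalized cohort."""
    if cohort.tmb is None:
        raise ValueError(f"cohort {cohort.cohort_id!r} has no TMB")
    return pd.DataFrame(
        {
            "ioselect": ioselect_score(cohort.expression, up_set, down_set),
            "tmb": cohort.tmb,
        }
    )


def train_ioselect_classifier(
    cohorts: list[CohortData],
    up_set: list[str] | None = None,
    down_set: list[str] | None = None,
    features: list[str] = ("ioselect", "tmb"),
    model_id: str = "ioselect_tmb",
) -> ResponseModel:
    """Pool training cohorts, build (ioselect, tmb) features, fit logistic."""
    tables, ys = [], []
    for c in cohorts:
        tables.append(ioselect_tmb_features(c, up_set, down_set)[list(features)])
        ys.append(response_to_binary(c.response))
    X = pd.concat(tables)
    y = np.concatenate(ys)
    ok = X.notna().all(axis=1).to_numpy()
    model = fit_logistic(
        X[ok], y[ok], model_id=model_id,
        score_genes={"up_set": list(up_set or IOSELECT_UP), "down_set": list(down_set or IOSELECT_DOWN)},
        provenance={"training_cohorts": [c.cohort_id for c in cohorts]},
    )
    return model


def evaluate_on_cohort(
    model: ResponseModel,
    cohort: CohortData,
    up_set: list[str] | None = None,
    down_set: list[str] | None = None,
) -> float:
    """Held-out AUC of a fitted classifier on one cohort."""
    feats = ioselect_tmb_features(cohort, up_set, down_set)[model.feature_names]
    ok = feats.notna().all(axis=1).to_numpy()
    scores = model.decision(feats[ok])
    return auc(scores, response_to_binary(cohort.response)[ok])
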