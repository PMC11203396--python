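"""Per-gene NNLS deconvolution of bulk expression into compartment means.

Bulk expression of a gene in sample *i* is modeled as a purity-weighted sum of
two compartment means,

    e_i = p_i * c + (1 - p_i) * s + eps_i,      c, s >= 0,

where ``p_i`` is the tumor purity (cancer-cell fraction), ``c`` the mean
cancer-compartment expression and ``s`` the mean stromal expression, on
whatever scale the expression vector is supplied (the pipeline convention is
normalized log2 expression). The model has no separate intercept: the two
design columns ``p`` and ``1 - p`` sum to one. Non-negative least squares
estimates (c, s); the standard error of the fitted compartment mean is the
predicted-mean SE of the regression line at purity 1 (cancer) or 0 (stroma):

    SE_h = sqrt( MSE * ( 1/n + (p_h - p_bar)^2 / sum_i (p_i - p_bar)^2 ) )

with MSE = RSS / (n - 2) by default (two estimated parameters; divisor
configurable). When the non-negativity constraint is active the SE formula is
still reported (it assumes an unconstrained fit) and the ``clamped`` flag is
set — downstream inference is carried by the permutation test, not the SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .cohort import CohortData

CANCER = "cancer"
STROMA = "stroma"
COMPARTMENTS = (CANCER, STROMA)

_DEGENERACY_TOL = 1e-12


class UnidentifiableGeneError(ValueError):
    """Purity carries no information (all values equal): the two compartment
    means are confounded with the sample mean and cannot be separated."""


@dataclass
class DeconvolutionFit:
    """NNLS compartment-mean estimates for one gene in one sample group."""

    gene_id: str
    cancer_mean: float
    stroma_mean: float
    cancer_se: float
    stroma_se: float
    mse: float
    n_samples: int
    mean_purity: float
    clamped: str = "none"  # none | cancer_at_zero | stroma_at_zero

    def mean(self, compartment: str) -> float:
        return self.cancer_mean if compartment == CANCER else self.stroma_mean

    def se(self, compartment: str) -> float:
        return self.cancer_se if compartment == CANCER else self.stroma_se

    def predicted(self, p: float) -> float:
        """Fitted bulk value at purity ``p``."""
        return p * self.cancer_mean + (1.0 - p) * self.stroma_mean


def _check_identifiable(p: np.ndarray) -> None:
    if p.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(p) < _DEGENERACY_TOL:
        raise UnidentifiableGeneError(
            "all purities equal: compartment means are not identifiable"
        )


def compartment_se(mse: float, p: np.ndarray, p_h: float) -> float:
    """Predicted-mean standard error at purity ``p_h`` (1=cancer, 0=stroma)."""
    p = np.asarray(p, float)
    n = p.size
    pbar = p.mean()
    sxx = float(((p - pbar) ** 2).sum())
    if sxx < _DEGENERACY_TOL:
        raise UnidentifiableGeneError("zero purity spread: SE undefined")
    return float(np.sqrt(mse * (1.0 / n + (p_h - pbar) ** 2 / sxx)))


def fit_gene(
    e: np.ndarray, p: np.ndarray, gene_id: str = "", mse_divisor: str = "n-2"
) -> DeconvolutionFit:
    """NNLS fit of one gene's expression on purity.

    ``mse_divisor`` is ``"n-2"`` (default, unbiased for the unconstrained
    two-parameter fit) or ``"n"``.
    """
    e = np.asarray(e, float)
    p = np.asarray(p, float)
    if e.shape != p.shape:
        raise ValueError("expression and purity must have equal length")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("purity must lie in [0, 1]")
    _check_identifiable(p)
    n = e.size

    X = np.column_stack([p, 1.0 - p])
    (c, s), _ = _scipy_nnls(X, e)

    # active-constraint flag from the unconstrained solution
    coef_u, *_ = np.linalg.lstsq(X, e, rcond=None)
    clamped = "none"
    if coef_u[0] < 0 and c <= _DEGENERACY_TOL:
        clamped = "cancer_at_zero"
    elif coef_u[1] < 0 and s <= _DEGENERACY_TOL:
        clamped = "stroma_at_zero"

    resid = e - X @ np.array([c, s])
    rss = float(resid @ resid)
    denom = n - 2 if mse_divisor == "n-2" else n
    mse = rss / denom if denom > 0 else (0.0 if rss < 1e-10 else rss)
    mse = max(mse, 0.0)
    return DeconvolutionFit(
        gene_id=gene_id,
        cancer_mean=float(c),
        stroma_mean=float(s),
        cancer_se=compartment_se(mse, p, 1.0),
        stroma_se=compartment_se(mse, p, 0.0),
        mse=mse,
        n_samples=n,
        mean_purity=float(p.mean()),
        clamped=clamped,
    )


def batch_nnls(E: np.ndarray, p: np.ndarray, ddof: int = 2) -> dict[str, np.ndarray]:
    """Vectorized NNLS over all genes at once (rows of ``E``) for one purity
    vector.

    The two-parameter problem is solved in closed form from the normal
    equations; when a coefficient goes negative the two single-compartment
    clamped candidates are compared by residual sum of squares and the better
    one taken (the exact NNLS solution for two nonnegative coefficients).

    Returns arrays ``cancer``, ``stroma``, ``cancer_se``, ``stroma_se``,
    ``mse``, ``clamped`` (int8: 0 none, 1 cancer at 0, 2 stroma at 0).
    """
    E = np.atleast_2d(np.asarray(E, float))
    p = np.asarray(p, float)
    _check_identifiable(p)
    n = p.size
    q = 1.0 - p

    a11 = float(p @ p)
    a12 = float(p @ q)
    a22 = float(q @ q)
    det = a11 * a22 - a12 * a12
    if det < _DEGENERACY_TOL:
        raise UnidentifiableGeneError("collinear design: purity has no spread")

    b1 = E @ p
    b2 = E @ q
    e2 = np.einsum("ij,ij->i", E, E)

    def sse(c: np.ndarray, s: np.ndarray) -> np.ndarray:
        return np.maximum(
            e2 - 2 * c * b1 - 2 * s * b2 + c * c * a11 + 2 * c * s * a12 + s * s * a22, 0.0
        )

    c_u = (a22 * b1 - a12 * b2) / det
    s_u = (a11 * b2 - a12 * b1) / det

    c = c_u.copy()
    s = s_u.copy()
    clamped = np.zeros(E.shape[0], dtype=np.int8)
    neg = (c_u < 0) | (s_u < 0)
    if neg.any():
        c1 = np.zeros(neg.sum())                      # cancer clamped at 0
        s1 = np.maximum(b2[neg] / a22, 0.0)
        s2 = np.zeros(neg.sum())                      # stroma clamped at 0
        c2 = np.maximum(b1[neg] / a11, 0.0)
        # evaluate candidate SSEs on the restricted rows
        e2n, b1n, b2n = e2[neg], b1[neg], b2[neg]

        def sse_n(cc, ss):
            return np.maximum(
                e2n - 2 * cc * b1n - 2 * ss * b2n + cc * cc * a11 + 2 * cc * ss * a12 + ss * ss * a22,
                0.0,
            )

        pick1 = sse_n(c1, s1) <= sse_n(c2, s2)
        c[neg] = np.where(pick1, c1, c2)
        s[neg] = np.where(pick1, s1, s2)
        clamped[neg] = np.where(pick1, 1, 2)

    rss = sse(c, s)
    denom = n - ddof
    if denom > 0:
        mse = rss / denom
    else:
        mse = np.where(rss < 1e-10, 0.0, rss)

    pbar = p.mean()
    sxx = a11 - n * pbar * pbar  # = sum (p - pbar)^2
    cancer_se = np.sqrt(mse * (1.0 / n + (1.0 - pbar) ** 2 / sxx))
    stroma_se = np.sqrt(mse * (1.0 / n + pbar**2 / sxx))
    return {
        "cancer": c,
        "stroma": s,
        "cancer_se": cancer_se,
        "stroma_se": stroma_se,
        "mse": mse,
        "clamped": clamped,
        "n": n,
        "mean_purity": pbar,
    }


def deconvolve_group(
    cohort: CohortData,
    sample_mask: np.ndarray | None = None,
    group: str | None = None,
    mse_divisor: str = "n-2",
) -> pd.DataFrame:
    """Fit every gene over a subset of a cohort's samples.

    Select samples either with a boolean ``sample_mask`` or with
    ``group in {"responder", "nonresponder", "all"}``. Genes whose retained
    samples leave no purity spread are carried as all-NaN rows (never silently
    dropped). Samples with missing expression are dropped pairwise per gene.
    """
    if group is not None:
        if group == "all":
            sample_mask = np.ones(cohort.n_samples, dtype=bool)
        else:
            sample_mask = (cohort.response == group).to_numpy()
    if sample_mask is None:
        sample_mask = np.ones(cohort.n_samples, dtype=bool)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    if sample_mask.sum() == 0:
        raise ValueError("empty sample selection")
    if sample_mask.sum() < 2:
        raise ValueError("need at least 2 samples per group")

    E = cohort.expression.to_numpy(float)[:, sample_mask]
    p = cohort.purity.to_numpy(float)[sample_mask]
    genes = cohort.gene_ids
    ddof = 2 if mse_divisor == "n-2" else 0

    out = pd.DataFrame(
        index=pd.Index(genes, name="gene_id"),
        columns=["cancer_mean", "cancer_se", "stroma_mean", "stroma_se",
                 "mse", "n", "mean_purity", "clamped"],
        dtype=object,
    )
    complete = np.isfinite(E).all(axis=1)
    if complete.any():
        res = batch_nnls(E[complete], p, ddof=ddof)
        idx = np.flatnonzero(complete)
        out.iloc[idx, 0] = res["cancer"]
        out.iloc[idx, 1] = res["cancer_se"]
        out.iloc[idx, 2] = res["stroma"]
        out.iloc[idx, 3] = res["stroma_se"]
        out.iloc[idx, 4] = res["mse"]
        out.iloc[idx, 5] = res["n"]
        out.iloc[idx, 6] = res["mean_purity"]
        out.iloc[idx, 7] = np.array(["none", "cancer_at_zero", "stroma_at_zero"])[res["clamped"]]
    for i in np.flatnonzero(~complete):
        ok = np.isfinite(E[i])
        try:
            fit = fit_gene(E[i, ok], p[ok], gene_id=genes[i], mse_divisor=mse_divisor)
        except (ValueError, UnidentifiableGeneError):
            continue  # left as NaN marker row
        out.iloc[i] = [fit.cancer_mean, fit.cancer_se, fit.stroma_mean, fit.stroma_se,
                       fit.mse, fit.n_samples, fit.mean_purity, fit.clamped]
    for col in out.columns[:-1]:
        out[col] = pd.to_numeric(out[col])
    return out


def compartment_log2fc(
    fit_a: DeconvolutionFit | None, fit_b: DeconvolutionFit | None, compartment: str
) -> float:
    """Group A minus group B compartment mean on the normalized log2 scale.

    A difference of log2-scale compartment means is reported as a log2 fold
    change; a missing fit on either side yields NaN.
    """
    if fit_a is None or fit_b is None:
        return float("nan")
    return fit_a.mean(compartment) - fit_b.mean(compartment)
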