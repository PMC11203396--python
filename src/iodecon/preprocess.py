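"""Normalization, gene filtering, label mapping, and consensus purity.

Expression from heterogeneous sources (raw counts, FPKM, TPM) is brought onto
a common analysis scale: TPM -> log2(TPM + pseudocount) -> upper-quartile
normalization (each sample shifted on the log scale so its 75th-percentile
expression over nonzero genes matches the cross-sample mean of those
percentiles). Genes with zeros in more than half the samples are removed
before analysis. RECIST categories map CR/PR -> responder, SD/PD ->
nonresponder. Purity estimates from several methods are quantile-quantile
normalized to a common reference distribution and averaged into a consensus.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import NONRESPONDER, RESPONDER, SCALE_LOG2, CohortData

logger = logging.getLogger(__name__)

RECIST_MAP = {"CR": RESPONDER, "PR": RESPONDER, "SD": NONRESPONDER, "PD": NONRESPONDER}


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Convert raw read counts to TPM given per-gene lengths in kilobases.

    Per sample: rate_g = counts_g / length_g; TPM_g = rate_g / sum(rates) * 1e6.
    All-zero samples are left all-zero with a warning.
    """
    lengths = gene_lengths.loc[counts.index].to_numpy(float)
    if (lengths <= 0).any():
        bad = counts.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene length for: {bad}")
    rates = counts.to_numpy(float) / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("all-zero samples left unscaled: %s", list(counts.columns[zero]))
        totals = np.where(zero, 1.0, totals)
    return pd.DataFrame(rates / totals * 1e6, index=counts.index, columns=counts.columns)


def fpkm_to_tpm(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Convert FPKM to TPM: per sample, TPM_g = FPKM_g / sum(FPKM) * 1e6."""
    x = fpkm.to_numpy(float)
    if (x < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    totals = x.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("all-zero samples left unscaled: %s", list(fpkm.columns[zero]))
        totals = np.where(zero, 1.0, totals)
    return pd.DataFrame(x / totals * 1e6, index=fpkm.index, columns=fpkm.columns)


def filter_genes(matrix: pd.DataFrame, max_zero_fraction: float = 0.5) -> tuple[pd.DataFrame, list[str]]:
    """Keep genes whose zero fraction is <= ``max_zero_fraction`` (order kept).

    A gene with zeros in *more than* the threshold fraction of samples is
    removed; a gene exactly at the threshold is kept.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be in [0, 1]")
    zero_frac = (matrix == 0).sum(axis=1) / matrix.shape[1]
    kept = matrix.index[zero_frac <= max_zero_fraction].tolist()
    return matrix.loc[kept], kept


def log2_upper_quantile_normalize(
    tpm: pd.DataFrame, pseudocount: float = 1.0, quantile: float = 0.75
) -> pd.DataFrame:
    """log2(TPM + pseudocount), then per-sample upper-quartile alignment.

    Each sample's log2 values are shifted (a multiplicative rescaling on the
    linear scale) so that its ``quantile``-th percentile over genes with
    nonzero TPM equals the cross-sample mean of those percentiles.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = tpm.to_numpy(float)
    if (x < 0).any():
        raise ValueError("TPM values must be nonnegative")
    log2x = np.log2(x + pseudocount)
    q = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        nz = x[:, j] > 0
        if not nz.any():
            raise ValueError(f"sample {tpm.columns[j]!r} has no nonzero gene")
        q[j] = np.quantile(log2x[nz, j], quantile)
    shifted = log2x + (q.mean() - q)[None, :]
    return pd.DataFrame(shifted, index=tpm.index, columns=tpm.columns)


def normalize_cohort(
    cohort: CohortData,
    pseudocount: float = 1.0,
    quantile: float = 0.75,
    max_zero_fraction: float = 0.5,
) -> CohortData:
    """Gene-filter and log2/upper-quartile normalize a TPM-scale cohort."""
    if cohort.scale == SCALE_LOG2:
        return cohort
    filtered, _kept = filter_genes(cohort.expression, max_zero_fraction)
    normed = log2_upper_quantile_normalize(filtered, pseudocount=pseudocount, quantile=quantile)
    return CohortData(
        cohort_id=cohort.cohort_id,
        expression=normed,
        purity=cohort.purity,
        response=cohort.response,
        cohort_class=cohort.cohort_class,
        tmb=cohort.tmb,
        scale=SCALE_LOG2,
        true_response=cohort.true_response,
        premix=cohort.premix,
    )


def consensus_purity(estimates: pd.DataFrame) -> pd.Series:
    """Consensus purity from a method x sample table of estimates.

    Each method's estimates are quantile-normalized against a reference
    distribution (the per-rank mean over methods, built on samples covered by
    every method); methods reporting samples outside the shared set are mapped
    by interpolation of their empirical quantiles. The consensus is the
    per-sample mean of normalized estimates over methods reporting that
    sample, clipped to [0, 1].
    """
    if estimates.shape[0] < 1:
        raise ValueError("at least one purity method required")
    no_cov = estimates.columns[estimates.isna().all(axis=0)].tolist()
    if no_cov:
        raise ValueError(f"samples with no purity estimate from any method: {no_cov}")
    if estimates.shape[0] == 1:
        return estimates.iloc[0].clip(0.0, 1.0)

    shared = estimates.columns[estimates.notna().all(axis=0)]
    if len(shared) >= 2:
        ref = np.sort(estimates[shared].to_numpy(float), axis=1).mean(axis=0)
    else:
        # no usable shared-sample reference: fall back to pooled values
        pooled = estimates.to_numpy(float)
        ref = np.sort(pooled[np.isfinite(pooled)])
    ref_grid = np.linspace(0.0, 1.0, len(ref))

    normalized = pd.DataFrame(np.nan, index=estimates.index, columns=estimates.columns)
    for method in estimates.index:
        vals = estimates.loc[method].dropna()
        if len(vals) < 2:
            normalized.loc[method, vals.index] = vals  # passed through
            continue
        order = vals.rank(method="average").to_numpy() - 1.0
        frac = order / (len(vals) - 1.0)
        normalized.loc[method, vals.index] = np.interp(frac, ref_grid, ref)
    return normalized.mean(axis=0).clip(0.0, 1.0)


def classify_response(recist: pd.Series) -> pd.Series:
    """Map RECIST categories (case-insensitive) to responder/nonresponder."""
    upper = recist.astype(str).str.strip().str.upper()
    unknown = sorted(set(upper) - set(RECIST_MAP))
    if unknown:
        raise ValueError(f"unrecognized RECIST labels: {unknown}")
    return upper.map(RECIST_MAP).rename("response")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
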