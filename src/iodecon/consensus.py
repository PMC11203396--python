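"""Cross-cohort consensus DEG calls and the ligand-receptor coordination survey.

Per-cohort permutation p-values for each gene x compartment are combined with
Fisher's method (X = -2 * sum(ln p_k) ~ chi-square with 2K df under the null)
and Bonferroni-adjusted within each compartment family. A gene survives into
the consensus list only if (i) its adjusted q-value is at or below alpha,
(ii) no two cohorts support opposite directions at the nominal threshold
(p < 0.1), and (iii) at least one clinically annotated ICB cohort supports the
consensus direction at that nominal threshold — the guard against signals
driven purely by the responder-enriched proxy cohorts (e.g. MSI biology rather
than checkpoint-blockade response).

The ligand-receptor survey asks, for curated immune-checkpoint and cytokine
pairs, whether ligand and receptor change coordinately in the same compartment
across the ICB cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .deconvolve import COMPARTMENTS

NOMINAL_P = 0.1  # the only nominal per-cohort threshold used by the filters


@dataclass
class LigandReceptorPair:
    ligand_gene: str
    receptor_gene: str
    interaction_class: str  # activating | inhibitory
    annotation: str = ""
    source_set: str = "checkpoint"  # checkpoint | cytokine

    def __post_init__(self) -> None:
        if self.ligand_gene == self.receptor_gene:
            raise ValueError("ligand and receptor must differ")


def fisher_combine(pvals) -> float:
    """Fisher's combined p: upper tail of chi-square(2K) at -2*sum(ln p)."""
    p = np.asarray([v for v in pvals if np.isfinite(v)], float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        raise ValueError(
            "p-value of 0 cannot be combined; use the add-one permutation "
            "p-value convention upstream"
        )
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(x, df=2 * p.size))


def bonferroni_adjust(
    meta_ps: np.ndarray, alpha: float = 0.01, m: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """q = min(1, p * m) and the significance calls at ``alpha``.

    ``m`` defaults to the number of tests supplied (the family size).
    """
    meta_ps = np.asarray(meta_ps, float)
    if m is None:
        m = meta_ps.size
    q = np.minimum(1.0, meta_ps * m)
    return q, q <= alpha


def consensus_direction(log2fcs: np.ndarray, pvals: np.ndarray) -> int:
    """Sign of the p-weighted majority of per-cohort log2FC signs (0 = tie)."""
    ok = np.isfinite(log2fcs) & np.isfinite(pvals)
    if not ok.any():
        return 0
    w = -np.log10(np.clip(pvals[ok], 1e-300, 1.0))
    score = float((np.sign(log2fcs[ok]) * w).sum())
    return int(np.sign(score))


def direction_conflict(
    log2fcs: np.ndarray, pvals: np.ndarray, per_cohort_threshold: float = NOMINAL_P
) -> bool:
    """True iff supporting cohorts (p < threshold) exist in both directions."""
    ok = np.isfinite(log2fcs) & np.isfinite(pvals)
    support = ok & (pvals < per_cohort_threshold)
    return bool((support & (log2fcs > 0)).any() and (support & (log2fcs < 0)).any())


def icb_support(
    log2fcs: np.ndarray,
    pvals: np.ndarray,
    is_icb: np.ndarray,
    direction: int,
    threshold: float = NOMINAL_P,
) -> bool:
    """True iff some ICB cohort has p < threshold with log2FC matching the
    consensus direction."""
    if direction == 0:
        return False
    ok = np.isfinite(log2fcs) & np.isfinite(pvals) & is_icb
    return bool((ok & (pvals < threshold) & (np.sign(log2fcs) == direction)).any())


def build_consensus(
    tables: Mapping[str, pd.DataFrame],
    icb_cohort_ids: list[str],
    alpha: float = 0.01,
    per_cohort_threshold: float = NOMINAL_P,
    family: str = "per_compartment",
    min_cohorts: int = 2,
) -> pd.DataFrame:
    """Combine per-cohort DE tables into consensus records for both
    compartments.

    ``tables`` maps cohort_id to a table from :func:`iodecon.perm_de.cohort_de`
    (columns gene_id, compartment, delta, p_value). The gene universe is the
    intersection across cohorts; per gene, cohorts with missing results are
    skipped (Fisher K reduced) and genes observed in fewer than ``min_cohorts``
    cohorts are dropped. The Bonferroni family is the number of genes tested
    within each compartment (``family="joint"`` doubles it).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 cohorts")
    missing_icb = [c for c in icb_cohort_ids if c not in tables]
    if missing_icb:
        raise ValueError(f"icb cohorts absent from tables: {missing_icb}")
    cohort_ids = list(tables)
    is_icb = np.array([c in set(icb_cohort_ids) for c in cohort_ids])

    universes = [set(t["gene_id"]) for t in tables.values()]
    genes = sorted(set.intersection(*universes))
    if not genes:
        raise ValueError("empty gene intersection across cohorts")

    records = []
    for comp in COMPARTMENTS:
        lfc = np.full((len(genes), len(cohort_ids)), np.nan)
        pv = np.full((len(genes), len(cohort_ids)), np.nan)
        for j, cid in enumerate(cohort_ids):
            t = tables[cid]
            sub = t[t["compartment"] == comp].set_index("gene_id")
            sub = sub.reindex(genes)
            lfc[:, j] = sub["delta"].to_numpy(float)
            pv[:, j] = sub["p_value"].to_numpy(float)

        n_obs = np.isfinite(pv).sum(axis=1)
        tested = n_obs >= min_cohorts
        meta_p = np.full(len(genes), np.nan)
        for i in np.flatnonzero(tested):
            meta_p[i] = fisher_combine(pv[i, np.isfinite(pv[i])])

        m = int(tested.sum()) * (2 if family == "joint" else 1)
        q = np.full(len(genes), np.nan)
        q[tested], _ = bonferroni_adjust(meta_p[tested], alpha=alpha, m=m)

        for i, g in enumerate(genes):
            if not tested[i]:
                continue
            direction = consensus_direction(lfc[i], pv[i])
            conflict = direction_conflict(lfc[i], pv[i], per_cohort_threshold) or direction == 0
            supported = icb_support(lfc[i], pv[i], is_icb, direction, per_cohort_threshold)
            rec = {
                "gene_id": g,
                "compartment": comp,
                "meta_p": meta_p[i],
                "q_value": q[i],
                "direction": direction,
                "direction_conflict": conflict,
                "icb_supported": supported,
                "significant": bool(q[i] <= alpha) and not conflict and supported,
                "n_cohorts": int(n_obs[i]),
            }
            for j, cid in enumerate(cohort_ids):
                rec[f"log2fc_{cid}"] = lfc[i, j]
                rec[f"p_{cid}"] = pv[i, j]
            records.append(rec)

    out = pd.DataFrame.from_records(records)
    return out.sort_values(["compartment", "meta_p"], kind="stable").reset_index(drop=True)


def ligand_receptor_survey(
    pairs: pd.DataFrame,
    tables: Mapping[str, pd.DataFrame],
    icb_cohort_ids: list[str],
    min_cohorts: int = 3,
    threshold: float = NOMINAL_P,
) -> pd.DataFrame:
    """Coordination of ligand-receptor pairs across the ICB cohorts.

    Per gene and compartment, the consensus signed evidence is the median over
    ICB cohorts of sign(log2FC) * (-log10 p), reported only when the gene has
    p < ``threshold`` in at least ``min_cohorts`` ICB cohorts. A pair is
    *coordinated* in a compartment when both genes qualify there with the same
    evidence sign. Pair genes absent from the tables are flagged, not fatal.
    """
    icb = [c for c in icb_cohort_ids if c in tables]
    if not icb:
        raise ValueError("no ICB cohorts present in tables")

    def gene_evidence(gene: str, comp: str) -> tuple[float, bool, bool]:
        lfcs, ps = [], []
        present = False
        for cid in icb:
            t = tables[cid]
            row = t[(t["gene_id"] == gene) & (t["compartment"] == comp)]
            if row.empty or not np.isfinite(row["p_value"].iloc[0]):
                continue
            present = True
            lfcs.append(float(row["delta"].iloc[0]))
            ps.append(float(row["p_value"].iloc[0]))
        if not present:
            return np.nan, False, True
        lfcs_a, ps_a = np.array(lfcs), np.array(ps)
        qualified = int((ps_a < threshold).sum()) >= min_cohorts
        evidence = float(np.median(np.sign(lfcs_a) * (-np.log10(np.clip(ps_a, 1e-300, 1.0)))))
        return evidence, qualified, False

    rows = []
    for _, pr in pairs.iterrows():
        for comp in COMPARTMENTS:
            le, lq, lmiss = gene_evidence(pr["ligand"], comp)
            re_, rq, rmiss = gene_evidence(pr["receptor"], comp)
            coordinated = (
                lq and rq and np.sign(le) != 0 and np.sign(le) == np.sign(re_)
            )
            rows.append(
                {
                    "ligand": pr["ligand"],
                    "receptor": pr["receptor"],
                    "interaction_class": pr.get("interaction_class", ""),
                    "source_set": pr.get("source_set", ""),
                    "compartment": comp,
                    "ligand_evidence": le if lq else np.nan,
                    "receptor_evidence": re_ if rq else np.nan,
                    "ligand_qualified": lq,
                    "receptor_qualified": rq,
                    "gene_missing": lmiss or rmiss,
                    "coordinated": bool(coordinated),
                }
            )
    return pd.DataFrame(rows)


def read_lr_pairs(path) -> pd.DataFrame:
    """Read a ligand-receptor pair table (TSV: ligand, receptor,
    interaction_class, annotation, source_set)."""
    df = pd.read_csv(path, sep="\t")
    required = {"ligand", "receptor"}
    if not required <= set(df.columns):
        raise ValueError(f"pair table must have columns {sorted(required)}")
    for _, row in df.iterrows():
        LigandReceptorPair(
            ligand_gene=row["ligand"],
            receptor_gene=row["receptor"],
            interaction_class=row.get("interaction_class", ""),
            annotation=row.get("annotation", ""),
            source_set=row.get("source_set", "checkpoint"),
        )
    return df


def default_pairs(source_set: str = "checkpoint") -> pd.DataFrame:
    """Bundled starter pair tables (user-editable curated lists)."""
    name = {"checkpoint": "checkpoint_pairs.tsv", "cytokine": "cytokine_pairs.tsv"}[source_set]
    with resources.as_file(resources.files("iodecon.data") / name) as path:
        return read_lr_pairs(path)
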