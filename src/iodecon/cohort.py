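"""Shared cohort container and its on-disk layout.

A *cohort* bundles everything the compartment-resolved analysis needs for one
patient series: a gene x sample expression matrix, per-sample tumor purity
(the mixing weight of the cancer compartment), binary response labels, optional
tumor mutation burden (TMB, mutations/Mb), and the cohort class — ``icb`` for
cohorts with clinically annotated checkpoint-blockade response, ``proxy`` for
responder-enriched surrogate cohorts (e.g. MSI vs MSS tumors).

On disk a cohort is a directory of plain TSV/JSON files::

    expression.tsv   genes x samples (first column = gene id)
    samples.tsv      sample_id, purity, response, tmb, cohort_class
    cohort.json      cohort_id, cohort_class, scale
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RESPONDER = "responder"
NONRESPONDER = "nonresponder"

#: expression scale tags
SCALE_TPM = "tpm"      # linear transcripts-per-million
SCALE_LOG2 = "log2"    # log2(TPM + pseudocount), upper-quartile normalized


@dataclass
class CohortData:
    """One cohort's expression, purity, labels and (optional) TMB.

    ``true_response`` and ``premix`` are synthetic-only diagnostics filled in by
    the study generator: the latent response driving the expression signal, and
    the pre-TPM-rescaling linear two-compartment mixture used by ground-truth
    recovery oracles. They are never written to or read from disk.
    """

    cohort_id: str
    expression: pd.DataFrame            # genes x samples
    purity: pd.Series                   # per sample, in [0, 1]
    response: pd.Series                 # values in {responder, nonresponder}
    cohort_class: str = "icb"           # "icb" | "proxy"
    tmb: pd.Series | None = None        # mutations/Mb
    scale: str = SCALE_LOG2
    true_response: pd.Series | None = field(default=None, repr=False)
    premix: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.expression.index.name = "gene_id"
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        samples = list(self.expression.columns)
        for name, series in (("purity", self.purity), ("response", self.response)):
            if list(series.index) != samples:
                raise ValueError(
                    f"{name} index does not match expression columns in cohort "
                    f"{self.cohort_id!r}"
                )
        p = self.purity.to_numpy(float)
        if np.isnan(p).any():
            raise ValueError(f"missing purity values in cohort {self.cohort_id!r}")
        if (p < 0).any() or (p > 1).any():
            raise ValueError(f"purity outside [0, 1] in cohort {self.cohort_id!r}")
        groups = set(self.response)
        if not groups <= {RESPONDER, NONRESPONDER}:
            raise ValueError(f"unrecognized response labels: {groups - {RESPONDER, NONRESPONDER}}")
        if len(groups) < 2:
            raise ValueError(f"cohort {self.cohort_id!r} has an empty response group")
        if self.cohort_class not in ("icb", "proxy"):
            raise ValueError(f"cohort_class must be 'icb' or 'proxy', got {self.cohort_class!r}")
        if self.tmb is not None and list(self.tmb.index) != samples:
            raise ValueError(f"tmb index does not match expression columns in {self.cohort_id!r}")

    # -- conveniences ------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def responder_mask(self) -> np.ndarray:
        return (self.response == RESPONDER).to_numpy()

    def subset(self, sample_ids: list[str]) -> "CohortData":
        """A new cohort restricted to ``sample_ids`` (order preserved)."""
        return CohortData(
            cohort_id=self.cohort_id,
            expression=self.expression[sample_ids],
            purity=self.purity.loc[sample_ids],
            response=self.response.loc[sample_ids],
            cohort_class=self.cohort_class,
            tmb=None if self.tmb is None else self.tmb.loc[sample_ids],
            scale=self.scale,
            true_response=None if self.true_response is None else self.true_response.loc[sample_ids],
            premix=None if self.premix is None else self.premix[sample_ids],
        )

    # -- I/O ---------------------------------------------------------------
    def write_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(path / "expression.tsv", sep="\t", index_label="gene_id")
        meta = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "purity": self.purity.to_numpy(),
                "response": self.response.to_numpy(),
                "tmb": np.nan if self.tmb is None else self.tmb.to_numpy(),
                "cohort_class": self.cohort_class,
            }
        )
        meta.to_csv(path / "samples.tsv", sep="\t", index=False)
        (path / "cohort.json").write_text(
            json.dumps(
                {"cohort_id": self.cohort_id, "cohort_class": self.cohort_class, "scale": self.scale},
                indent=2,
            )
        )
        return path

    @classmethod
    def read_dir(cls, path: str | Path) -> "CohortData":
        path = Path(path)
        info = json.loads((path / "cohort.json").read_text())
        expr = pd.read_csv(path / "expression.tsv", sep="\t", index_col="gene_id")
        meta = pd.read_csv(path / "samples.tsv", sep="\t").set_index("sample_id")
        meta = meta.loc[list(expr.columns)]
        tmb = meta["tmb"] if "tmb" in meta and meta["tmb"].notna().all() else None
        return cls(
            cohort_id=info["cohort_id"],
            expression=expr,
            purity=meta["purity"],
            response=meta["response"],
            cohort_class=info["cohort_class"],
            tmb=tmb,
            scale=info.get("scale", SCALE_LOG2),
        )
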