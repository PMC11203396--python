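"""Multi-cohort synthetic studies with known compartment-specific ground truth.

The generator inverts the two-compartment mixing model that the analysis
estimates: for each gene and sample, linear-scale bulk expression is

    bulk = purity * 2**cancer_log2_mean + (1 - purity) * 2**stroma_log2_mean

times multiplicative noise ``2**Normal(0, noise_sd)``, then rescaled per sample
to the TPM convention (columns sum to 1e6). Response-associated effects are
planted in log2 units: a *stroma-shared* signal applied identically in every
cohort, and *cancer-compartment* signals each confined to a single cohort —
the structure whose downstream consequence (stromal consensus DEGs recoverable
across cohorts, cancer signals diluted away by meta-analysis) the pipeline is
designed to measure.

Two cohort classes are emulated: ``icb`` cohorts whose observed labels are the
true responses, and ``proxy`` cohorts (MSI-like responder-enriched series)
whose "responder" label contains true responders only at rate
``proxy_fidelity`` (clinically, roughly 30-50% of MSI tumors respond to
checkpoint blockade), with a small background response rate among the
remaining samples.

All distributional choices here are stand-ins for real data generating
processes — see docs/methods.md for what they do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NONRESPONDER, RESPONDER, SCALE_TPM, CohortData

# Default study layout: 4 ICB cohorts (sample sizes mirroring typical published
# checkpoint-blockade series: gastric n=45, urothelial n=298, two melanoma
# n=118/73) and 3 MSI-proxy cohorts of 300 tumors each.
DEFAULT_ICB_LAYOUT = [
    ("icb_gastric", 45, 0.25),
    ("icb_urothelial", 298, 0.20),
    ("icb_melanoma_a", 118, 0.30),
    ("icb_melanoma_b", 73, 0.45),
]
DEFAULT_PROXY_LAYOUT = [
    ("proxy_colorectal", 300, 0.15),
    ("proxy_gastric", 300, 0.20),
    ("proxy_endometrial", 300, 0.30),
]
DEFAULT_COHORT_IDS = [c for c, _, _ in DEFAULT_ICB_LAYOUT + DEFAULT_PROXY_LAYOUT]

#: TMB (mutations/Mb) is log-normal with responders elevated: medians ~10 vs ~4.
DEFAULT_TMB_PARAMS = {RESPONDER: (np.log(10.0), 0.8), NONRESPONDER: (np.log(4.0), 0.8)}

# log2(stroma/cancer) baseline divergence: ~N(0, 1.5) for unplanted genes;
# planted stromal DEGs are stroma-dominant (+N(2, 0.5)) and planted cancer DEGs
# cancer-dominant (-N(2, 0.5)), emulating the compartment specificity of
# immune-gene vs cancer-intrinsic expression.
_NULL_DIVERGENCE_SD = 1.5
_PLANTED_DIVERGENCE_MEAN = 2.0
_PLANTED_DIVERGENCE_SD = 0.5


@dataclass
class GroundTruth:
    """Planted per-gene compartment means and response effects for one study."""

    gene_ids: list[str]
    baseline_cancer: np.ndarray        # per-gene log2 mean in cancer cells
    baseline_stroma: np.ndarray        # per-gene log2 mean in stroma
    stroma_up_genes: list[str]         # responder-up stromal effect, all cohorts
    stroma_down_genes: list[str]       # responder-down stromal effect, all cohorts
    cancer_cohort_effects: dict[str, dict[str, float]]  # cohort -> gene -> log2 effect
    effect_size: float
    noise_sd: float                    # SD of log2-scale multiplicative noise
    tmb_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TMB_PARAMS)
    )

    def __post_init__(self) -> None:
        up, down = set(self.stroma_up_genes), set(self.stroma_down_genes)
        cancer = self.cancer_gene_set()
        if up & down or up & cancer or down & cancer:
            raise ValueError("planted stroma-up/stroma-down/cancer gene sets must be disjoint")
        if not (np.isfinite(self.baseline_cancer).all() and np.isfinite(self.baseline_stroma).all()):
            raise ValueError("baseline means must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def cancer_gene_set(self) -> set[str]:
        return {g for eff in self.cancer_cohort_effects.values() for g in eff}

    def planted_genes(self) -> set[str]:
        return set(self.stroma_up_genes) | set(self.stroma_down_genes) | self.cancer_gene_set()

    def stroma_effect_vector(self) -> np.ndarray:
        """Per-gene responder-minus-nonresponder stromal effect (log2)."""
        eff = np.zeros(len(self.gene_ids))
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        for g in self.stroma_up_genes:
            eff[idx[g]] = self.effect_size
        for g in self.stroma_down_genes:
            eff[idx[g]] = -self.effect_size
        return eff

    def cancer_effect_vector(self, cohort_id: str) -> np.ndarray:
        """Per-gene responder-minus-nonresponder cancer effect in one cohort."""
        eff = np.zeros(len(self.gene_ids))
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        for g, e in self.cancer_cohort_effects.get(cohort_id, {}).items():
            eff[idx[g]] = e
        return eff


@dataclass
class CohortConfig:
    """Sampling plan for one synthetic cohort."""

    cohort_id: str
    n_samples: int
    cohort_class: str = "icb"          # "icb" | "proxy"
    responder_fraction: float = 0.3    # observed responder(-enriched) fraction
    purity_beta_a: float = 5.0         # Beta purity: median ~0.64, TCGA-like spread
    purity_beta_b: float = 3.0
    proxy_fidelity: float = 0.4        # P(true responder | "responder-enriched")
    proxy_background_rate: float = 0.05  # P(true responder | not enriched)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_class not in ("icb", "proxy"):
            raise ValueError(f"cohort_class must be 'icb' or 'proxy', got {self.cohort_class!r}")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValueError("responder_fraction must be in (0, 1)")
        n_resp = int(round(self.responder_fraction * self.n_samples))
        if n_resp < 2 or self.n_samples - n_resp < 2:
            raise ValueError(
                f"cohort {self.cohort_id!r}: responder_fraction {self.responder_fraction} "
                f"leaves fewer than 2 samples in one response group"
            )
        if not 0.0 <= self.proxy_fidelity <= 1.0:
            raise ValueError("proxy_fidelity must be in [0, 1]")
        if not 0.0 <= self.proxy_background_rate <= 1.0:
            raise ValueError("proxy_background_rate must be in [0, 1]")


def generate_ground_truth(
    n_genes: int,
    n_stroma_up: int,
    n_stroma_down: int,
    n_cancer_specific: int,
    effect_size: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    cancer_cohorts: list[str] | None = None,
    tmb_params: dict[str, tuple[float, float]] | None = None,
) -> GroundTruth:
    """Draw a study ground truth with disjoint planted gene sets.

    Baseline cancer log2 means are uniform in [2, 10]; stromal baselines equal
    the cancer baseline plus a compartment divergence (see module docstring).
    Cancer-specific effects are assigned round-robin over ``cancer_cohorts``
    (default: the 7 default study cohorts) with alternating sign; stromal
    effects are ``+effect_size`` for up genes and ``-effect_size`` for down
    genes, identical in every cohort.
    """
    n_planted = n_stroma_up + n_stroma_down + n_cancer_specific
    if n_planted > n_genes:
        raise ValueError(
            f"requested {n_planted} planted genes "
            f"({n_stroma_up} stroma-up + {n_stroma_down} stroma-down + "
            f"{n_cancer_specific} cancer-specific) but only {n_genes} genes"
        )
    if cancer_cohorts is None:
        cancer_cohorts = list(DEFAULT_COHORT_IDS)
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    baseline_cancer = rng.uniform(2.0, 10.0, n_genes)
    divergence = rng.normal(0.0, _NULL_DIVERGENCE_SD, n_genes)

    planted = rng.choice(n_genes, size=n_planted, replace=False)
    up_idx = planted[:n_stroma_up]
    down_idx = planted[n_stroma_up : n_stroma_up + n_stroma_down]
    cancer_idx = planted[n_stroma_up + n_stroma_down :]
    # compartment-dominant baselines for planted genes
    stroma_idx = np.concatenate([up_idx, down_idx]).astype(int)
    divergence[stroma_idx] = rng.normal(
        _PLANTED_DIVERGENCE_MEAN, _PLANTED_DIVERGENCE_SD, stroma_idx.size
    )
    divergence[cancer_idx] = rng.normal(
        -_PLANTED_DIVERGENCE_MEAN, _PLANTED_DIVERGENCE_SD, cancer_idx.size
    )
    baseline_stroma = baseline_cancer + divergence

    cancer_effects: dict[str, dict[str, float]] = {}
    for k, gi in enumerate(cancer_idx):
        cohort = cancer_cohorts[k % len(cancer_cohorts)]
        sign = 1.0 if k % 2 == 0 else -1.0
        cancer_effects.setdefault(cohort, {})[gene_ids[gi]] = sign * effect_size

    return GroundTruth(
        gene_ids=gene_ids,
        baseline_cancer=baseline_cancer,
        baseline_stroma=baseline_stroma,
        stroma_up_genes=[gene_ids[i] for i in up_idx],
        stroma_down_genes=[gene_ids[i] for i in down_idx],
        cancer_cohort_effects=cancer_effects,
        effect_size=float(effect_size),
        noise_sd=float(noise_sd),
        tmb_params=dict(tmb_params or DEFAULT_TMB_PARAMS),
    )


def generate_cohort(truth: GroundTruth, cfg: CohortConfig) -> CohortData:
    """Sample one cohort from the two-compartment mixing model.

    Returns a :class:`CohortData` on the linear TPM scale (``scale='tpm'``)
    whose ``premix`` attribute holds the pre-rescaling linear mixture (noise
    included) and whose ``true_response`` holds the latent response that drove
    the expression and TMB signal.
    """
    if cfg.purity_beta_a <= 0 or cfg.purity_beta_b <= 0:
        raise ValueError(
            f"degenerate Beta purity parameters (a={cfg.purity_beta_a}, b={cfg.purity_beta_b})"
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"{cfg.cohort_id}_s{i:04d}" for i in range(n)]

    purity = rng.beta(cfg.purity_beta_a, cfg.purity_beta_b, n)

    n_resp = int(round(cfg.responder_fraction * n))
    observed = np.zeros(n, dtype=bool)
    observed[rng.permutation(n)[:n_resp]] = True
    if cfg.cohort_class == "icb":
        true = observed.copy()
    else:
        u = rng.random(n)
        true = np.where(observed, u < cfg.proxy_fidelity, u < cfg.proxy_background_rate)

    # per-gene, per-sample compartment log2 means
    stroma_eff = truth.stroma_effect_vector()
    cancer_eff = truth.cancer_effect_vector(cfg.cohort_id)
    t = true.astype(float)
    cancer_log2 = truth.baseline_cancer[:, None] + np.outer(cancer_eff, t)
    stroma_log2 = truth.baseline_stroma[:, None] + np.outer(stroma_eff, t)

    premix = purity[None, :] * 2.0**cancer_log2 + (1.0 - purity[None, :]) * 2.0**stroma_log2
    if truth.noise_sd > 0:
        premix = premix * 2.0 ** rng.normal(0.0, truth.noise_sd, premix.shape)

    tpm = premix / premix.sum(axis=0, keepdims=True) * 1e6

    z = rng.normal(0.0, 1.0, n)
    loc = np.where(true, truth.tmb_params[RESPONDER][0], truth.tmb_params[NONRESPONDER][0])
    scale = np.where(true, truth.tmb_params[RESPONDER][1], truth.tmb_params[NONRESPONDER][1])
    tmb = np.exp(loc + scale * z)

    labels = np.where(observed, RESPONDER, NONRESPONDER)
    return CohortData(
        cohort_id=cfg.cohort_id,
        expression=pd.DataFrame(tpm, index=truth.gene_ids, columns=sample_ids),
        purity=pd.Series(purity, index=sample_ids, name="purity"),
        response=pd.Series(labels, index=sample_ids, name="response"),
        cohort_class=cfg.cohort_class,
        tmb=pd.Series(tmb, index=sample_ids, name="tmb"),
        scale=SCALE_TPM,
        true_response=pd.Series(np.where(true, RESPONDER, NONRESPONDER), index=sample_ids),
        premix=pd.DataFrame(premix, index=truth.gene_ids, columns=sample_ids),
    )


def generate_study(truth: GroundTruth, cohort_cfgs: list[CohortConfig]) -> list[CohortData]:
    """Independent cohorts sharing one ground truth (stromal effects shared,
    cancer effects only in the cohorts named by ``cancer_cohort_effects``)."""
    ids = [c.cohort_id for c in cohort_cfgs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cohort ids: {dupes}")
    return [generate_cohort(truth, cfg) for cfg in cohort_cfgs]


def default_study_configs(seed: int = 0, proxy_fidelity: float = 0.4) -> list[CohortConfig]:
    """The default 4 ICB + 3 proxy cohort layout with per-cohort child seeds."""
    child = np.random.SeedSequence(seed).generate_state(7) % (2**31)
    cfgs = []
    for i, (cid, n, frac) in enumerate(DEFAULT_ICB_LAYOUT):
        cfgs.append(
            CohortConfig(cohort_id=cid, n_samples=n, cohort_class="icb",
                         responder_fraction=frac, seed=int(child[i]))
        )
    for j, (cid, n, frac) in enumerate(DEFAULT_PROXY_LAYOUT):
        cfgs.append(
            CohortConfig(cohort_id=cid, n_samples=n, cohort_class="proxy",
                         responder_fraction=frac, proxy_fidelity=proxy_fidelity,
                         seed=int(child[4 + j]))
        )
    return cfgs


def generate_default_study(
    seed: int = 0,
    n_genes: int = 400,
    n_stroma_up: int | None = None,
    n_stroma_down: int | None = None,
    n_cancer_specific: int | None = None,
    effect_size: float = 1.0,
    noise_sd: float = 0.3,
    proxy_fidelity: float = 0.4,
) -> tuple[GroundTruth, list[CohortData]]:
    """Ground truth + cohorts for the default study layout in one call.

    Planted-set sizes default to 5% of genes for each stromal direction and
    3.5% for cancer-specific effects (20/20/14 at the 400-gene default).
    Cancer-specific effects are spread round-robin over all 7 cohorts, so each
    is present in exactly one cohort.
    """
    if n_stroma_up is None:
        n_stroma_up = max(2, round(0.05 * n_genes))
    if n_stroma_down is None:
        n_stroma_down = max(2, round(0.05 * n_genes))
    if n_cancer_specific is None:
        n_cancer_specific = max(1, round(0.035 * n_genes))
    truth = generate_ground_truth(
        n_genes, n_stroma_up, n_stroma_down, n_cancer_specific,
        effect_size=effect_size, noise_sd=noise_sd, seed=seed,
        cancer_cohorts=list(DEFAULT_COHORT_IDS),
    )
    cohorts = generate_study(truth, default_study_configs(seed=seed, proxy_fidelity=proxy_fidelity))
    return truth, cohorts


def generate_classifier_features(
    n_samples: int,
    n_signal: int = 3,
    n_noise: int = 56,
    effect: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Standard-normal feature matrix with ``n_signal`` planted predictors.

    Labels are Bernoulli with log-odds ``effect * sum(signal features)``;
    returns (features, binary labels, names of the planted features). Used to
    exercise penalized feature selection with a known answer.
    """
    rng = np.random.default_rng(seed)
    k = n_signal + n_noise
    X = rng.normal(0.0, 1.0, (n_samples, k))
    names = [f"f{i:03d}" for i in range(k)]
    logit = effect * X[:, :n_signal].sum(axis=1)
    y = (rng.random(n_samples) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    return pd.DataFrame(X, columns=names), y, names[:n_signal]
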