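"""Synthetic targeted-transcriptome cohort generator.

Emulates the statistical structure of a bone-marrow FPKM cohort from a
targeted RNA panel (1408 cancer-associated genes, ~10 million fragments per
sample) with binary post-transplant endpoints: acute GvHD and survival.
Because the study data are not deposited, every downstream stage of the
pipeline is exercised against cohorts drawn here, with a ground-truth channel
(which genes carry signal, and how much) for parameter-recovery tests.

Model
-----
Per-gene baseline mean counts at nominal depth are drawn log-normal so FPKM
spans several decades, as real panels do. Counts are negative binomial
(gamma-Poisson) with a shared, configurable dispersion; the expected count
scales with the sample's library size. Informative genes have their
case-group mean multiplied by ``2**(signed log2 fold-change)`` before FPKM
conversion. Optional within-block correlation is imposed by a Gaussian copula
over consecutive gene blocks. FPKM follows the standard definition
``counts * 1e9 / (gene_length_bp * total_fragments)``.

All randomness flows from one master seed through named counter-derived
substreams, so adding a downstream draw never perturbs an upstream one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as _cohort
from .exceptions import ConfigurationError, DomainError
from .io import CohortLabels, ExpressionMatrix, write_expression_matrix, write_labels

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "fpkm_from_counts",
    "sample_onset_days",
    "write_cohort",
]

_POST = _cohort.POST_TRANSPLANT


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the post-transplant study cohort.

    ``prevalence`` is the case rate of the endpoint carrying the planted
    signal (``signal_endpoint``); the other endpoint is drawn independently
    at the study cohort's observed rate. ``effect_log2fc`` is the common
    magnitude of the planted signed log2 fold-changes.
    """

    n_samples: int = _POST.n_patients                 # 119
    n_genes: int = _cohort.N_PANEL_GENES              # 1408
    n_informative: int = 92
    effect_log2fc: float = 1.0
    prevalence: float = 0.67
    dispersion: float = 0.3
    libsize_range: tuple[int, int] = (8_000_000, 12_000_000)
    block_size: int = 50
    block_rho: float = 0.0
    seed: int = 0
    signal_endpoint: Literal["agvhd", "survival"] = "agvhd"
    timepoint: Literal["pre", "post"] = "post"
    # log-normal parameters of the baseline mean count at nominal depth
    baseline_log_mean: float = math.log(60.0)
    baseline_log_sd: float = 1.6

    def validate(self) -> None:
        if not (isinstance(self.n_samples, (int, np.integer)) and self.n_samples > 0):
            raise ConfigurationError("n_samples must be a positive integer")
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes > 0):
            raise ConfigurationError("n_genes must be a positive integer")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ConfigurationError("n_informative must lie in [0, n_genes]")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be non-negative")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must lie strictly inside (0, 1)")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        low, high = self.libsize_range
        if not (0 < low <= high):
            raise ConfigurationError("libsize_range must satisfy 0 < low <= high")
        if self.block_size <= 0:
            raise ConfigurationError("block_size must be a positive integer")
        if not (0.0 <= self.block_rho < 1.0):
            raise ConfigurationError("block_rho must lie in [0, 1)")
        if self.signal_endpoint not in ("agvhd", "survival"):
            raise ConfigurationError("signal_endpoint must be 'agvhd' or 'survival'")
        if self.timepoint not in ("pre", "post"):
            raise ConfigurationError("timepoint must be 'pre' or 'post'")


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests; never read by the pipeline."""

    informative_genes: set[str]
    per_gene_effect: dict[str, float]
    case_assignment: dict[str, str] = field(default_factory=dict)  # sample -> case/control


def _stream(seed: int, key: int) -> np.random.Generator:
    """Counter-derived child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# substream keys; append only, never renumber
_K_GENE_PARAMS = 0
_K_CASES = 1
_K_LIBSIZE = 2
_K_COUNTS = 3
_K_EFFECTS = 4
_K_OTHER_ENDPOINT = 5
_K_ONSET = 6


def fpkm_from_counts(
    counts: np.ndarray, gene_lengths_bp: np.ndarray, total_fragments: float
) -> np.ndarray:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``fpkm_g = counts_g * 1e9 / (length_g * total_fragments)``; zero counts
    map to zero exactly.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths_bp, dtype=float)
    if counts.shape[0] != lengths.shape[0]:
        raise DomainError("counts and gene_lengths_bp must have equal length")
    if (counts < 0).any():
        raise DomainError("counts must be non-negative")
    if (lengths <= 0).any():
        raise DomainError("gene lengths must be strictly positive")
    if not total_fragments > 0:
        raise DomainError("total_fragments must be strictly positive")
    if lengths.ndim == 1 and counts.ndim == 2:
        lengths = lengths[:, None]
    return counts * 1e9 / (lengths * total_fragments)


def sample_onset_days(
    labels: CohortLabels, median_day: float = _cohort.MEDIAN_AGVHD_ONSET_DAYS,
    seed: int = 0, sigma: float = 0.6,
) -> pd.Series:
    """Draw aGvHD onset days for the cases (cosmetic realism channel).

    Log-normal with the given median: positive, right-skewed, matching the
    typical early post-transplant onset window. Controls get no onset day;
    an all-control cohort yields an empty series.
    """
    if median_day <= 0:
        raise DomainError("median_day must be positive")
    cases = labels.data.index[labels.data["agvhd"] == 1]
    rng = _stream(seed, _K_ONSET)
    days = np.exp(rng.normal(math.log(median_day), sigma, size=len(cases)))
    return pd.Series(days, index=cases, name="onset_day")


def _draw_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float,
    block_size: int, block_rho: float,
) -> np.ndarray:
    """NB(mu, dispersion) counts, optionally block-correlated via a copula."""
    r = 1.0 / dispersion
    if block_rho == 0.0:
        # gamma-Poisson mixture == negative binomial
        lam = rng.gamma(shape=r, scale=mu * dispersion)
        return rng.poisson(lam).astype(np.int64)
    n_genes, n_samples = mu.shape
    n_blocks = -(-n_genes // block_size)
    shared = rng.standard_normal((n_blocks, n_samples))
    shared = np.repeat(shared, block_size, axis=0)[:n_genes]
    eps = rng.standard_normal((n_genes, n_samples))
    z = math.sqrt(block_rho) * shared + math.sqrt(1.0 - block_rho) * eps
    u = stats.norm.cdf(z)
    p = r / (r + mu)
    return stats.nbinom.ppf(u, r, p).astype(np.int64)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, CohortLabels, GroundTruth]:
    """Generate one synthetic cohort: FPKM matrix, labels, and ground truth.

    Fully deterministic given the config (including its seed).
    """
    config.validate()
    seed = config.seed
    n_g, n_s = config.n_genes, config.n_samples
    width_g = max(4, len(str(n_g)))
    width_s = max(3, len(str(n_s)))
    gene_ids = [f"G{i:0{width_g}d}" for i in range(1, n_g + 1)]
    sample_ids = [f"S{i:0{width_s}d}" for i in range(1, n_s + 1)]

    rng_genes = _stream(seed, _K_GENE_PARAMS)
    base_mean = np.exp(
        rng_genes.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_g)
    )
    gene_lengths = np.exp(
        rng_genes.uniform(math.log(500.0), math.log(10_000.0), size=n_g)
    ).astype(np.int64)

    case = _stream(seed, _K_CASES).random(n_s) < config.prevalence
    libsize = _stream(seed, _K_LIBSIZE).integers(
        config.libsize_range[0], config.libsize_range[1] + 1, size=n_s
    )

    rng_eff = _stream(seed, _K_EFFECTS)
    info_idx = np.sort(rng_eff.choice(n_g, size=config.n_informative, replace=False))
    signs = rng_eff.choice([-1.0, 1.0], size=config.n_informative)
    effects = np.zeros(n_g)
    if config.n_informative and config.effect_log2fc > 0:
        effects[info_idx] = signs * config.effect_log2fc
    elif config.n_informative:
        # zero magnitude requested: genes are flagged but carry no shift
        effects[info_idx] = 0.0

    depth_factor = libsize / _cohort.NOMINAL_READS_PER_SAMPLE
    mu = base_mean[:, None] * depth_factor[None, :]
    mu = mu * np.power(2.0, effects[:, None] * case[None, :].astype(float))

    counts = _draw_counts(
        _stream(seed, _K_COUNTS), mu, config.dispersion,
        config.block_size, config.block_rho,
    )
    fpkm = counts * 1e9 / (gene_lengths[:, None].astype(float) * libsize[None, :])

    rng_other = _stream(seed, _K_OTHER_ENDPOINT)
    if config.signal_endpoint == "agvhd":
        agvhd = case.astype(int)
        death_rate = 1.0 - (_POST.survival_rate or 0.73)
        alive = (rng_other.random(n_s) >= death_rate).astype(int)
    else:
        # signal endpoint is survival; "case" means death
        alive = (~case).astype(int)
        agvhd = (rng_other.random(n_s) < _POST.agvhd_prevalence).astype(int)

    labels_df = pd.DataFrame(
        {
            "timepoint": config.timepoint,
            "agvhd": agvhd,
            "alive": alive,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    labels = CohortLabels(labels_df)
    onset = sample_onset_days(labels, seed=seed)
    labels.data["onset_day"] = onset.reindex(labels.data.index)

    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
    )
    truth = GroundTruth(
        informative_genes={gene_ids[i] for i in info_idx},
        per_gene_effect={gene_ids[i]: effects[i] for i in info_idx},
        case_assignment={
            s: ("case" if c else "control") for s, c in zip(sample_ids, case)
        },
    )
    return matrix, labels, truth


def write_cohort(
    out_dir: str | Path,
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    truth: GroundTruth | None = None,
    prefix: str = "cohort",
) -> dict[str, Path]:
    """Persist a cohort as TSV files; the truth file is never read back."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{prefix}_fpkm.tsv",
        "labels": out / f"{prefix}_labels.tsv",
    }
    write_expression_matrix(matrix, paths["matrix"])
    write_labels(labels, paths["labels"])
    if truth is not None:
        paths["truth"] = out / f"{prefix}_truth.tsv"
        rows = [
            {"gene": g, "log2fc": truth.per_gene_effect[g]}
            for g in sorted(truth.informative_genes)
        ]
        pd.DataFrame(rows, columns=["gene", "log2fc"]).to_csv(
            paths["truth"], sep="\t", index=False
        )
    return paths
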