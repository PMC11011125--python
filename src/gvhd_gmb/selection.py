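"""Stability-based per-gene selection of outcome-associated genes.

The selection step screens every gene of the targeted panel for univariate
discrimination between the two outcome groups, using rank statistics that are
invariant to any strictly monotone transform of the expression values (so raw
FPKM, log2(FPKM+1) and rank-normalized data all select the same genes):

* performance — the tie-corrected two-sample AUC (the Mann–Whitney
  probability), cross-validated over stratified inner folds and folded to
  ``max(A, 1 - A)`` so down- and up-regulated genes score symmetrically;
* significance — the two-sided Wilcoxon rank-sum test, Benjamini–Hochberg
  adjusted across the panel;
* stability — the fraction of B stratified 80% subsamples in which the gene
  passes the per-replicate BH criterion (subsampling stability selection).

A gene is selected when its adjusted p-value is at most ``alpha`` AND its
stability frequency is at least ``stability_threshold``; ``max_genes``
optionally truncates to the top genes by cross-validated AUC.

Matrix-wide paths use a vectorized tie-corrected normal approximation of the
rank-sum test (the only tractable form at 1408 genes x 100 subsamples); the
scalar :func:`rank_sum_pvalue` defers to scipy and is exact on small tie-free
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, DomainError
from .io import ExpressionMatrix

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "per_gene_auc",
    "rank_sum_pvalue",
    "adjust_pvalues",
    "stability_frequencies",
    "select_genes",
]


@dataclass
class SelectionConfig:
    """Tunables of the selection stage.

    B subsamples at ``subsample_fraction`` drive the stability frequency;
    ``alpha`` applies to BH-adjusted p-values both panel-wide and inside each
    replicate; ``cv_folds_inner`` controls the per-gene AUC cross-validation.
    """

    n_resamples: int = 100
    subsample_fraction: float = 0.8
    cv_folds_inner: int = 5
    alpha: float = 0.05
    stability_threshold: float = 0.6
    max_genes: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_resamples < 1:
            raise ConfigurationError("n_resamples must be >= 1")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ConfigurationError("subsample_fraction must lie in (0, 1]")
        if self.cv_folds_inner < 2:
            raise ConfigurationError("cv_folds_inner must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not (0.0 < self.stability_threshold <= 1.0):
            raise ConfigurationError("stability_threshold must lie in (0, 1]")
        if self.max_genes is not None and self.max_genes < 1:
            raise ConfigurationError("max_genes must be a positive integer")


@dataclass
class SelectionReport:
    """Per-gene screening results plus the ordered selected gene list."""

    table: pd.DataFrame  # index gene; cv_auc, p_value, p_adjusted, stability_frequency, selected
    selected_genes: list[str]
    config: SelectionConfig
    warning: str | None = None
    field_order: tuple[str, ...] = field(
        default=("cv_auc", "p_value", "p_adjusted", "stability_frequency", "selected"),
        repr=False,
    )

    def write(self, path: str | Path) -> None:
        df = self.table.copy()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def _validate_two_class(y: np.ndarray) -> tuple[int, int]:
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DomainError("both outcome classes must be non-empty")
    return n_pos, n_neg


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, [0, 1]).all():
        raise DomainError("labels must be binary 0/1")
    return y.astype(int)


def per_gene_auc(values, labels, fold: bool = True) -> float:
    """Tie-corrected two-sample AUC of one gene.

    Equals the Mann–Whitney probability (#concordant + half-ties over
    n_pos*n_neg); with ``fold`` the orientation is folded to
    ``max(A, 1 - A)`` so a strongly down-regulated gene scores as high as an
    up-regulated one.
    """
    x = np.asarray(values, dtype=float)
    y = _as_binary(labels)
    n_pos, n_neg = _validate_two_class(y)
    ranks = stats.rankdata(x)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    auc = u / (n_pos * n_neg)
    return float(max(auc, 1.0 - auc)) if fold else float(auc)


def rank_sum_pvalue(values, labels) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one gene.

    Exact on small tie-free inputs, tie-corrected normal approximation
    otherwise (scipy's method="auto"); a gene constant across both classes
    has p = 1 by the tie-corrected convention.
    """
    x = np.asarray(values, dtype=float)
    y = _as_binary(labels)
    _validate_two_class(y)
    cases, controls = x[y == 1], x[y == 0]
    if np.ptp(x) == 0:
        return 1.0
    res = stats.mannwhitneyu(cases, controls, alternative="two-sided", method="auto")
    return float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))


def _rank_stats_from_gid(
    gid: np.ndarray, ys: np.ndarray, n_pos: int, n_neg: int,
    use_continuity: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(raw AUC, two-sided asymptotic p) from value-sorted rows.

    ``gid`` assigns a tie-group id to each position of a value-sorted row
    (equal values share an id; ids increase along the row) and ``ys`` holds
    the corresponding binary labels. Average ranks of tie groups are
    recovered with running max/min scans over group boundaries, so the whole
    statistic is vectorized across genes; no un-sorting is needed because
    only rank sums enter it. Rank arithmetic stays in int32/float32 (exact
    for these magnitudes); the z/p math is float64.
    """
    g, n = gid.shape
    idx = np.arange(n, dtype=np.int32)
    starts_mask = np.ones((g, n), dtype=bool)
    starts_mask[:, 1:] = gid[:, 1:] != gid[:, :-1]
    ends_mask = np.ones((g, n), dtype=bool)
    ends_mask[:, :-1] = starts_mask[:, 1:]
    start = np.maximum.accumulate(
        np.where(starts_mask, idx, np.int32(-1)), axis=1
    )
    end = np.flip(
        np.minimum.accumulate(
            np.flip(np.where(ends_mask, idx, np.int32(n)), axis=1), axis=1
        ),
        axis=1,
    )
    avg_rank = (start + end).astype(np.float32) * 0.5 + 1.0
    rank_sum_pos = np.einsum("ij,ij->i", avg_rank, ys.astype(np.float32))
    u = rank_sum_pos.astype(float) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    t = end - start + 1
    tie = (np.einsum("ij,ij->i", t, t) - n).astype(float)  # sum over groups of t^3 - t
    var = (n_pos * n_neg / 12.0) * ((n + 1) - tie / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    centered = u - n_pos * n_neg / 2.0
    if use_continuity:
        centered = np.sign(centered) * np.maximum(np.abs(centered) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[sd == 0] = 1.0
    return auc, p


def _sorted_gid(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row sort order and tie-group ids in the sorted domain."""
    order = np.argsort(x, axis=1).astype(np.int32)
    xs = np.take_along_axis(x, order, axis=1)
    new_group = np.ones(x.shape, dtype=bool)
    new_group[:, 1:] = xs[:, 1:] != xs[:, :-1]
    gid = np.cumsum(new_group, axis=1, dtype=np.int32)
    return order, gid


def matrix_rank_stats(
    x_matrix: np.ndarray, labels, use_continuity: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (folded AUC, two-sided asymptotic rank-sum p) for a genes x
    samples array.

    Tie-corrected normal approximation with continuity correction; genes that
    are constant across all samples get AUC 0.5 and p = 1.
    """
    x = np.asarray(x_matrix, dtype=float)
    y = _as_binary(labels)
    n_pos, n_neg = _validate_two_class(y)
    order, gid = _sorted_gid(x)
    auc, p = _rank_stats_from_gid(gid, y[order], n_pos, n_neg, use_continuity)
    return np.maximum(auc, 1.0 - auc), p


def adjust_pvalues(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in (0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def _stratified_subsample(
    rng: np.random.Generator, y: np.ndarray, fraction: float
) -> np.ndarray:
    """Column indices of one stratified subsample; re-drawn if a class empties."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    k_pos = int(round(fraction * len(idx_pos)))
    k_neg = int(round(fraction * len(idx_neg)))
    for _ in range(10):
        take_pos = rng.choice(idx_pos, size=k_pos, replace=False)
        take_neg = rng.choice(idx_neg, size=k_neg, replace=False)
        if len(take_pos) and len(take_neg):
            return np.sort(np.concatenate([take_pos, take_neg]))
    raise DomainError(
        "stratified subsample left a class empty after 10 attempts; "
        "increase subsample_fraction or provide more samples"
    )


def stability_frequencies(
    matrix: ExpressionMatrix | np.ndarray, labels, config: SelectionConfig
) -> np.ndarray:
    """Fraction of B subsample replicates in which each gene passes BH at alpha.

    Replicates are stratified subsamples of ``subsample_fraction`` of each
    class, drawn from a stream seeded by ``config.seed``; frequencies are
    exact multiples of 1/B and fully reproducible.
    """
    config.validate()
    x = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    y = _as_binary(labels)
    _validate_two_class(y)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(101,)))
    n_genes, n = x.shape
    # sort every gene once; each replicate's sorted order is the full sorted
    # order filtered to the subsampled columns, so per replicate only cheap
    # boolean extractions remain
    full_order, gid_full = _sorted_gid(x)
    ys_full = y[full_order].astype(np.int8)
    hits = np.zeros(n_genes, dtype=np.int64)
    for _ in range(config.n_resamples):
        cols = _stratified_subsample(rng, y, config.subsample_fraction)
        in_sub = np.zeros(n, dtype=bool)
        in_sub[cols] = True
        mask = in_sub[full_order]
        m = cols.size
        gid_sub = gid_full[mask].reshape(n_genes, m)
        ys_sub = ys_full[mask].reshape(n_genes, m)
        n_pos = int(y[cols].sum())
        _, p = _rank_stats_from_gid(gid_sub, ys_sub, n_pos, m - n_pos)
        hits += adjust_pvalues(p) <= config.alpha
    return hits / config.n_resamples


def _cross_validated_auc(
    x: np.ndarray, y: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Mean held-out-fold folded AUC per gene over stratified inner folds.

    Ranking needs no fitting, so the cross-validated per-gene performance is
    the average of the AUC evaluated on each held-out fold. Falls back to the
    full-data AUC when class counts cannot sustain two folds.
    """
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    folds = min(n_folds, n_pos, n_neg)
    if folds < 2:
        auc, _ = matrix_rank_stats(x, y)
        return auc
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    aucs = np.zeros((folds, x.shape[0]))
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        aucs[i], _ = matrix_rank_stats(x[:, test_idx], y[test_idx])
    return aucs.mean(axis=0)


def select_genes(
    matrix: ExpressionMatrix, labels, config: SelectionConfig | None = None
) -> SelectionReport:
    """Screen every gene and return the stability-selected set.

    Selected means: BH-adjusted rank-sum p <= alpha AND stability frequency
    >= stability_threshold. The selected list is ordered by cross-validated
    AUC (descending), then adjusted p (ascending), then symbol; ``max_genes``
    truncates that ordering. An empty selection is returned with a warning
    flag, not an error.
    """
    config = config or SelectionConfig()
    config.validate()
    y = _as_binary(labels)
    _validate_two_class(y)
    x = matrix.values
    genes = matrix.gene_ids
    if x.shape[1] != len(y):
        raise DomainError("labels are not aligned with the matrix samples")

    cv_auc = _cross_validated_auc(x, y, config.cv_folds_inner, config.seed)
    _, p = matrix_rank_stats(x, y)
    p_adj = adjust_pvalues(p)
    freq = stability_frequencies(x, y, config)
    selected = (p_adj <= config.alpha) & (freq >= config.stability_threshold)

    order = sorted(
        range(len(genes)),
        key=lambda i: (-cv_auc[i], p_adj[i], genes[i]),
    )
    chosen = [i for i in order if selected[i]]
    if config.max_genes is not None and len(chosen) > config.max_genes:
        keep = set(chosen[: config.max_genes])
        selected = np.array([i in keep for i in range(len(genes))])
        chosen = chosen[: config.max_genes]

    table = pd.DataFrame(
        {
            "cv_auc": cv_auc,
            "p_value": p,
            "p_adjusted": p_adj,
            "stability_frequency": freq,
            "selected": selected,
        },
        index=pd.Index(genes, name="gene"),
    )
    warning = "no genes passed the selection criteria" if not chosen else None
    return SelectionReport(
        table=table,
        selected_genes=[genes[i] for i in chosen],
        config=config,
        warning=warning,
    )
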