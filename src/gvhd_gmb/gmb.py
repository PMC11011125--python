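"""Geometric-mean naïve Bayesian (GMB) classifier.

A naïve Bayes variant for expression panels: per selected gene, Gaussian
class-conditional densities on log2(FPKM + 1); the class likelihood is the
*geometric mean* of the per-gene densities (the G-th root of their product)
rather than the product itself. Taking the geometric mean equalizes the
influence of panels of different sizes and makes the posterior score
invariant to duplicating the feature set — the plain product classifier
sharpens toward 0/1 as genes are duplicated, the GMB score does not.

The score of a sample is

    score = pi1 * Gtilde1 / (pi1 * Gtilde1 + pi0 * Gtilde0),
    Gtilde_c = exp( (1/G) * sum_g log f(x_g | c) ),

computed in log space throughout, so panels of 1000+ genes with per-gene
densities as small as 1e-300 score without underflow.

Cross-validated training scores use stratified k-fold (default k = 12): the
model is fitted on k-1 folds and scores the held-out fold, so every training
sample receives exactly one out-of-fold score. In ``nested`` mode gene
selection is re-run inside each fold (no selection leakage); ``paper`` mode
applies one selection computed on the full training cohort to every fold,
which mirrors reporting pipelines that select before cross-validating and
produces optimistically high training AUCs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, DomainError, FittingError, ScoringError
from .io import ExpressionMatrix
from .selection import SelectionConfig, _as_binary, select_genes

__all__ = [
    "GMBModel",
    "ScoreSet",
    "log_fpkm",
    "fit_gmb",
    "gmb_score",
    "cross_validated_scores",
    "apply_model",
]

DEFAULT_VARIANCE_FLOOR = 1e-3
TRANSFORM_NAME = "log2(FPKM+1)"


def log_fpkm(values: np.ndarray) -> np.ndarray:
    """The package-wide expression transform for Gaussian-model steps."""
    return np.log2(np.asarray(values, dtype=float) + 1.0)


@dataclass
class GMBModel:
    """Per-gene class-conditional Gaussian parameters plus class priors.

    means/variances have shape (2, G): row 0 = controls, row 1 = cases, on
    the log2(FPKM+1) scale. Variances are floored at ``variance_floor``.
    """

    genes: list[str]
    means: np.ndarray
    variances: np.ndarray
    class_priors: np.ndarray
    variance_floor: float = DEFAULT_VARIANCE_FLOOR
    transform: str = TRANSFORM_NAME

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.class_priors = np.asarray(self.class_priors, dtype=float)
        if not self.genes:
            raise FittingError("model gene list is empty")
        if self.means.shape != (2, len(self.genes)):
            raise FittingError("means must have shape (2, n_genes)")
        if self.variances.shape != (2, len(self.genes)):
            raise FittingError("variances must have shape (2, n_genes)")
        if (self.variances < self.variance_floor - 1e-15).any():
            raise FittingError("variances below the variance floor")
        if (self.class_priors <= 0).any() or abs(self.class_priors.sum() - 1) > 1e-9:
            raise FittingError("class priors must be positive and sum to 1")

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "model": "geometric_mean_naive_bayes",
            "transform": self.transform,
            "genes": list(self.genes),
            "means": {"control": self.means[0].tolist(), "case": self.means[1].tolist()},
            "variances": {
                "control": self.variances[0].tolist(),
                "case": self.variances[1].tolist(),
            },
            "class_priors": {"control": self.class_priors[0], "case": self.class_priors[1]},
            "variance_floor": self.variance_floor,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "GMBModel":
        payload = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(
            genes=list(payload["genes"]),
            means=np.array([payload["means"]["control"], payload["means"]["case"]]),
            variances=np.array(
                [payload["variances"]["control"], payload["variances"]["case"]]
            ),
            class_priors=np.array(
                [payload["class_priors"]["control"], payload["class_priors"]["case"]]
            ),
            variance_floor=float(payload["variance_floor"]),
            transform=payload.get("transform", TRANSFORM_NAME),
        )


@dataclass
class ScoreSet:
    """Per-sample posterior scores with fold provenance.

    ``fold`` is the 1-based cross-validation fold in which the sample was
    held out, or "external" for validation-set scores.
    """

    data: pd.DataFrame  # index sample_id; columns score, fold, label

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise DomainError("a sample was scored more than once")
        if len(self.data) and not np.isfinite(self.data["score"].to_numpy(float)).all():
            raise DomainError("non-finite score")

    @property
    def scores(self) -> np.ndarray:
        return self.data["score"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=int)

    def write(self, path: str | Path) -> None:
        df = self.data.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# fitting and scoring
# ---------------------------------------------------------------------------

def fit_gmb(
    matrix: ExpressionMatrix,
    labels,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    priors: Literal["empirical", "equal"] = "empirical",
) -> GMBModel:
    """Fit class-conditional Gaussian moments on log2(FPKM+1).

    The matrix must already be restricted to the selected genes. Each class
    needs at least 2 samples; variances are clipped from below at
    ``variance_floor`` (a constant gene hits the floor exactly).
    """
    if variance_floor <= 0:
        raise ConfigurationError("variance_floor must be positive")
    y = _as_binary(labels)
    x = log_fpkm(matrix.values)
    n_per_class = np.array([(y == 0).sum(), (y == 1).sum()])
    if (n_per_class < 2).any():
        raise FittingError(
            f"each class needs >= 2 training samples, got {n_per_class.tolist()}"
        )
    means = np.stack([x[:, y == c].mean(axis=1) for c in (0, 1)])
    variances = np.stack([x[:, y == c].var(axis=1, ddof=1) for c in (0, 1)])
    variances = np.maximum(variances, variance_floor)
    if priors == "empirical":
        class_priors = n_per_class / n_per_class.sum()
    elif priors == "equal":
        class_priors = np.array([0.5, 0.5])
    else:
        raise ConfigurationError("priors must be 'empirical' or 'equal'")
    return GMBModel(
        genes=matrix.gene_ids,
        means=means,
        variances=variances,
        class_priors=class_priors,
        variance_floor=variance_floor,
    )


def _log_density_means(
    model: GMBModel, x: np.ndarray, combine: Literal["geometric", "product"]
) -> np.ndarray:
    """Per-class combined log-likelihood, shape (2, n_samples)."""
    out = np.empty((2, x.shape[1]))
    for c in (0, 1):
        mu = model.means[c][:, None]
        var = model.variances[c][:, None]
        logf = -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)
        out[c] = logf.mean(axis=0) if combine == "geometric" else logf.sum(axis=0)
    return out


def gmb_score(
    model: GMBModel,
    sample,
    combine: Literal["geometric", "product"] = "geometric",
) -> float | np.ndarray:
    """Posterior score(s) for the case class, in (0, 1).

    ``sample`` is either one expression vector over the model genes (FPKM
    scale) or a genes x samples array. ``combine="product"`` computes the
    plain product naïve Bayes score instead of the geometric mean — kept for
    head-to-head comparison; it is NOT duplication-invariant.
    """
    x = np.asarray(sample, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[:, None]
    if x.shape[0] != len(model.genes):
        raise ScoringError(
            f"sample provides {x.shape[0]} values for {len(model.genes)} model genes"
        )
    if not np.isfinite(x).all():
        bad = np.where(~np.isfinite(x).all(axis=1))[0]
        raise ScoringError(f"missing value for gene(s): {[model.genes[i] for i in bad]}")
    logl = _log_density_means(model, log_fpkm(x), combine)
    margin = (np.log(model.class_priors[1]) + logl[1]) - (
        np.log(model.class_priors[0]) + logl[0]
    )
    from scipy.special import expit

    score = expit(margin)
    return float(score[0]) if single else score


def apply_model(model: GMBModel, matrix: ExpressionMatrix) -> ScoreSet:
    """Score every sample of a validation matrix; fold tag "external".

    The matrix must contain every model gene; extra genes are ignored and the
    model's gene order is enforced.
    """
    missing = [g for g in model.genes if g not in set(matrix.gene_ids)]
    if missing:
        raise ScoringError(f"validation matrix lacks model gene(s): {missing}")
    if matrix.n_samples == 0:
        return ScoreSet(
            pd.DataFrame(
                {"score": [], "fold": [], "label": []},
                index=pd.Index([], name="sample_id"),
            )
        )
    sub = matrix.subset_genes(model.genes)
    scores = gmb_score(model, sub.values)
    return ScoreSet(
        pd.DataFrame(
            {"score": scores, "fold": "external", "label": -1},
            index=pd.Index(matrix.sample_ids, name="sample_id"),
        )
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validated_scores(
    matrix: ExpressionMatrix,
    labels,
    selection_config: SelectionConfig | None = None,
    k: int = 12,
    mode: Literal["nested", "paper"] = "nested",
    seed: int = 0,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    priors: Literal["empirical", "equal"] = "empirical",
) -> ScoreSet:
    """Out-of-fold GMB scores under stratified k-fold cross-validation.

    nested: gene selection is re-run inside each k-1 training portion, so no
    information from a held-out fold touches its scorer. A fold whose inner
    selection is empty is scored with the class priors alone (the naïve Bayes
    limit with no features), yielding a constant, uninformative score.

    paper: one selection computed on the whole input cohort is reused in every
    fold — the leaky variant kept for comparability with pipelines that
    select before cross-validating.
    """
    if mode not in ("nested", "paper"):
        raise ConfigurationError(f"unknown cross-validation mode {mode!r}")
    y = _as_binary(labels)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("both outcome classes must be non-empty")
    if k > min(n_pos, n_neg):
        raise ConfigurationError(
            f"k={k} exceeds the smaller class count {min(n_pos, n_neg)}; "
            f"use k <= {min(n_pos, n_neg)}"
        )
    selection_config = selection_config or SelectionConfig()
    sample_ids = np.array(matrix.sample_ids)

    shared_genes: list[str] | None = None
    if mode == "paper":
        shared_genes = select_genes(matrix, y, selection_config).selected_genes

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    records: list[pd.DataFrame] = []
    for fold_no, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(len(y)), y), start=1
    ):
        train_ids = sample_ids[train_idx]
        test_ids = sample_ids[test_idx]
        if mode == "nested":
            genes = select_genes(
                matrix.subset_samples(train_ids), y[train_idx], selection_config
            ).selected_genes
        else:
            genes = shared_genes or []
        if genes:
            model = fit_gmb(
                matrix.subset_genes(genes).subset_samples(train_ids),
                y[train_idx],
                variance_floor=variance_floor,
                priors=priors,
            )
            scores = gmb_score(
                model, matrix.subset_genes(genes).subset_samples(test_ids).values
            )
        else:
            if priors == "equal":
                prior_case = 0.5
            else:
                prior_case = float(y[train_idx].mean())
            scores = np.full(len(test_idx), prior_case)
        records.append(
            pd.DataFrame(
                {"score": scores, "fold": fold_no, "label": y[test_idx]},
                index=pd.Index(test_ids, name="sample_id"),
            )
        )
    data = pd.concat(records).loc[sample_ids]
    return ScoreSet(data)
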