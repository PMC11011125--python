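"""End-to-end analysis orchestration.

One endpoint analysis reproduces the study design: stratified 2/3–1/3
train/validation split, gene selection on the training set only, k-fold
(k = 12) cross-validated GMB scores on the training set, training ROC with a
Youden cut-off, a final model fitted on the whole training set, and a
validation ROC evaluated at the training-derived cut-off. ``run_all``
executes the four analyses (pre/post timepoint x aGvHD/survival endpoint)
with independent derived seeds.

Validation samples are quarantined immediately after the split: nothing
downstream of the split touches their labels until the final evaluation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from . import __version__
from .exceptions import ConfigurationError, PipelineError
from .gmb import (
    DEFAULT_VARIANCE_FLOOR,
    apply_model,
    cross_validated_scores,
    fit_gmb,
    ScoreSet,
)
from .io import CohortLabels, ExpressionMatrix
from .roc import ROCResult, evaluate_endpoint, youden_cutoff
from .selection import SelectionConfig, select_genes

__all__ = [
    "PipelineConfig",
    "SplitAssignment",
    "RunReport",
    "split_cohort",
    "run_endpoint_analysis",
    "run_all",
]

logger = logging.getLogger("gvhd_gmb")

TRAIN_FRACTION = 2.0 / 3.0


@dataclass
class PipelineConfig:
    """Everything one endpoint analysis needs besides the data and the seed."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    k_folds: int = 12
    cv_mode: Literal["nested", "paper"] = "nested"
    variance_floor: float = DEFAULT_VARIANCE_FLOOR
    priors: Literal["empirical", "equal"] = "empirical"
    split_fraction: float = TRAIN_FRACTION
    stratify: bool = True
    # "training": Youden cut-off derived on training scores and transferred;
    # "validation": derived on the validation scores themselves (the leaky
    # reading of reporting a cut-off "in the validation set").
    cutoff_on: Literal["training", "validation"] = "training"

    def validate(self) -> None:
        self.selection.validate()
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if not (0.0 < self.split_fraction < 1.0):
            raise ConfigurationError("split_fraction must lie in (0, 1)")
        if self.cv_mode not in ("nested", "paper"):
            raise ConfigurationError("cv_mode must be 'nested' or 'paper'")
        if self.cutoff_on not in ("training", "validation"):
            raise ConfigurationError("cutoff_on must be 'training' or 'validation'")


@dataclass
class SplitAssignment:
    """Training/validation membership for every sample."""

    assignment: dict[str, str]  # sample_id -> "training" | "validation"
    seed: int
    stratified: bool

    @property
    def training_ids(self) -> list[str]:
        return [s for s, part in self.assignment.items() if part == "training"]

    @property
    def validation_ids(self) -> list[str]:
        return [s for s, part in self.assignment.items() if part == "validation"]


@dataclass
class RunReport:
    """All numbers of one endpoint analysis, recomputable from its scores."""

    endpoint: str
    timepoint: str
    mode: str
    status: str  # "ok" | "no informative genes"
    n_selected: int
    selected_genes: list[str]
    training_roc: ROCResult | None
    validation_roc: ROCResult | None
    training_scores: ScoreSet | None
    validation_scores: ScoreSet | None
    split: SplitAssignment
    seed: int
    config: PipelineConfig
    version: str = __version__

    def summary(self) -> dict:
        out: dict = {
            "endpoint": self.endpoint,
            "timepoint": self.timepoint,
            "mode": self.mode,
            "status": self.status,
            "n_selected": self.n_selected,
            "selected_genes": self.selected_genes,
            "n_training": len(self.split.training_ids),
            "n_validation": len(self.split.validation_ids),
            "seed": self.seed,
            "version": self.version,
        }
        if self.training_roc is not None:
            out["training"] = self.training_roc.summary()
        if self.validation_roc is not None:
            out["validation"] = self.validation_roc.summary()
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dict(self.summary())
        payload["config"] = {
            "selection": asdict(self.config.selection),
            "k_folds": self.config.k_folds,
            "cv_mode": self.config.cv_mode,
            "variance_floor": self.config.variance_floor,
            "priors": self.config.priors,
            "split_fraction": self.config.split_fraction,
            "stratify": self.config.stratify,
            "cutoff_on": self.config.cutoff_on,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_cohort(
    labels: CohortLabels,
    fraction: float = TRAIN_FRACTION,
    stratify: bool = True,
    seed: int = 0,
    endpoint: str = "agvhd",
) -> SplitAssignment:
    """Randomly split the cohort into training and validation sets.

    The training size is round(fraction * n) exactly; under stratification the
    per-class training sizes are apportioned by largest remainder so class
    proportions in the two halves differ by at most one sample's worth.
    Deterministic given the seed.
    """
    sample_ids = np.array(labels.sample_ids)
    n = len(sample_ids)
    if n < 3:
        raise ConfigurationError("need at least 3 samples to split")
    n_train = int(round(fraction * n))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))

    if not stratify:
        perm = rng.permutation(n)
        train = set(sample_ids[perm[:n_train]])
    else:
        y = labels.endpoint(endpoint).to_numpy()
        strata = [np.flatnonzero(y == c) for c in (0, 1)]
        if any(len(s) < 2 for s in strata):
            raise ConfigurationError(
                "a class has fewer than 2 samples; use stratify=False"
            )
        ideal = [fraction * len(s) for s in strata]
        base = [int(np.floor(v)) for v in ideal]
        shortfall = n_train - sum(base)
        remainders = np.array([v - b for v, b in zip(ideal, base)])
        for idx in np.argsort(-remainders)[:shortfall]:
            base[idx] += 1
        train = set()
        for stratum, k in zip(strata, base):
            perm = rng.permutation(len(stratum))
            train.update(sample_ids[stratum[perm[:k]]])
    assignment = {
        s: ("training" if s in train else "validation") for s in sample_ids
    }
    return SplitAssignment(assignment=assignment, seed=seed, stratified=stratify)


# ---------------------------------------------------------------------------
# one endpoint
# ---------------------------------------------------------------------------

def _derive_seed(seed: int, *keys: int) -> int:
    return int(
        np.random.SeedSequence(seed, spawn_key=tuple(keys)).generate_state(1)[0]
        % (2**31)
    )


def run_endpoint_analysis(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    endpoint: Literal["agvhd", "survival"],
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    timepoint: str | None = None,
) -> RunReport:
    """Split, select, cross-validate, fit, and evaluate one endpoint."""
    config = config or PipelineConfig()
    config.validate()
    y_all = labels.endpoint(endpoint)
    timepoint = timepoint or str(labels.data["timepoint"].iloc[0])

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    split = stage(
        "split", split_cohort, labels,
        fraction=config.split_fraction, stratify=config.stratify,
        seed=_derive_seed(seed, 1), endpoint=endpoint,
    )
    train_ids, val_ids = split.training_ids, split.validation_ids
    x_train = matrix.subset_samples(train_ids)
    y_train = y_all.loc[train_ids].to_numpy()
    # validation labels are quarantined here; nothing below reads them until
    # the final evaluation
    x_val = matrix.subset_samples(val_ids)

    sel_config = SelectionConfig(**{**asdict(config.selection), "seed": _derive_seed(seed, 2)})
    report = stage("select", select_genes, x_train, y_train, sel_config)
    genes = report.selected_genes
    if not genes:
        logger.warning("endpoint %s: no informative genes selected", endpoint)
        return RunReport(
            endpoint=endpoint, timepoint=timepoint, mode=config.cv_mode,
            status="no informative genes", n_selected=0, selected_genes=[],
            training_roc=None, validation_roc=None,
            training_scores=None, validation_scores=None,
            split=split, seed=seed, config=config,
        )

    cv_scores = stage(
        "cross_validate", cross_validated_scores,
        x_train, y_train, sel_config,
        k=config.k_folds, mode=config.cv_mode, seed=_derive_seed(seed, 3),
        variance_floor=config.variance_floor, priors=config.priors,
    )
    training_roc = stage("training_roc", evaluate_endpoint, cv_scores, y_train, "training")

    model = stage(
        "fit_final", fit_gmb, x_train.subset_genes(genes), y_train,
        variance_floor=config.variance_floor, priors=config.priors,
    )
    val_scores = stage("apply_model", apply_model, model, x_val)
    y_val = y_all.loc[val_ids].to_numpy()
    val_scores.data["label"] = y_val
    if config.cutoff_on == "training":
        cutoff_src: str | float = float(training_roc.cutoff)
    else:
        cutoff_src = "training"  # derive Youden on the validation scores
    validation_roc = stage(
        "validation_roc", evaluate_endpoint, val_scores, y_val, cutoff_src
    )

    run = RunReport(
        endpoint=endpoint, timepoint=timepoint, mode=config.cv_mode, status="ok",
        n_selected=len(genes), selected_genes=genes,
        training_roc=training_roc, validation_roc=validation_roc,
        training_scores=cv_scores, validation_scores=val_scores,
        split=split, seed=seed, config=config,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prefix = f"{timepoint}_{endpoint}"
        report.write(out / f"{prefix}_selection.tsv")
        cv_scores.write(out / f"{prefix}_training_scores.tsv")
        val_scores.write(out / f"{prefix}_validation_scores.tsv")
        training_roc.write(out / f"{prefix}_training_roc.tsv")
        validation_roc.write(out / f"{prefix}_validation_roc.tsv")
        model.to_json(out / f"{prefix}_model.json")
        run.to_json(out / f"{prefix}_report.json")
    return run


def run_all(
    data: dict[str, tuple[ExpressionMatrix, CohortLabels]],
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[tuple[str, str], RunReport]:
    """The four analyses: (pre, post) x (agvhd, survival), independent seeds.

    ``data`` maps timepoint ("pre"/"post") to its (matrix, labels) pair; a
    missing timepoint skips its two analyses with a warning.
    """
    reports: dict[tuple[str, str], RunReport] = {}
    for t_idx, timepoint in enumerate(("pre", "post")):
        if timepoint not in data:
            warnings.warn(f"timepoint {timepoint!r} not supplied; skipping", stacklevel=2)
            logger.warning("timepoint %s missing; skipped", timepoint)
            continue
        matrix, labels = data[timepoint]
        for e_idx, endpoint in enumerate(("agvhd", "survival")):
            run_seed = _derive_seed(seed, 10 + t_idx, e_idx)
            reports[(timepoint, endpoint)] = run_endpoint_analysis(
                matrix, labels, endpoint, config=config, seed=run_seed,
                out_dir=out_dir, timepoint=timepoint,
            )
    return reports


def summary_table(reports: dict[tuple[str, str], RunReport]):
    """Combined one-row-per-analysis summary of a run_all quartet."""
    import pandas as pd

    rows = []
    for (timepoint, endpoint), run in sorted(reports.items()):
        row = {
            "timepoint": timepoint,
            "endpoint": endpoint,
            "status": run.status,
            "n_selected": run.n_selected,
        }
        if run.training_roc is not None:
            row["training_auc"] = run.training_roc.auc
            row["cutoff"] = run.training_roc.cutoff
        if run.validation_roc is not None:
            row["validation_auc"] = run.validation_roc.auc
            row["validation_sens"] = run.validation_roc.sens_at_cutoff
            row["validation_spec"] = run.validation_roc.spec_at_cutoff
        rows.append(row)
    return pd.DataFrame(rows)
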