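"""ROC construction, AUC inference, and cut-off selection.

Conventions, stated once and tested:

* thresholds are listed in descending order, with sentinels at +inf (nothing
  called positive) and -inf (everything positive);
* a score equal to the threshold is called positive (>= rule);
* the AUC equals both the trapezoidal area under the stored curve and the
  tie-corrected Mann–Whitney probability;
* the standard error is Hanley–McNeil's closed form with
  Q1 = A/(2-A), Q2 = 2A^2/(1+A), and the 95% CI is the Wald interval
  A ± 1.96*SE, deliberately NOT clipped to [0, 1] (published intervals such
  as an upper bound of 1.007 are only representable unclipped);
* the p-value is a two-sided normal test of A = 0.5 using the Hanley–McNeil
  SE evaluated at A = 0.5 with the same class counts;
* the default cut-off maximizes Youden's J = sensitivity + specificity - 1,
  ties broken toward the smallest cut-off (favouring sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "ROCResult",
    "roc_curve",
    "auc_ci_hanley",
    "null_auc_se",
    "auc_pvalue",
    "youden_cutoff",
    "evaluate_endpoint",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ROCResult:
    """A full ROC analysis: curve, AUC inference, and operating point."""

    thresholds: np.ndarray          # descending, +inf first, -inf last
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    n_pos: int
    n_neg: int
    cutoff: float | None = None
    sens_at_cutoff: float | None = None
    spec_at_cutoff: float | None = None
    cutoff_source: str | None = None
    scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> dict:
        out = {
            "auc": self.auc,
            "se": self.se,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p_value": self.p_value,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        if self.cutoff is not None:
            out.update(
                cutoff=self.cutoff,
                sensitivity=self.sens_at_cutoff,
                specificity=self.spec_at_cutoff,
                cutoff_source=self.cutoff_source,
            )
        return out

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def write(self, path: str | Path) -> None:
        """TSV: a commented header block of the summary, then the curve rows."""
        lines = [f"# {key}\t{value}" for key, value in self.summary().items()]
        body = self.curve_frame().to_csv(sep="\t", index=False, float_format="%.10g")
        Path(path).write_text("\n".join(lines) + "\n" + body)

    def plot(self, path: str | Path, title: str = "ROC") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(1 - self.specificity, self.sensitivity, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls=":", c="grey")
        if self.cutoff is not None and np.isfinite(self.cutoff):
            ax.scatter(
                [1 - self.spec_at_cutoff], [self.sens_at_cutoff],
                marker="o", c="crimson", zorder=3,
                label=f"cut-off {self.cutoff:.3g}",
            )
            ax.legend(loc="lower right")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{title}\nAUC {self.auc:.3f} (95% CI {self.ci95[0]:.3f}-{self.ci95[1]:.3f})")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


# ---------------------------------------------------------------------------
# curve and inference
# ---------------------------------------------------------------------------

def roc_curve(scores, labels) -> ROCResult:
    """Build the ROC curve and fill in AUC, SE, CI, and p-value.

    One threshold per distinct score plus the two sentinels; AUC is the
    trapezoidal area, which equals the tie-corrected Mann–Whitney statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise DomainError("scores and labels must align")
    if not np.isfinite(s).all():
        raise DomainError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("both classes must be present to build a ROC curve")

    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    # sklearn's first threshold is +inf; append the -inf sentinel explicitly
    thresholds = np.concatenate([thr, [-np.inf]])
    thresholds[0] = np.inf
    sens = np.concatenate([tpr, [1.0]])
    spec = 1.0 - np.concatenate([fpr, [1.0]])
    auc = float(np.trapezoid(np.concatenate([tpr, [1.0]]), np.concatenate([fpr, [1.0]])))

    se, ci = auc_ci_hanley(auc, n_pos, n_neg)
    p = auc_pvalue(auc, null_auc_se(n_pos, n_neg))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        se=se,
        ci95=ci,
        p_value=p,
        n_pos=n_pos,
        n_neg=n_neg,
        scores=s,
        labels=y,
    )


def _hanley_variance(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return max(var, 0.0)  # guard against roundoff at A near 0 or 1


def auc_ci_hanley(auc: float, n_pos: int, n_neg: int) -> tuple[float, tuple[float, float]]:
    """Hanley–McNeil SE and unclipped Wald 95% CI of an AUC.

    The interval is A ± 1.96*SE with no truncation at 0/1, matching the
    convention under which a printed upper bound can exceed 1.
    """
    if n_pos < 1 or n_neg < 1:
        raise DomainError("both class counts must be >= 1")
    if not 0.0 <= auc <= 1.0:
        raise DomainError("auc must lie in [0, 1]")
    se = float(np.sqrt(_hanley_variance(auc, n_pos, n_neg)))
    return se, (auc - _Z95 * se, auc + _Z95 * se)


def null_auc_se(n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil SE evaluated at the null value A = 0.5."""
    if n_pos < 1 or n_neg < 1:
        raise DomainError("both class counts must be >= 1")
    return float(np.sqrt(_hanley_variance(0.5, n_pos, n_neg)))


def auc_pvalue(auc: float, se_null: float) -> float:
    """Two-sided normal test of A = 0.5 with the null-hypothesis SE.

    Conventions: se_null = 0 with auc = 0.5 gives p = 1; se_null = 0 with any
    other auc gives the smallest positive float. p always lies in (0, 1].
    """
    if se_null < 0:
        raise DomainError("se_null must be non-negative")
    if se_null == 0.0:
        return 1.0 if auc == 0.5 else float(np.finfo(float).tiny)
    z = (auc - 0.5) / se_null
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# operating points
# ---------------------------------------------------------------------------

def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """Cut-off maximizing Youden's J, ties broken toward the smallest cut-off.

    Returns (cutoff, sensitivity, specificity) and records them on the
    ROCResult. With completely uninformative scores J = 0 everywhere and the
    -inf sentinel is returned (sensitivity 1, specificity 0).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.max(j)
    # thresholds are descending, so the last argmax is the smallest cut-off
    idx = np.flatnonzero(j >= best - 1e-15)[-1]
    roc.cutoff = float(roc.thresholds[idx])
    roc.sens_at_cutoff = float(roc.sensitivity[idx])
    roc.spec_at_cutoff = float(roc.specificity[idx])
    roc.cutoff_source = "youden"
    return roc.cutoff, roc.sens_at_cutoff, roc.spec_at_cutoff


def _operating_point(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> tuple[float, float]:
    pos = labels == 1
    sens = float((scores[pos] >= cutoff).mean())
    spec = float((scores[~pos] < cutoff).mean())
    return sens, spec


def evaluate_endpoint(
    scores,
    labels=None,
    cutoff_source: str | float | tuple[Literal["fixed"], float] = "training",
) -> ROCResult:
    """Full ROC evaluation of a score set against its binary labels.

    ``scores`` may be a ScoreSet (labels taken from it) or an array with an
    explicit ``labels`` argument. ``cutoff_source`` is "training" (derive the
    Youden cut-off from these scores themselves), a numeric value, or
    "fixed:VALUE" / ("fixed", VALUE) — the fixed forms emulate applying a
    training-derived cut-off to a validation set.
    """
    if hasattr(scores, "scores") and hasattr(scores, "labels"):
        y = scores.labels if labels is None else np.asarray(labels, int)
        s = scores.scores
    else:
        if labels is None:
            raise DomainError("labels are required when scores is a plain array")
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=int)

    roc = roc_curve(s, y)
    if isinstance(cutoff_source, str) and cutoff_source == "training":
        youden_cutoff(roc)
        roc.cutoff_source = "training-youden"
        return roc
    if isinstance(cutoff_source, tuple) and cutoff_source[0] == "fixed":
        value = float(cutoff_source[1])
    elif isinstance(cutoff_source, str) and cutoff_source.startswith("fixed:"):
        value = float(cutoff_source.split(":", 1)[1])
    elif isinstance(cutoff_source, (int, float)) and not isinstance(cutoff_source, bool):
        value = float(cutoff_source)
    else:
        raise ConfigurationError(f"unknown cutoff_source {cutoff_source!r}")
    sens, spec = _operating_point(s, y, value)
    roc.cutoff = value
    roc.sens_at_cutoff = sens
    roc.spec_at_cutoff = spec
    roc.cutoff_source = "fixed"
    return roc
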