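"""Expression validation from read-coverage tracks and ROC evaluation.

A locus counts as expressed when its coverage is high, shows a distinct 5'
end, and does not continue into the flanks (i.e. the reads are not part of a
considerably longer transcript).  These criteria are inherently qualitative;
this module encodes them as three configurable metrics with logged defaults.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, Locus

logger = logging.getLogger(__name__)


@dataclass
class ExpressionConfig:
    min_mean_cov: float = 10.0   # reads per base over the locus
    edge_min: float = 0.5        # 5'-end coverage relative to the locus maximum
    flank_max: float = 0.2       # flank/locus mean-coverage ratio ceiling
    flank_width: int = 50        # nt of flank inspected on each side
    edge_window: int = 2         # +/- nt around the 5' end (start heterogeneity)


@dataclass(frozen=True)
class ExpressionCall:
    locus: Locus
    mean_cov: float
    edge_sharpness: float
    flank_ratio: float
    expressed: bool


def call_expressed(
    track: CoverageTrack,
    locus: Locus,
    config: Optional[ExpressionConfig] = None,
) -> ExpressionCall:
    """Deterministic expression call for one locus from per-base coverage.

    ``mean_cov`` is the mean over the locus; ``edge_sharpness`` the maximum
    coverage within +/-2 nt of the 5' end divided by the locus maximum;
    ``flank_ratio`` the larger of the two flank means divided by the locus
    mean.  Expressed iff mean >= ``min_mean_cov``, edge >= ``edge_min`` and
    flank <= ``flank_max``.
    """
    config = config or ExpressionConfig()
    if locus.width <= 0:
        raise ValueError("zero-length locus")
    arr = track.per_base(locus.seq_id, locus.end + config.flank_width)
    body = arr[locus.start : locus.end]
    mean_cov = float(body.mean())
    body_max = float(body.max())

    tss = locus.start if locus.strand == "+" else locus.end - 1
    w = config.edge_window
    edge_slice = arr[max(0, tss - w) : tss + w + 1]
    edge_max = float(edge_slice.max()) if edge_slice.size else 0.0
    edge_sharpness = edge_max / body_max if body_max > 0 else 0.0

    up = arr[max(0, locus.start - config.flank_width) : locus.start]
    down = arr[locus.end : locus.end + config.flank_width]
    flank_means = [float(x.mean()) for x in (up, down) if x.size]
    flank_ratio = max(flank_means) / mean_cov if (flank_means and mean_cov > 0) else 0.0

    expressed = (
        mean_cov >= config.min_mean_cov
        and edge_sharpness >= config.edge_min
        and flank_ratio <= config.flank_max
    )
    return ExpressionCall(
        locus=locus,
        mean_cov=mean_cov,
        edge_sharpness=edge_sharpness,
        flank_ratio=flank_ratio,
        expressed=expressed,
    )


@dataclass
class ROCResult:
    """A receiver operating characteristic curve with trapezoidal AUC."""

    thresholds: np.ndarray  # descending unique scores
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def operating_point(self, threshold: float) -> tuple[float, float]:
        """(fpr, tpr) of the decision rule ``score >= threshold``."""
        idx = np.searchsorted(-self.thresholds, -threshold, side="right")
        return float(self.fpr[idx]), float(self.tpr[idx])


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC curve by threshold sweep over the unique scores (ties grouped).

    The curve always starts at (0, 0) and ends at (1, 1); the AUC is the
    trapezoidal integral of the points, which equals the Mann-Whitney
    concordance probability with tie correction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0:
        raise ValueError("no positive labels")
    if n_neg == 0:
        raise ValueError("no negative labels")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # group ties: step only where the score strictly drops
    distinct = np.flatnonzero(np.diff(sorted_scores)) if scores.size > 1 else np.array([], int)
    boundaries = np.concatenate([distinct, [scores.size - 1]])
    tp = np.cumsum(sorted_labels)[boundaries]
    fp = np.cumsum(~sorted_labels)[boundaries]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = sorted_scores[boundaries]
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def mann_whitney_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Concordance probability P(score+ > score-) + 0.5 P(tie), via mid-ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are required")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # mid-ranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class ClassifierComparison:
    roc_total: ROCResult
    roc_structural: ROCResult
    auc_total: float
    auc_structural: float
    op_total: tuple[float, float]        # operating point of the total-score threshold
    op_structural: tuple[float, float]   # operating point of the structural threshold
    frame: pd.DataFrame


def compare_classifiers(
    results: Sequence,
    calls: Sequence[ExpressionCall],
    total_threshold: float = 32.0,
    structural_threshold: float = 25.0,
) -> ClassifierComparison:
    """ROC comparison of the promoter-anchored total score against the
    structural score alone, with expression calls as truth labels.

    ``results`` and ``calls`` are joined on locus; unmatched loci raise,
    listing the offenders.  The decision thresholds (32 for the total, 25
    for the structural score) are marked as operating points on the curves.
    """
    call_by_locus = {c.locus.key(): c for c in calls}
    unmatched = [r.candidate.locus.key() for r in results
                 if r.candidate.locus.key() not in call_by_locus]
    if unmatched:
        raise ValueError(f"no expression call for loci: {unmatched[:10]}"
                         + (" ..." if len(unmatched) > 10 else ""))
    rows = []
    for r in results:
        call = call_by_locus[r.candidate.locus.key()]
        rows.append(
            {
                "locus": r.candidate.locus.key(),
                "total": r.total,
                "structural": r.structural_component,
                "expressed": call.expressed,
            }
        )
    frame = pd.DataFrame(rows)
    roc_total = roc_curve(frame["total"], frame["expressed"])
    roc_structural = roc_curve(frame["structural"], frame["expressed"])
    return ClassifierComparison(
        roc_total=roc_total,
        roc_structural=roc_structural,
        auc_total=roc_total.auc,
        auc_structural=roc_structural.auc,
        op_total=roc_total.operating_point(total_threshold),
        op_structural=roc_structural.operating_point(structural_threshold),
        frame=frame,
    )


def plot_roc(comparison: ClassifierComparison, path) -> None:
    """Write a two-curve ROC plot (total vs structural score) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(comparison.roc_total.fpr, comparison.roc_total.tpr,
            label=f"classifier total (AUC {comparison.auc_total:.3f})")
    ax.plot(comparison.roc_structural.fpr, comparison.roc_structural.tpr,
            label=f"structural score (AUC {comparison.auc_structural:.3f})")
    ax.scatter(*comparison.op_total, marker="o", zorder=3)
    ax.scatter(*comparison.op_structural, marker="s", zorder=3)
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
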