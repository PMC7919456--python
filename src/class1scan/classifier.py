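"""The promoter-anchored Class I classifier.

A candidate's total score is the sum of three components:

* its structural (covariance-model or built-in) bit score, gated at 15;
* the best DUSE motif score found within 150 nt upstream of the predicted
  transcription start (0 when no DUSE is found);
* a distance adjustment: +5 when the DUSE sits at the canonical ~60-nt
  spacing from the start of transcription (or from a TGTG box that itself
  sits 60 nt downstream of DUSE), -5 for a DUSE at the wrong distance, and
  -10 when DUSE is missing altogether.

Candidates reaching a total of 32 are classified as expressed Class I RNA
gene loci.  The TGTG box contributes no score of its own; it serves only as
an alternative distance anchor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .candidates import CandidateHit
from .genome_io import GenomeSequence, Locus, upstream_window
from .motifs import PWM, MotifHit, scan

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    """All scoring constants of the classifier, in one place."""

    upstream_window: int = 150
    canonical_spacing: int = 60        # nt between DUSE 3' edge and the anchor
    spacing_tolerance: int = 10
    duse_tgtg_spacing: int = 60        # canonical DUSE -> TGTG gap
    distance_bonus: float = 5.0
    wrong_distance_penalty: float = -5.0
    missing_duse_penalty: float = -10.0
    decision_threshold: float = 32.0
    structural_gate: float = 15.0
    duse_min_score_frac: float = 0.6   # reporting floor, fraction of PWM max
    tgtg_min_score_frac: float = 0.6
    measure_from: str = "3prime"       # DUSE edge used for the distance ("3prime"|"5prime")

    def __post_init__(self) -> None:
        if self.upstream_window <= 0 or self.canonical_spacing <= 0:
            raise ValueError("windows must be positive")
        if not (self.distance_bonus > 0 > self.wrong_distance_penalty):
            raise ValueError("bonus must be positive and penalties negative")
        if self.measure_from not in ("3prime", "5prime"):
            raise ValueError("measure_from must be '3prime' or '5prime'")


@dataclass(frozen=True)
class UpstreamAnnotation:
    """DUSE/TGTG context of one candidate's upstream window."""

    duse: Optional[MotifHit]
    tgtg: Optional[MotifHit]
    anchor: str                       # "TSS" or "TGTG"
    duse_distance: Optional[int]      # nt from the DUSE edge to the anchor
    distance_ok: bool
    truncated_window: bool = False

    def __post_init__(self) -> None:
        if self.distance_ok and self.duse is None:
            raise ValueError("distance_ok requires a DUSE hit")
        if self.anchor == "TGTG" and self.tgtg is None:
            raise ValueError("TGTG anchor requires a TGTG hit")


@dataclass(frozen=True)
class ClassifierResult:
    """Component-wise total score and decision for one candidate."""

    candidate: CandidateHit
    annotation: UpstreamAnnotation
    structural_component: float
    duse_component: float
    distance_component: float
    total: float
    classified: bool
    gated: bool = False               # True when rejected by the structural gate


def _duse_gap(duse: MotifHit, anchor_pos: int, strand: str, measure_from: str) -> int:
    """Gap (nt) from the DUSE hit's chosen edge to the anchor position,
    measured along the transcript orientation."""
    if strand == "+":
        edge = duse.locus.end if measure_from == "3prime" else duse.locus.start
        return anchor_pos - edge
    edge = duse.locus.start if measure_from == "3prime" else duse.locus.end
    return edge - anchor_pos


def annotate_upstream(
    candidate: CandidateHit,
    genome: GenomeSequence,
    duse_pwm: PWM,
    tgtg_pwm: PWM,
    config: Optional[ClassifierConfig] = None,
) -> UpstreamAnnotation:
    """Scan the upstream window of a candidate for DUSE and the TGTG box.

    DUSE is the best-scoring hit above the reporting floor (ties: closest to
    canonical spacing, then smallest distance).  The anchor is the TSS unless
    the spacing to the TSS is wrong *and* a TGTG box lies between DUSE and
    the TSS with DUSE at canonical spacing upstream of it, in which case the
    TGTG box anchors the distance.  ``distance_ok`` holds iff the gap is
    within ``spacing_tolerance`` of ``canonical_spacing``.
    """
    config = config or ClassifierConfig()
    window, truncated = upstream_window(genome, candidate.locus, config.upstream_window)
    strand = candidate.locus.strand
    tss = candidate.predicted_tss

    duse_hits = scan(duse_pwm, genome, window, config.duse_min_score_frac * duse_pwm.max_score)
    tgtg_hits = scan(tgtg_pwm, genome, window, config.tgtg_min_score_frac * tgtg_pwm.max_score)
    tgtg = tgtg_hits[0] if tgtg_hits else None

    if not duse_hits:
        return UpstreamAnnotation(
            duse=None, tgtg=tgtg, anchor="TSS", duse_distance=None,
            distance_ok=False, truncated_window=truncated,
        )

    def tss_gap(hit: MotifHit) -> int:
        return _duse_gap(hit, tss, strand, config.measure_from)

    best_score = max(h.score for h in duse_hits)
    contenders = [h for h in duse_hits if h.score == best_score]
    duse = min(
        contenders,
        key=lambda h: (abs(tss_gap(h) - config.canonical_spacing), tss_gap(h)),
    )
    distance = tss_gap(duse)
    anchor = "TSS"
    distance_ok = abs(distance - config.canonical_spacing) <= config.spacing_tolerance

    if not distance_ok and tgtg is not None:
        # gap from the DUSE edge to the TGTG hit's TSS-proximal edge
        if strand == "+":
            edge = duse.locus.end if config.measure_from == "3prime" else duse.locus.start
            tgtg_gap = tgtg.locus.start - edge
            between = edge <= tgtg.locus.start and tgtg.locus.end <= tss
        else:
            edge = duse.locus.start if config.measure_from == "3prime" else duse.locus.end
            tgtg_gap = edge - tgtg.locus.end
            between = tss <= tgtg.locus.start and tgtg.locus.end <= edge
        if between and abs(tgtg_gap - config.duse_tgtg_spacing) <= config.spacing_tolerance:
            anchor = "TGTG"
            distance = tgtg_gap
            distance_ok = True

    return UpstreamAnnotation(
        duse=duse, tgtg=tgtg, anchor=anchor, duse_distance=int(distance),
        distance_ok=distance_ok, truncated_window=truncated,
    )


def distance_component(
    annotation: UpstreamAnnotation, config: Optional[ClassifierConfig] = None
) -> float:
    """+5 for DUSE at the canonical distance, -5 for a DUSE at the wrong
    distance, -10 for no DUSE at all (default constants)."""
    config = config or ClassifierConfig()
    if annotation.duse is None:
        return config.missing_duse_penalty
    if annotation.distance_ok:
        return config.distance_bonus
    return config.wrong_distance_penalty


def classify(
    candidate: CandidateHit,
    annotation: UpstreamAnnotation,
    config: Optional[ClassifierConfig] = None,
) -> ClassifierResult:
    """Combine the three score components into the classification decision.

    ``total`` is exactly ``structural + duse + distance``; a candidate is
    classified iff the total reaches the decision threshold *and* its
    structural score passes the gate.  Gated candidates are reported with
    ``gated=True`` rather than silently dropped.
    """
    config = config or ClassifierConfig()
    structural = candidate.structural_score
    duse_score = annotation.duse.score if annotation.duse is not None else 0.0
    dist = distance_component(annotation, config)
    total = structural + duse_score + dist
    gated = structural < config.structural_gate
    classified = (not gated) and total >= config.decision_threshold
    return ClassifierResult(
        candidate=candidate,
        annotation=annotation,
        structural_component=structural,
        duse_component=duse_score,
        distance_component=dist,
        total=total,
        classified=classified,
        gated=gated,
    )


def classify_genome(
    genome: GenomeSequence,
    hits: Sequence[CandidateHit],
    duse_pwm: Optional[PWM] = None,
    tgtg_pwm: Optional[PWM] = None,
    config: Optional[ClassifierConfig] = None,
) -> list[ClassifierResult]:
    """Classify every (deduplicated) candidate; results sorted by total, descending."""
    if duse_pwm is None or tgtg_pwm is None:
        from .defaults import default_duse_pwm, default_tgtg_pwm

        duse_pwm = duse_pwm or default_duse_pwm()
        tgtg_pwm = tgtg_pwm or default_tgtg_pwm()
    config = config or ClassifierConfig()
    results = []
    for hit in hits:
        annotation = annotate_upstream(hit, genome, duse_pwm, tgtg_pwm, config)
        results.append(classify(hit, annotation, config))
    results.sort(key=lambda r: (-r.total, r.candidate.locus.start))
    n_gated = sum(r.gated for r in results)
    n_classified = sum(r.classified for r in results)
    logger.info(
        "%s: %d candidates, %d below structural gate, %d classified",
        genome.id, len(results), n_gated, n_classified,
    )
    return results


def results_frame(results: Sequence[ClassifierResult]) -> pd.DataFrame:
    """Tabular view of classifier results (one row per candidate)."""
    rows = []
    for r in results:
        loc = r.candidate.locus
        rows.append(
            {
                "seq_id": loc.seq_id,
                "start": loc.start,
                "end": loc.end,
                "strand": loc.strand,
                "structural": r.structural_component,
                "duse": r.duse_component,
                "distance_nt": r.annotation.duse_distance,
                "anchor": r.annotation.anchor,
                "adjustment": r.distance_component,
                "total": r.total,
                "classified": r.classified,
                "gated": r.gated,
            }
        )
    return pd.DataFrame(rows)
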