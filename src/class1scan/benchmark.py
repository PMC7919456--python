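"""End-to-end benchmark: decision-boundary measurement and recovery metrics.

Two entry points used by both the test suite and the acceptance script:

* :func:`measure_decision_boundaries` recovers the classifier's scoring
  constants (distance adjustments, canonical spacing band, decision
  threshold, structural gate) empirically, by sweeping constructed inputs
  through the real pipeline rather than reading the configuration back.
* :func:`run_benchmark` generates a seeded synthetic genome, runs the full
  candidate search -> classification -> expression validation pipeline, and
  reports recovery metrics against the implanted truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .candidates import CandidateHit, SearchParams, builtin_candidate_score, find_candidates
from .classifier import ClassifierConfig, annotate_upstream, classify, classify_genome
from .curation import annotate_stem, composition_stats
from .defaults import default_duse_pwm, default_motif_pwm, default_tgtg_pwm
from .expression import ExpressionConfig, call_expressed, compare_classifiers, roc_curve
from .genome_io import GenomeSequence, Locus
from .motifs import PWM, build_pwm
from .synthetic import (
    GENE_NO_DUSE,
    TRUE,
    SynthConfig,
    TruthSet,
    generate_coverage,
    generate_genome,
)


def exact_duse_pwm(k: int = 12) -> PWM:
    """A poly-C PWM whose hit on C^k scores exactly ``k`` bits.

    Built from the single site C^k with pseudocount 0.1 and a background
    whose C probability is exactly half the column's C probability, so the
    matched column log-odds is log2(2.0) = 1.0 exactly in floating point.
    Used to construct worked examples with exact decimal totals.
    """
    p_c = (1 + 0.1) / (1 + 4 * 0.1)
    other = (1 - p_c / 2) / 3
    background = [other, p_c / 2, other, other]
    return build_pwm(["C" * k], name=f"polyC{k}", background=background)


@dataclass
class BoundaryReport:
    """Empirically recovered classifier decision boundaries."""

    adjustment_correct: float       # distance adjustment at canonical spacing
    adjustment_wrong: float         # adjustment at a clearly wrong spacing
    adjustment_missing: float       # adjustment with no DUSE upstream
    spacing_band: tuple             # (lo, hi) spacings earning the bonus
    spacing_band_center: float
    decision_threshold: float       # minimal classified total score
    structural_gate: float          # minimal classified structural score
    spacing_sweep: pd.DataFrame = field(repr=False, default=None)


def _planted_genome(
    locus_seq: str, spacing: Optional[int], duse_site: str, pad: int = 200, seed: int = 0
) -> tuple[GenomeSequence, CandidateHit]:
    """Background + [DUSE + gap] + locus + background, with the candidate
    taken from the known implant coordinates."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    p = np.array([0.375, 0.125, 0.125, 0.375])
    bg = lambda n: "".join(bases[rng.choice(4, size=n, p=p)])
    if spacing is None:
        upstream = bg(pad)
    else:
        upstream = bg(pad) + duse_site + bg(spacing)
    residues = upstream + locus_seq + bg(60)
    genome = GenomeSequence("planted", residues)
    start = len(upstream)
    hit = CandidateHit(
        locus=Locus("planted", start, start + len(locus_seq), "+"),
        structural_score=builtin_candidate_score(locus_seq),
    )
    return genome, hit


def _example_locus(seed: int = 0) -> str:
    from .synthetic import _make_class1_sequence

    rng = np.random.default_rng(seed)
    seq, _motif = _make_class1_sequence(rng, SynthConfig(), default_motif_pwm())
    return seq


def measure_decision_boundaries(seed: int = 0) -> BoundaryReport:
    """Recover the classifier's constants by sweeping constructed inputs.

    * Distance adjustment as a function of DUSE-TSS spacing (20-120 nt in
      1-nt steps), with the canonical band read off the sweep.
    * Decision threshold: structural score held fixed, DUSE strength swept
      in exact 1-bit steps; the threshold is the smallest classified total.
    * Structural gate: DUSE strength held high, structural score swept; the
      gate is the smallest classified structural score.
    """
    duse_pwm = default_duse_pwm()
    tgtg_pwm = default_tgtg_pwm()
    config = ClassifierConfig()
    locus_seq = _example_locus(seed)
    site = duse_pwm.consensus

    rows = []
    for spacing in range(20, 121):
        genome, hit = _planted_genome(locus_seq, spacing, site, seed=seed)
        annotation = annotate_upstream(hit, genome, duse_pwm, tgtg_pwm, config)
        result = classify(hit, annotation, config)
        rows.append(
            {
                "spacing": spacing,
                "adjustment": result.distance_component,
                "distance_nt": annotation.duse_distance,
            }
        )
    sweep = pd.DataFrame(rows)
    bonus = sweep["adjustment"].max()
    band = sweep.loc[sweep["adjustment"] == bonus, "spacing"]
    band_lo, band_hi = int(band.min()), int(band.max())
    adjustment_correct = float(
        sweep.loc[sweep["spacing"] == 60, "adjustment"].iloc[0]
    )
    adjustment_wrong = float(
        sweep.loc[sweep["spacing"] == 100, "adjustment"].iloc[0]
    )

    genome_no_duse, hit = _planted_genome(locus_seq, None, site, seed=seed)
    annotation = annotate_upstream(hit, genome_no_duse, duse_pwm, tgtg_pwm, config)
    if annotation.duse is not None:  # pragma: no cover - rare chance match
        raise RuntimeError("background produced a chance DUSE; change the seed")
    adjustment_missing = classify(hit, annotation, config).distance_component

    # decision threshold: exact-scoring DUSE of k bits, structural fixed at 20
    threshold_candidates = []
    for k in range(4, 25):
        pwm_k = exact_duse_pwm(k)
        genome, hit = _planted_genome(locus_seq, 60, "C" * k, seed=seed)
        hit = replace(hit, structural_score=20.0)
        annotation = annotate_upstream(hit, genome, pwm_k, tgtg_pwm, config)
        result = classify(hit, annotation, config)
        if result.classified:
            threshold_candidates.append(result.total)
    decision_threshold = float(min(threshold_candidates))

    # structural gate: strong exact DUSE (24 bits), structural swept finely
    pwm24 = exact_duse_pwm(24)
    genome, base_hit = _planted_genome(locus_seq, 60, "C" * 24, seed=seed)
    gate_candidates = []
    for s in np.arange(5.0, 30.25, 0.25):
        hit = replace(base_hit, structural_score=float(s))
        annotation = annotate_upstream(hit, genome, pwm24, tgtg_pwm, config)
        result = classify(hit, annotation, config)
        if result.classified:
            gate_candidates.append(result.structural_component)
    structural_gate = float(min(gate_candidates))

    return BoundaryReport(
        adjustment_correct=adjustment_correct,
        adjustment_wrong=adjustment_wrong,
        adjustment_missing=float(adjustment_missing),
        spacing_band=(band_lo, band_hi),
        spacing_band_center=(band_lo + band_hi) / 2,
        decision_threshold=decision_threshold,
        structural_gate=structural_gate,
        spacing_sweep=sweep,
    )


@dataclass
class BenchmarkReport:
    """Recovery metrics of the full pipeline on one synthetic genome."""

    config: SynthConfig
    n_candidates: int
    n_classified: int
    n_true: int
    n_true_classified: int
    sensitivity: float
    decoys_classified: dict            # class -> count classified
    n_duse_absent_classified: int
    auc_total: float
    auc_structural: float
    median_length: float
    median_gc: float
    stem_pairs_mode: int
    motif_length: int
    expressed_fraction_of_classified: float
    comparison: object = field(repr=False, default=None)
    results: list = field(repr=False, default_factory=list)
    truth: TruthSet = field(repr=False, default=None)


def _overlapping_truth(locus: Locus, truth: TruthSet, min_frac: float = 0.5):
    """The truth entry covered by >= ``min_frac`` of its width on the same
    strand, or None."""
    best = None
    for entry in truth.entries:
        t = entry.locus
        if t.strand != locus.strand or t.seq_id != locus.seq_id:
            continue
        overlap = min(t.end, locus.end) - max(t.start, locus.start)
        if overlap >= min_frac * t.width:
            if best is None or overlap > best[0]:
                best = (overlap, entry)
    return None if best is None else best[1]


def run_benchmark(config: Optional[SynthConfig] = None) -> BenchmarkReport:
    """Generate, search, classify and validate one synthetic genome."""
    config = config or SynthConfig()
    genome, truth = generate_genome(config)
    hits = find_candidates(genome, SearchParams())
    results = classify_genome(genome, hits)

    matches = [_overlapping_truth(r.candidate.locus, truth) for r in results]
    truth_labels = np.array([m is not None and m.cls == TRUE for m in matches])

    classified_keys = {
        m.locus.key() for r, m in zip(results, matches) if r.classified and m is not None
    }
    true_entries = truth.true_entries
    n_true_classified = sum(e.locus.key() in classified_keys for e in true_entries)
    decoys_classified = {
        cls: sum(e.locus.key() in classified_keys for e in truth.of_class(cls))
        for cls in ("gene_no_duse", "duse_wrong_distance", "duse_only", "shuffled_motif")
    }

    totals = np.array([r.total for r in results])
    structurals = np.array([r.structural_component for r in results])
    roc_total = roc_curve(totals, truth_labels)
    roc_structural = roc_curve(structurals, truth_labels)

    # Expression-label ROC comparison over the truth-matched candidates only:
    # background windows carry no gene architecture and are ranked identically
    # by both scores, so including them would dilute both AUCs equally and
    # mask the comparison the decoy classes are designed to probe.
    track = generate_coverage(genome, truth, config)
    matched_results = [r for r, m in zip(results, matches) if m is not None]
    calls = [call_expressed(track, r.candidate.locus) for r in matched_results]
    comparison = compare_classifiers(matched_results, calls)

    n_classified = int(sum(r.classified for r in results))
    classified_calls = [
        call_expressed(track, r.candidate.locus) for r in results if r.classified
    ]
    expressed_of_classified = (
        sum(c.expressed for c in classified_calls) / n_classified if n_classified else 0.0
    )

    seqs = [e.sequence for e in true_entries]
    comp = composition_stats(seqs)
    stems = [annotate_stem(s).n_pairs for s in seqs]
    stem_mode = int(pd.Series(stems).mode().iloc[0])

    return BenchmarkReport(
        config=config,
        n_candidates=len(results),
        n_classified=n_classified,
        n_true=len(true_entries),
        n_true_classified=int(n_true_classified),
        sensitivity=n_true_classified / len(true_entries) if true_entries else 0.0,
        decoys_classified=decoys_classified,
        n_duse_absent_classified=int(decoys_classified[GENE_NO_DUSE]),
        auc_total=roc_total.auc,
        auc_structural=roc_structural.auc,
        median_length=comp.median_length,
        median_gc=comp.median_gc,
        stem_pairs_mode=stem_mode,
        motif_length=default_motif_pwm().length,
        expressed_fraction_of_classified=float(expressed_of_classified),
        comparison=comparison,
        results=results,
        truth=truth,
    )
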