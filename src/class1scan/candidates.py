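"""Scored Class I gene candidates.

Candidates come from one of two sources: an external structural-homology
search ingested from its tabular output (``genome_io.read_tblout``), or the
built-in stand-in scorer defined here.  The stand-in is deliberately *not* a
covariance model: it is a transparent additive feature score over the
family's hallmarks (terminal stem, 11-nt motif, AAG/CTGT termini, length)
calibrated on the same bit scale as the structural gate, so that the
promoter-anchored classifier downstream can be exercised end-to-end.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .curation import GU_PAIRS, WC_PAIRS, annotate_stem, best_motif_window
from .genome_io import GenomeSequence, Locus, reverse_complement
from .motifs import PWM, encode, scan_scores

_STRAND_CODE = {"+": 0, "-": 1}


@dataclass(frozen=True)
class CandidateHit:
    """A structural-search hit with bit score and predicted transcript start."""

    locus: Locus
    structural_score: float
    source: str = "builtin"
    predicted_tss: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.structural_score):
            raise ValueError("structural_score must be finite")
        if self.source not in ("external", "builtin"):
            raise ValueError(f"unknown candidate source {self.source!r}")
        if self.predicted_tss is None:
            object.__setattr__(self, "predicted_tss", self.locus.five_prime)


@dataclass
class SearchParams:
    """Built-in scorer weights and reporting thresholds.

    ``min_report_score`` (default 15 bits) is the reporting gate applied to
    structural hits; windows of every length in ``[min_len, max_len]`` are
    scored on both strands.
    """

    min_report_score: float = 15.0
    min_len: int = 40
    max_len: int = 90
    stem_weight: float = 2.0
    terminus5_weight: float = 2.0
    terminus3_weight: float = 2.0
    length_penalty: float = 0.2
    target_length: int = 60
    stem_cap: int = 8
    max_offset: int = 3
    stem_min_pairs: int = 4
    min_loop: int = 3
    allow_GU: bool = True
    motif_slack: int = 3
    motif_pwm: Optional[PWM] = None
    tss_offset: int = 0

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        if self.motif_pwm is None:
            from .defaults import default_motif_pwm

            self.motif_pwm = default_motif_pwm()


def _terminus_matches(seq: str, ref: str) -> int:
    return sum(a == b for a, b in zip(seq, ref))


def builtin_candidate_score(seq: str, params: Optional[SearchParams] = None) -> float:
    """Additive hallmark score (bits) of a candidate window.

    ``S = 2*B + M + 2*T5 + 2*T3 - 0.2*|len - 60|`` with default weights,
    where B is the base-pair count of the best terminal stem (capped at 8),
    M the best 11-nt motif score within 3 nt 3' of the 5' stem arm (floored
    at 0), and T5/T3 the per-position matches of the termini to AAG and CTGT.
    Deterministic, and independent of any genomic context.
    """
    params = params or SearchParams()
    seq = seq.upper()
    if not (20 <= len(seq) <= 200):
        raise ValueError(f"sequence length {len(seq)} outside [20, 200]")
    stem = annotate_stem(
        seq,
        max_offset=params.max_offset,
        min_pairs=params.stem_min_pairs,
        allow_GU=params.allow_GU,
        min_loop=params.min_loop,
    )
    B = min(stem.n_pairs, params.stem_cap)
    _, motif_score = best_motif_window(seq, stem, params.motif_pwm, params.motif_slack)
    M = max(0.0, motif_score)
    T5 = _terminus_matches(seq[:3], "AAG")
    T3 = _terminus_matches(seq[-4:], "CTGT")
    return (
        params.stem_weight * B
        + M
        + params.terminus5_weight * T5
        + params.terminus3_weight * T3
        - params.length_penalty * abs(len(seq) - params.target_length)
    )


def _pair_matrix(allow_GU: bool) -> np.ndarray:
    pairm = np.zeros((5, 5), dtype=np.uint8)
    order = "ACGT"
    pairs = set(WC_PAIRS) | (set(GU_PAIRS) if allow_GU else set())
    for a, b in pairs:
        pairm[order.index(a), order.index(b)] = 1
    return pairm


def find_candidates(
    genome: GenomeSequence, params: Optional[SearchParams] = None
) -> list[CandidateHit]:
    """Exhaustive built-in candidate search over both strands.

    Windows of every length in ``[min_len, max_len]`` are scored with
    :func:`builtin_candidate_score`; windows at or above
    ``min_report_score`` are resolved to a non-overlapping set per strand by
    greedy score order (tie: lowest start, then plus strand), and returned
    sorted by genomic start.
    """
    from ._kernels import greedy_keep, scan_strand

    params = params or SearchParams()
    L = genome.length
    if L < params.min_len:
        return []
    pairm = _pair_matrix(params.allow_GU)
    pwm = params.motif_pwm
    aag = encode("AAG")
    ctgt = encode("CTGT")

    all_start: list[np.ndarray] = []
    all_end: list[np.ndarray] = []
    all_score: list[np.ndarray] = []
    all_strand: list[np.ndarray] = []
    for strand in ("+", "-"):
        seq = genome.residues if strand == "+" else reverse_complement(genome.residues)
        codes = encode(seq)
        motif_scores = np.full(L, -np.inf)
        ms = scan_scores(pwm, seq)
        motif_scores[: ms.size] = ms
        # t5[p] = matches of codes[p:p+3] to AAG; t3[q] = matches of codes[q-4:q] to CTGT
        t5 = np.zeros(L)
        for k in range(3):
            n = L - k
            t5[:n] += (codes[k : k + n] == aag[k]).astype(float)
        t3 = np.zeros(L + 1)
        for k in range(4):
            idx = np.arange(4, L + 1)
            t3[idx] += (codes[idx - 4 + k] == ctgt[k]).astype(float)
        cap = max(1024, L)
        while True:
            out_start = np.zeros(cap, dtype=np.int64)
            out_end = np.zeros(cap, dtype=np.int64)
            out_score = np.zeros(cap, dtype=np.float64)
            n = scan_strand(
                codes, pairm, motif_scores, t5, t3,
                pwm.length,
                params.min_len, params.max_len,
                params.max_offset, params.stem_min_pairs, params.min_loop,
                params.stem_cap, params.motif_slack,
                params.stem_weight, params.terminus5_weight,
                params.terminus3_weight, params.length_penalty,
                params.target_length,
                params.min_report_score,
                out_start, out_end, out_score,
            )
            if n <= cap:
                break
            cap = n
        out_start, out_end, out_score = out_start[:n], out_end[:n], out_score[:n]
        if strand == "-":
            out_start, out_end = L - out_end, L - out_start
        all_start.append(out_start)
        all_end.append(out_end)
        all_score.append(out_score)
        all_strand.append(np.full(n, _STRAND_CODE[strand], dtype=np.int8))

    starts = np.concatenate(all_start)
    ends = np.concatenate(all_end)
    scores = np.concatenate(all_score)
    strands = np.concatenate(all_strand)
    if starts.size == 0:
        return []
    # greedy order: score desc, then start asc, then plus strand, then end asc
    order = np.lexsort((ends, strands, starts, -scores))
    keep = greedy_keep(starts, ends, strands, order, L).astype(bool)
    hits = [
        CandidateHit(
            locus=Locus(genome.id, int(s), int(e), "+" if st == 0 else "-"),
            structural_score=float(sc),
            source="builtin",
        )
        for s, e, sc, st in zip(starts[keep], ends[keep], scores[keep], strands[keep])
    ]
    if params.tss_offset:
        hits = [shift_tss(h, params.tss_offset) for h in hits]
    hits.sort(key=lambda h: (h.locus.start, h.locus.strand))
    return hits


def shift_tss(hit: CandidateHit, offset: int) -> CandidateHit:
    """Shift the predicted TSS ``offset`` nt upstream of the hit 5' end."""
    tss = hit.locus.five_prime - offset if hit.locus.strand == "+" \
        else hit.locus.five_prime + offset
    return replace(hit, predicted_tss=tss)


def dedupe_hits(hits: Sequence[CandidateHit]) -> list[CandidateHit]:
    """Collapse overlapping same-strand hits to the highest-scoring one.

    Deterministic tie-breaking: highest score, then lowest start, then the
    plus strand.  Disjoint hits pass through unchanged.
    """
    ordered = sorted(
        hits,
        key=lambda h: (
            -h.structural_score,
            h.locus.seq_id,
            h.locus.start,
            _STRAND_CODE[h.locus.strand],
            h.locus.end,
        ),
    )
    kept: list[CandidateHit] = []
    for hit in ordered:
        if any(
            k.locus.strand == hit.locus.strand and k.locus.overlaps(hit.locus)
            for k in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.locus.seq_id, h.locus.start, h.locus.strand))
    return kept
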