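"""Class I hallmark curation and conserved-feature analyses.

Curation encodes the hallmarks of the RNA family: a short terminal stem
joining the 5' and 3' ends, an 11-nt sequence motif immediately 3' of the
5' stem arm, conserved AAG.../...CTGT termini, and (optionally) a run of T
residues downstream that acts as a Pol III terminator.  Cross-locus analyses
(base-pair table with compensatory mutations, length/GC composition,
pairedness profile of the 11-nt motif) summarise structural conservation
across a set of curated loci.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import BedRecord, GenomeSequence, Locus
from .motifs import PWM, score_window

logger = logging.getLogger(__name__)

# Watson-Crick and G-U wobble pairs, 5' residue first.
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "T"), ("T", "G")}


def pair_kind(a: str, b: str, allow_GU: bool = True) -> Optional[str]:
    """'WC', 'GU', or None.  N never pairs (background policy)."""
    if (a, b) in WC_PAIRS:
        return "WC"
    if allow_GU and (a, b) in GU_PAIRS:
        return "GU"
    return None


@dataclass(frozen=True)
class StemAnnotation:
    """The best terminal stem of a sequence.

    ``pairs`` lists (5' index, 3' index, kind) outermost first; pairs are
    nested and non-crossing by construction.  ``five_prime_G_index`` is the
    index of the first G residue on the 5' stem arm (outermost inward), or
    None: this is the completely conserved G that anchors the family's stem.
    """

    n_pairs: int
    pairs: tuple = ()
    five_prime_G_index: Optional[int] = None
    loop: tuple = (0, 0)


def annotate_stem(
    seq: str,
    max_offset: int = 3,
    min_pairs: int = 4,
    allow_GU: bool = True,
    min_loop: int = 3,
) -> StemAnnotation:
    """Find the best stem connecting the 5' and 3' ends of ``seq``.

    For every pair of start offsets (i from the 5' end, j from the 3' end,
    both <= ``max_offset``) consecutive base pairs (Watson-Crick plus G-U when
    ``allow_GU``) are extended inward with no mismatches, keeping at least
    ``min_loop`` unpaired residues between the arms.  The longest run wins;
    ties go to the smallest 5' offset, then the smallest 3' offset.  A best
    run shorter than ``min_pairs`` does not qualify as a stem (``n_pairs`` 0).
    """
    if len(seq) < 20:
        raise ValueError("annotate_stem requires sequences of at least 20 nt")
    seq = seq.upper()
    L = len(seq)
    best_run = 0
    best_ij = (0, 0)
    for i in range(max_offset + 1):
        for j in range(max_offset + 1):
            k = 0
            while True:
                x, y = i + k, L - 1 - j - k
                if y - x <= min_loop:
                    break
                if pair_kind(seq[x], seq[y], allow_GU) is None:
                    break
                k += 1
            if k > best_run:
                best_run, best_ij = k, (i, j)
    if best_run < min_pairs:
        return StemAnnotation(n_pairs=0, pairs=(), five_prime_G_index=None, loop=(0, L))
    i, j = best_ij
    pairs = tuple(
        (i + k, L - 1 - j - k, pair_kind(seq[i + k], seq[L - 1 - j - k], allow_GU))
        for k in range(best_run)
    )
    g_index = next((x for x, _, _ in pairs if seq[x] == "G"), None)
    loop = (i + best_run, L - j - best_run)
    return StemAnnotation(n_pairs=best_run, pairs=pairs, five_prime_G_index=g_index, loop=loop)


@dataclass
class CurationConfig:
    min_pairs: int = 4
    max_offset: int = 3
    allow_GU: bool = True
    min_loop: int = 3
    ctgt_min_identity: int = 3      # of 4: the terminus is "almost perfectly" conserved
    motif_floor_frac: float = 0.5   # fraction of PWM max for motif_ok
    motif_slack: int = 3            # motif may start up to this many nt 3' of the stem


@dataclass(frozen=True)
class CurationResult:
    stem: StemAnnotation
    stem_ok: bool
    terminus5_ok: bool
    terminus3_ok: bool
    motif_ok: bool
    motif_start: Optional[int]
    motif_score: float
    terminator: Optional[Locus] = None

    @property
    def passed(self) -> bool:
        return self.stem_ok and self.motif_ok and (self.terminus5_ok or self.terminus3_ok)


def best_motif_window(
    seq: str, stem: StemAnnotation, pwm: PWM, slack: int = 3
) -> tuple[Optional[int], float]:
    """Best-scoring motif window starting within ``slack`` nt 3' of the 5' stem arm.

    Without a qualifying stem the search anchors at the sequence start.
    Returns (start index or None, score; -inf when no window fits).
    """
    stem_end = stem.pairs[-1][0] if stem.n_pairs else -1
    best = (None, float("-inf"))
    for start in range(stem_end + 1, stem_end + 2 + slack):
        if start < 0 or start + pwm.length > len(seq):
            continue
        s = score_window(pwm, seq[start : start + pwm.length])
        if s > best[1]:
            best = (start, s)
    return best


def curate(
    seq: str,
    motif_pwm: Optional[PWM] = None,
    config: Optional[CurationConfig] = None,
) -> CurationResult:
    """Apply the Class I hallmark checks to a candidate sequence.

    ``passed`` requires a qualifying stem, a motif window scoring at least
    ``motif_floor_frac`` of the PWM maximum, and at least one conserved
    terminus: a 5' start of one or two A residues followed by a G that lies
    on the stem's 5' arm, or a 3' end matching CTGT at >=
    ``ctgt_min_identity`` of 4 positions.
    """
    if motif_pwm is None:
        from .defaults import default_motif_pwm

        motif_pwm = default_motif_pwm()
    config = config or CurationConfig()
    seq = seq.upper()
    stem = annotate_stem(
        seq,
        max_offset=config.max_offset,
        min_pairs=config.min_pairs,
        allow_GU=config.allow_GU,
        min_loop=config.min_loop,
    )
    stem_ok = stem.n_pairs >= config.min_pairs

    g = stem.five_prime_G_index
    terminus5_ok = (
        g is not None and 1 <= g <= 2 and all(c == "A" for c in seq[:g])
    )
    terminus3_ok = (
        len(seq) >= 4
        and sum(a == b for a, b in zip(seq[-4:], "CTGT")) >= config.ctgt_min_identity
    )
    motif_start, motif_score = best_motif_window(seq, stem, motif_pwm, config.motif_slack)
    motif_ok = motif_score >= config.motif_floor_frac * motif_pwm.max_score
    return CurationResult(
        stem=stem,
        stem_ok=stem_ok,
        terminus5_ok=terminus5_ok,
        terminus3_ok=terminus3_ok,
        motif_ok=motif_ok,
        motif_start=motif_start,
        motif_score=motif_score,
    )


# ---------------------------------------------------------------------------
# Cross-locus conservation tables
# ---------------------------------------------------------------------------

@dataclass
class PairTable:
    """Per-stem-position nucleotide-combination counts, outermost pair first.

    ``compensatory_count`` counts the distinct combinations (summed over
    positions) that differ from the position's modal pair at *both* positions
    yet still base-pair - the classic signature of structural rather than
    sequence conservation.
    """

    positions: list[Counter]
    modal: list[str]
    compensatory_count: int
    n_loci: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos, counter in enumerate(self.positions):
            for combo, count in sorted(counter.items()):
                rows.append(
                    {
                        "position": pos,
                        "pair": combo,
                        "count": count,
                        "pairs_up": pair_kind(combo[0], combo[1]) is not None,
                        "modal": combo == self.modal[pos],
                    }
                )
        return pd.DataFrame(rows)


def pair_table(items: Sequence[tuple[str, StemAnnotation]]) -> PairTable:
    """Tabulate stem base-pair combinations across loci, aligned from the stem base.

    Positions beyond a shorter stem's length are skipped for that locus
    (column sums therefore equal the number of loci covering the position).
    """
    max_len = max((stem.n_pairs for _, stem in items), default=0)
    positions = [Counter() for _ in range(max_len)]
    for seq, stem in items:
        seq = seq.upper()
        for pos, (x, y, _) in enumerate(stem.pairs):
            positions[pos][seq[x] + seq[y]] += 1
    modal = [
        min(c.items(), key=lambda kv: (-kv[1], kv[0]))[0] if c else ""
        for c in positions
    ]
    compensatory = 0
    for pos, counter in enumerate(positions):
        m = modal[pos]
        for combo in counter:
            if (
                combo != m
                and combo[0] != m[0]
                and combo[1] != m[1]
                and pair_kind(combo[0], combo[1]) is not None
            ):
                compensatory += 1
    return PairTable(
        positions=positions,
        modal=modal,
        compensatory_count=compensatory,
        n_loci=len(items),
    )


@dataclass
class CompositionSummary:
    """Per-locus length and GC fraction with medians."""

    frame: pd.DataFrame

    @property
    def median_length(self) -> float:
        return float(self.frame["length"].median())

    @property
    def median_gc(self) -> float:
        return float(self.frame["gc"].median())


def composition_stats(seqs: Sequence[str], species: Optional[Sequence[str]] = None) -> CompositionSummary:
    """Exact lengths and GC fractions; medians by the standard midpoint rule."""
    rows = []
    for idx, seq in enumerate(seqs):
        seq = seq.upper()
        if not seq:
            raise ValueError("empty sequence in composition_stats")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        row = {"length": len(seq), "gc": gc}
        if species is not None:
            row["species"] = species[idx]
        rows.append(row)
    return CompositionSummary(frame=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Secondary-structure pairedness profile
# ---------------------------------------------------------------------------

def max_pairing_structure(seq: str, min_loop: int = 3, allow_GU: bool = True) -> str:
    """Maximum base-pairing (Nussinov-style) dot-bracket structure.

    A deliberately simple stand-in for thermodynamic folding: it maximises the
    number of nested WC (+ G-U) pairs with a minimum hairpin loop of
    ``min_loop``.  Ties are resolved deterministically (leave position
    unpaired first, then the smallest pairing partner).
    """
    seq = seq.upper()
    n = len(seq)
    M = np.zeros((n + 1, n + 1), dtype=np.int32)  # M[i][j]: best pairs in seq[i:j]
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = M[i + 1][j]
            for k in range(i + min_loop + 1, j):
                if pair_kind(seq[i], seq[k], allow_GU) is not None:
                    cand = 1 + M[i + 1][k] + M[k + 1][j]
                    if cand > best:
                        best = cand
            M[i][j] = best
    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if M[i][j] == M[i + 1][j]:
                i += 1
                continue
            for k in range(i + min_loop + 1, j):
                if pair_kind(seq[i], seq[k], allow_GU) is not None:
                    if M[i][j] == 1 + M[i + 1][k] + M[k + 1][j]:
                        structure[i], structure[k] = "(", ")"
                        traceback(i + 1, k)
                        i = k + 1
                        break
            else:  # pragma: no cover - defensive
                i += 1

    traceback(0, n)
    return "".join(structure)


def paired_positions(structure: str) -> np.ndarray:
    """Boolean per-position paired flags from a dot-bracket string."""
    return np.array([c in "()" for c in structure], dtype=bool)


def pairedness_profile(
    seqs: Sequence[str],
    motif_starts: Sequence[int],
    motif_length: int = 11,
    structures: Optional[Sequence[str]] = None,
    min_loop: int = 3,
) -> np.ndarray:
    """Fraction of loci whose predicted structure pairs each motif position.

    Structures default to :func:`max_pairing_structure`; externally computed
    dot-bracket strings (e.g. from a thermodynamic folder) may be supplied
    instead.
    """
    counts = np.zeros(motif_length)
    n = np.zeros(motif_length)
    for idx, seq in enumerate(seqs):
        start = motif_starts[idx]
        if start is None or start + motif_length > len(seq):
            continue
        structure = structures[idx] if structures is not None else \
            max_pairing_structure(seq, min_loop=min_loop)
        flags = paired_positions(structure)
        counts += flags[start : start + motif_length]
        n += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(n > 0, counts / np.maximum(n, 1), 0.0)
    return profile


# ---------------------------------------------------------------------------
# Pol III terminator
# ---------------------------------------------------------------------------

def find_terminator(
    genome: GenomeSequence,
    locus: Locus,
    max_gap: int = 30,
    min_run: int = 4,
) -> Optional[Locus]:
    """First run of >= ``min_run`` T (transcript strand) starting within
    ``max_gap`` nt downstream of the locus 3' end.

    The run is reported in genomic coordinates and may extend beyond the gap;
    it qualifies iff it *starts* within the gap.
    """
    residues = genome.residues
    if locus.strand == "+":
        region_start = locus.end
        region = residues[region_start : min(genome.length, locus.end + max_gap + min_run * 4)]
        base = "T"
    else:
        region_end = locus.start
        region = residues[max(0, locus.start - max_gap - min_run * 4) : region_end][::-1]
        base = "A"  # T on the transcript strand is A on the forward strand
    run_start = None
    run_len = 0
    for offset, c in enumerate(region):
        if c == base:
            if run_len == 0:
                run_start = offset
            run_len += 1
            if run_len >= min_run and run_start < max_gap:
                # extend to the full run
                end = offset + 1
                while end < len(region) and region[end] == base:
                    end += 1
                if locus.strand == "+":
                    return Locus(locus.seq_id, locus.end + run_start, locus.end + end, "+")
                return Locus(locus.seq_id, locus.start - end, locus.start - run_start, "-")
        else:
            run_len = 0
            if offset >= max_gap:
                break
    return None


# ---------------------------------------------------------------------------
# Clusters and shared synteny
# ---------------------------------------------------------------------------

def clusters(loci: Sequence[Locus], max_gap: int = 1000) -> list[list[Locus]]:
    """Groups of >= 2 loci on the same contig within ``max_gap`` nt of each other."""
    out: list[list[Locus]] = []
    by_contig: dict[str, list[Locus]] = {}
    for loc in loci:
        by_contig.setdefault(loc.seq_id, []).append(loc)
    for contig_loci in by_contig.values():
        contig_loci.sort(key=lambda l: l.start)
        current = [contig_loci[0]]
        for loc in contig_loci[1:]:
            if loc.start - current[-1].end <= max_gap:
                current.append(loc)
            else:
                if len(current) >= 2:
                    out.append(current)
                current = [loc]
        if len(current) >= 2:
            out.append(current)
    return out


@dataclass
class SyntenyReport:
    """Pairs of loci in two genomes supported by shared flanking orthologs."""

    pairs: pd.DataFrame  # locus_a, locus_b, n_support, well_supported

    @property
    def well_supported(self) -> pd.DataFrame:
        if self.pairs.empty:
            return self.pairs
        return self.pairs[self.pairs["well_supported"]]


def read_ortholog_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_a, gene_b) -> mapping gene_a -> {gene_b, ...}."""
    mapping: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            mapping.setdefault(a, set()).add(b)
    return mapping


def _flanking_genes(locus: Locus, genes: Sequence[BedRecord], flank: int) -> set[str]:
    lo, hi = locus.start - flank, locus.end + flank
    return {
        g.name
        for g in genes
        if g.locus.seq_id == locus.seq_id and g.locus.start < hi and g.locus.end > lo
    }


def shared_synteny(
    loci_a: Sequence[Locus],
    genes_a: Sequence[BedRecord],
    loci_b: Sequence[Locus],
    genes_b: Sequence[BedRecord],
    ortholog_map: Mapping[str, set[str]],
    flank: int = 10_000,
) -> SyntenyReport:
    """Shared-synteny search between two genomes.

    For each locus in A the genes within ``flank`` nt are mapped through the
    ortholog table; loci in B lying within ``flank`` nt of any such ortholog
    are reported, with the number of distinct supporting orthologs.  Pairs
    with >= 2 supporting orthologs are flagged well-supported.  Gene ids
    absent from the map are skipped with a debug log.
    """
    rows = []
    flank_b = {id(loc): _flanking_genes(loc, genes_b, flank) for loc in loci_b}
    for loc_a in loci_a:
        orthologs: set[str] = set()
        for gene in _flanking_genes(loc_a, genes_a, flank):
            mapped = ortholog_map.get(gene)
            if mapped is None:
                logger.debug("gene %s absent from ortholog map; ignored", gene)
                continue
            orthologs |= mapped
        if not orthologs:
            continue
        for loc_b in loci_b:
            support = orthologs & flank_b[id(loc_b)]
            if support:
                rows.append(
                    {
                        "locus_a": loc_a.key(),
                        "locus_b": loc_b.key(),
                        "n_support": len(support),
                        "well_supported": len(support) >= 2,
                    }
                )
    columns = ["locus_a", "locus_b", "n_support", "well_supported"]
    return SyntenyReport(pairs=pd.DataFrame(rows, columns=columns))
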