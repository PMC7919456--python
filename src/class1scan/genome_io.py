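"""Reading and writing of the genomic file formats the pipeline touches.

All internal coordinates are 0-based, half-open.  External 1-based formats
(cmsearch tblout) are converted at the parsing boundary, in this module only.
"Upstream" is always relative to the direction of transcription: for a
minus-strand locus the upstream window lies at *higher* genomic coordinates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Locus:
    """A strand-aware genomic interval (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("Locus.seq_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Boundary coordinate of the transcript 5' end (the TSS side)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """Boundary coordinate of the transcript 3' end."""
        return self.end if self.strand == "+" else self.start

    def overlaps(self, other: "Locus") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> tuple:
        return (self.seq_id, self.start, self.end, self.strand)


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: identifier plus DNA residues over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeSequence.id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.residues)


def sanitize_residues(raw: str, seq_id: str = "?") -> str:
    """Upper-case and map any non-ACGTN residue to N (logged)."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        logger.warning(
            "sequence %s: %d residue type(s) outside ACGTN mapped to N: %s",
            seq_id,
            len(bad),
            "".join(sorted(bad)),
        )
        seq = "".join(c if c in VALID_RESIDUES else "N" for c in seq)
    return seq


def read_fasta(path) -> list[GenomeSequence]:
    """Read a multi-record FASTA file, order preserved.

    Lower-case residues are upper-cased; residues outside {A,C,G,T,N} are
    mapped to N with a logged warning.  An empty file or duplicate record
    identifiers raise ``ValueError``.
    """
    records = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id: {rec.id!r}")
            seen.add(rec.id)
            records.append(
                GenomeSequence(id=rec.id, residues=sanitize_residues(str(rec.seq), rec.id))
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(genomes: Iterable[GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as out:
        for g in genomes:
            out.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                out.write(g.residues[i : i + width] + "\n")


def genome_dict(genomes: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    return {g.id: g for g in genomes}


def extract_interval(genome: GenomeSequence, locus: Locus) -> str:
    """Residues of ``locus`` in transcript orientation.

    Plus strand returns the forward slice; minus strand returns its reverse
    complement.
    """
    if locus.seq_id != genome.id:
        raise ValueError(f"locus seq_id {locus.seq_id!r} does not match genome {genome.id!r}")
    if locus.end > genome.length:
        raise ValueError(
            f"locus [{locus.start}, {locus.end}) out of bounds for {genome.id} "
            f"(length {genome.length})"
        )
    seq = genome.residues[locus.start : locus.end]
    return seq if locus.strand == "+" else reverse_complement(seq)


def upstream_window(
    genome: GenomeSequence, locus: Locus, width: int = 150
) -> tuple[Optional[Locus], bool]:
    """Window of up to ``width`` nt immediately 5' of the transcript start.

    Strand-aware: for a plus-strand locus the window is ``[start-width, start)``;
    for a minus-strand locus it is ``[end, end+width)``.  The window is truncated
    at contig edges; the second element of the returned tuple flags truncation.
    An empty window (locus flush against the contig edge) is returned as
    ``None`` with the flag set.
    """
    if locus.strand == "+":
        s, e = max(0, locus.start - width), locus.start
        truncated = s > locus.start - width
    else:
        s, e = locus.end, min(genome.length, locus.end + width)
        truncated = e < locus.end + width
    if s >= e:
        return None, True
    return Locus(locus.seq_id, s, e, locus.strand), truncated


# ---------------------------------------------------------------------------
# cmsearch tblout
# ---------------------------------------------------------------------------

def read_tblout(path) -> list:
    """Parse hits in the cmsearch ``--tblout`` dialect.

    1-based inclusive seq_from/seq_to are converted to 0-based half-open
    coordinates; strand is taken from the strand column (a seq_from greater
    than seq_to also implies the minus strand).  The bit score is preserved as
    the hit's structural score.  Hits are returned sorted by (seq_id, start).
    """
    from .candidates import CandidateHit  # local import: avoids module cycle

    hits = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 15:
                raise ValueError(f"{path}:{lineno}: malformed tblout line ({len(fields)} fields)")
            try:
                seq_id = fields[0]
                seq_from = int(fields[7])
                seq_to = int(fields[8])
                strand = fields[9]
                score = float(fields[14])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed tblout line: {err}") from None
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if seq_from > seq_to:
                strand = "-"
                seq_from, seq_to = seq_to, seq_from
            locus = Locus(seq_id, seq_from - 1, seq_to, strand)
            hits.append(CandidateHit(locus=locus, structural_score=score, source="external"))
    hits.sort(key=lambda h: (h.locus.seq_id, h.locus.start))
    return hits


def write_tblout(hits: Sequence, path, query: str = "classI") -> None:
    """Write hits back out in the tblout dialect (inverse of :func:`read_tblout`)."""
    with open(path, "w") as out:
        out.write("#target name\taccession\tquery name\taccession\tmdl\tmdl from\t"
                  "mdl to\tseq from\tseq to\tstrand\ttrunc\tpass\tgc\tbias\tscore\t"
                  "E-value\tinc\tdescription of target\n")
        for h in hits:
            loc = h.locus
            if loc.strand == "+":
                seq_from, seq_to = loc.start + 1, loc.end
            else:
                seq_from, seq_to = loc.end, loc.start + 1
            out.write(
                f"{loc.seq_id} - {query} - cm 1 1 {seq_from} {seq_to} {loc.strand} "
                f"no 1 0.30 0.0 {h.structural_score:.1f} 1e-5 ! -\n"
            )


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    locus: Locus
    name: str = "."
    score: float = 0.0


def read_bed(path) -> list[BedRecord]:
    """Read BED (3-6 columns), 0-based half-open, strand defaulting to '+'."""
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "+"
            records.append(BedRecord(Locus(seq_id, start, end, strand), name, score))
    return records


def write_bed(loci: Iterable, path, names: Optional[Sequence[str]] = None,
              scores: Optional[Sequence[float]] = None) -> None:
    """Write loci as BED6 (0-based half-open, strand in column 6)."""
    loci = list(loci)
    names = list(names) if names is not None else ["."] * len(loci)
    scores = list(scores) if scores is not None else [0.0] * len(loci)
    with open(path, "w") as out:
        for loc, name, score in zip(loci, names, scores):
            out.write(f"{loc.seq_id}\t{loc.start}\t{loc.end}\t{name}\t{score:g}\t{loc.strand}\n")


class CoverageTrack:
    """Per-base, non-negative read counts per contig (forward-coordinate order).

    Positions not covered by any bedGraph interval are zero.
    """

    def __init__(self, counts: Optional[Mapping[str, np.ndarray]] = None):
        self._counts: dict[str, np.ndarray] = {}
        if counts:
            for seq_id, arr in counts.items():
                arr = np.asarray(arr, dtype=float)
                if (arr < 0).any():
                    raise ValueError(f"negative coverage for {seq_id}")
                self._counts[seq_id] = arr

    @property
    def seq_ids(self) -> list[str]:
        return list(self._counts)

    def per_base(self, seq_id: str, length: Optional[int] = None) -> np.ndarray:
        """Counts for ``seq_id``, zero-padded to ``length`` when given."""
        arr = self._counts.get(seq_id)
        if arr is None:
            if length is None:
                raise KeyError(f"no coverage for contig {seq_id!r} and no length given")
            return np.zeros(length, dtype=float)
        if length is not None and length > arr.size:
            arr = np.concatenate([arr, np.zeros(length - arr.size)])
        return arr

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._counts


def read_bedgraph(path, contig_lengths: Optional[Mapping[str, int]] = None) -> CoverageTrack:
    """Read a bedGraph file into a :class:`CoverageTrack`.

    Intervals are 0-based half-open; overlapping intervals on the same contig
    are a format error.  An empty file yields an all-zero track.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph line has fewer than 4 columns")
            seq_id, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value")
            intervals.setdefault(seq_id, []).append((start, end, value))
    counts: dict[str, np.ndarray] = {}
    for seq_id, ivs in intervals.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping bedGraph intervals on {seq_id} at {s2}")
        length = (contig_lengths or {}).get(seq_id, ivs[-1][1])
        arr = np.zeros(length, dtype=float)
        for s, e, v in ivs:
            arr[s:e] = v
        counts[seq_id] = arr
    if contig_lengths:
        for seq_id, length in contig_lengths.items():
            if seq_id not in counts:
                counts[seq_id] = np.zeros(length, dtype=float)
    return CoverageTrack(counts)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track as run-length-encoded bedGraph (zeros omitted)."""
    with open(path, "w") as out:
        for seq_id in track.seq_ids:
            arr = track.per_base(seq_id)
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [arr.size]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    out.write(f"{seq_id}\t{s}\t{e}\t{arr[s]:g}\n")
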