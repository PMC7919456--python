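"""Position-weight-matrix models for the DUSE and TGTG-box promoter elements.

A :class:`PWM` stores per-column probabilities (pseudocounted site frequencies)
and scores sequences in log-odds bits against a background composition.
``score_pvalue`` gives the exact null distribution of scores under the
background by dynamic programming over integer-discretized column scores, the
same construction used by standard motif scanners.

N residues score as background (zero log-odds contribution) everywhere.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_io import GenomeSequence, Locus, extract_interval, reverse_complement

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate("ACGTN")}


_CODE_TABLE = np.full(256, 4, dtype=np.int8)
for _c, _i in _CODE.items():
    _CODE_TABLE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string over {A,C,G,T,N} to integer codes 0..4 (other -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


@dataclass
class PWM:
    """Log-odds motif model (bits), columns over A,C,G,T."""

    name: str
    probs: np.ndarray          # (length, 4) column probabilities
    background: np.ndarray     # (4,) background probabilities
    pseudocount: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (length, 4)")
        if self.length < 4:
            raise ValueError("PWM length must be >= 4")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each PWM column must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 4) log2(p / background)."""
        return np.log2(self.probs / self.background)

    @property
    def lookup(self) -> np.ndarray:
        """(length, 5) log-odds with a zero column for N (background policy)."""
        lo = self.log_odds
        return np.concatenate([lo, np.zeros((self.length, 1))], axis=1)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name + "_rc",
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence at a genomic locus."""

    locus: Locus
    score: float
    matched: str
    pvalue: Optional[float] = None


def build_pwm(
    sites: Sequence[str],
    name: str = "motif",
    pseudocount: float = 0.1,
    background: Optional[Sequence[float]] = None,
) -> PWM:
    """Build a PWM from equal-length aligned sites.

    Column probabilities are ``(count + pseudocount) / (n + 4*pseudocount)``
    and log-odds are ``log2(p / background)``.
    """
    sites = [s.upper() for s in sites]
    if not sites:
        raise ValueError("at least one site is required")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("sites must all have the same length")
    if any(set(s) - set(ALPHABET) for s in sites):
        raise ValueError("sites must contain only A, C, G, T")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValueError("background probabilities must all be positive")
    counts = np.zeros((length, 4))
    for s in sites:
        for j, c in enumerate(s):
            counts[j, ALPHABET.index(c)] += 1
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return PWM(name=name, probs=probs, background=background, pseudocount=pseudocount)


def score_window(pwm: PWM, seq: str) -> float:
    """Log-odds score (bits) of a window exactly the PWM's length.

    N contributes 0 at its column (scores as background).
    """
    if len(seq) != pwm.length:
        raise ValueError(f"window length {len(seq)} != PWM length {pwm.length}")
    lut = pwm.lookup
    codes = encode(seq.upper())
    return float(lut[np.arange(pwm.length), codes].sum())


def scan_scores(pwm: PWM, seq: str) -> np.ndarray:
    """Scores of every offset of ``seq`` (length ``len(seq) - L + 1``)."""
    codes = encode(seq.upper())
    n = codes.size - pwm.length + 1
    if n <= 0:
        return np.empty(0)
    lut = pwm.lookup
    scores = np.zeros(n)
    for k in range(pwm.length):
        scores += lut[k, codes[k : k + n]]
    return scores


def scan(
    pwm: PWM,
    genome: GenomeSequence,
    window: Optional[Locus],
    min_score: float,
    both_strands: bool = False,
) -> list[MotifHit]:
    """Scan a window for motif occurrences scoring at least ``min_score``.

    The window is scanned in transcript orientation (its own strand) only,
    unless ``both_strands`` is set.  Hits are sorted by descending score,
    then ascending genomic start.  A window shorter than the PWM yields an
    empty result.
    """
    if window is None:
        return []
    hits: list[MotifHit] = []

    def _collect(oriented_seq: str, strand: str) -> None:
        # offset is along the scanned strand's 5'->3' direction; map back to
        # forward genomic coordinates of the matched bases
        scores = scan_scores(pwm, oriented_seq)
        for offset in np.flatnonzero(scores >= min_score):
            offset = int(offset)
            if strand == "+":
                start = window.start + offset
            else:
                start = window.end - offset - pwm.length
            hits.append(
                MotifHit(
                    locus=Locus(window.seq_id, start, start + pwm.length, strand),
                    score=float(scores[offset]),
                    matched=oriented_seq[offset : offset + pwm.length],
                )
            )

    oriented = extract_interval(genome, window)
    _collect(oriented, window.strand)
    if both_strands:
        other = "-" if window.strand == "+" else "+"
        _collect(reverse_complement(oriented), other)
    hits.sort(key=lambda h: (-h.score, h.locus.start))
    return hits


def score_pvalue(pwm: PWM, score: float, granularity: float = 1e-3) -> float:
    """P(random background sequence of the PWM's length scores >= ``score``).

    Exact up to integer discretization of the column log-odds at
    ``granularity`` bits, by dynamic programming over the discretized score
    distribution under the background.  Monotone non-increasing in ``score``.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    ints = np.rint(pwm.log_odds / granularity).astype(np.int64)  # (L, 4)
    lo_min = int(ints.min(axis=1).sum())
    lo_max = int(ints.max(axis=1).sum())
    t = int(math.ceil(score / granularity - 1e-9))
    if t <= lo_min:
        return 1.0
    if t > lo_max:
        return 0.0
    dist: dict[int, float] = {0: 1.0}
    for col in range(pwm.length):
        new: dict[int, float] = {}
        for v, p in dist.items():
            for letter in range(4):
                key = v + int(ints[col, letter])
                new[key] = new.get(key, 0.0) + p * pwm.background[letter]
        dist = new
    return float(sum(p for v, p in dist.items() if v >= t))


# ---------------------------------------------------------------------------
# Site alignments and MEME minimal motif format
# ---------------------------------------------------------------------------

def read_sites(path) -> list[str]:
    """Plain-text site alignment: one site per line, '#' comments allowed."""
    sites = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                sites.append(line.upper())
    return sites


def write_sites(sites: Iterable[str], path) -> None:
    with open(path, "w") as out:
        for s in sites:
            out.write(s + "\n")


def write_meme(pwms: Sequence[PWM], path) -> None:
    """Serialize PWMs in MEME minimal motif format."""
    pwms = list(pwms)
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    with open(path, "w") as out:
        out.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        out.write("Background letter frequencies\n")
        out.write(" ".join(f"{c} {p:.6f}" for c, p in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            out.write(f"MOTIF {pwm.name}\n")
            out.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                out.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            out.write("\n")


def read_meme(path, pseudocount: float = 0.1) -> list[PWM]:
    """Read PWMs from MEME minimal motif format."""
    from Bio import motifs as bio_motifs

    with open(path) as handle:
        record = bio_motifs.parse(handle, "minimal")
    background = np.array([record.background[c] for c in ALPHABET])
    out = []
    for m in record:
        probs = np.array([[m.pwm[c][j] for c in ALPHABET] for j in range(m.length)])
        probs = probs / probs.sum(axis=1, keepdims=True)
        out.append(PWM(name=m.name, probs=probs, background=background,
                       pseudocount=pseudocount))
    return out
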