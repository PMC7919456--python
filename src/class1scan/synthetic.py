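"""Seedable synthetic genomes with implanted Class I-like loci and decoys.

The generator emulates the statistical structure the analysis assumes:
AT-rich background; loci of median ~60 nt and GC 32-41% built as
AA + G-opened terminal stem + 11-nt motif + variable loop + complementary
arm + CTGT, with a DUSE promoter element ~60 nt upstream of the transcript
start (optionally relayed through an AAATGTG TGTG box), a downstream run of
T residues, and occasional clusters of two loci.  Decoy classes probe each
classifier component independently:

* ``gene_no_duse``       - full gene architecture, no upstream DUSE;
* ``duse_wrong_distance``- full gene, DUSE at a fixed wrong spacing (100 nt);
* ``duse_only``          - a DUSE with unstructured downstream sequence;
* ``shuffled_motif``     - full gene with the 11-nt motif scrambled.

All randomness flows from the single explicit seed in :class:`SynthConfig`;
no global random state is touched.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .curation import CurationConfig, annotate_stem, curate
from .defaults import default_duse_pwm, default_motif_pwm
from .genome_io import (
    CoverageTrack,
    GenomeSequence,
    Locus,
    reverse_complement,
    write_bedgraph,
    write_fasta,
)
from .motifs import PWM, scan_scores, score_window, write_sites

TRUE = "true"
GENE_NO_DUSE = "gene_no_duse"
DUSE_WRONG_DISTANCE = "duse_wrong_distance"
DUSE_ONLY = "duse_only"
SHUFFLED_MOTIF = "shuffled_motif"
DECOY_CLASSES = (GENE_NO_DUSE, DUSE_WRONG_DISTANCE, DUSE_ONLY, SHUFFLED_MOTIF)

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "T", "T": "G"}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark."""

    genome_length: int = 200_000
    background_gc: float = 0.25
    n_true: int = 30
    n_gene_no_duse: int = 10
    n_duse_wrong_distance: int = 10
    n_duse_only: int = 10
    n_shuffled_motif: int = 10
    locus_length: tuple = (50, 70)
    locus_gc: tuple = (0.32, 0.41)
    stem_pairs: int = 6
    motif_length: int = 11
    duse_spacing: int = 60
    duse_jitter: int = 3
    wrong_spacing: int = 100
    tgtg_mode: bool = False
    tgtg_gap: tuple = (20, 40)
    cluster_fraction: float = 0.2
    expressed_fraction: float = 0.9
    terminator_gap: int = 5
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0 < self.locus_length[0] < self.locus_length[1]):
            raise ValueError("invalid locus_length range")
        if not (0 <= self.locus_gc[0] < self.locus_gc[1] <= 1):
            raise ValueError("invalid locus_gc range")
        for frac in (self.background_gc, self.cluster_fraction, self.expressed_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.stem_pairs < 3:
            raise ValueError("stem_pairs must be >= 3 (two conserved + inner pairs)")
        if min(self.n_true, self.n_gene_no_duse, self.n_duse_wrong_distance,
               self.n_duse_only, self.n_shuffled_motif) < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class TruthEntry:
    locus: Locus
    cls: str
    expressed: bool
    sequence: str                    # transcript-oriented locus residues
    duse: Optional[Locus] = None
    duse_site: Optional[str] = None
    motif_site: Optional[str] = None


@dataclass
class TruthSet:
    """Implanted-element labels driving recovery and ROC tests."""

    entries: list

    def of_class(self, cls: str) -> list[TruthEntry]:
        return [e for e in self.entries if e.cls == cls]

    @property
    def true_entries(self) -> list[TruthEntry]:
        return self.of_class(TRUE)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seq_id": e.locus.seq_id,
                "start": e.locus.start,
                "end": e.locus.end,
                "strand": e.locus.strand,
                "class": e.cls,
                "expressed": e.expressed,
            }
            for e in self.entries
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as out:
            for e in self.entries:
                name = f"{e.cls}|expressed={int(e.expressed)}"
                out.write(
                    f"{e.locus.seq_id}\t{e.locus.start}\t{e.locus.end}\t"
                    f"{name}\t0\t{e.locus.strand}\n"
                )


def _draw_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _draw_site(rng: np.random.Generator, pwm: PWM, min_frac: float, max_tries: int = 200) -> str:
    """Draw a functional site from the PWM's column distributions.

    Sites are redrawn until they score at least ``min_frac`` of the PWM
    maximum: implanted elements represent *functional* instances, not the
    full tail of the motif distribution.
    """
    letters = np.array(list("ACGT"))
    for _ in range(max_tries):
        idx = np.array([rng.choice(4, p=row) for row in pwm.probs])
        site = "".join(letters[idx])
        if score_window(pwm, site) >= min_frac * pwm.max_score:
            return site
    raise RuntimeError("could not draw a qualifying site")  # pragma: no cover


def _make_class1_sequence(
    rng: np.random.Generator,
    config: SynthConfig,
    motif_pwm: PWM,
    scramble_motif: bool = False,
    max_tries: int = 80,
) -> tuple[str, str]:
    """One locus sequence (transcript orientation) plus its motif instance.

    The terminal stem comprises the conserved A:T and G:C pairs formed by the
    AAG.../...CTGT termini plus ``stem_pairs - 2`` sampled inner pairs
    (occasionally G-U).  Rejection sampling guarantees the constructed
    architecture is the one the annotation recovers (designed stem is the
    best terminal stem; hallmarks pass curation).
    """
    inner_len = config.stem_pairs - 2
    for _ in range(max_tries):
        length = int(rng.integers(config.locus_length[0], config.locus_length[1] + 1))
        loop_len = length - (7 + inner_len * 2 + config.motif_length)
        if loop_len < 6:
            continue
        inner5 = []
        for _ in range(inner_len):
            base = "ACGT"[rng.choice(4, p=[0.3, 0.2, 0.2, 0.3])]
            if base in _WOBBLE and rng.random() < 0.15:
                partner = _WOBBLE[base]
            else:
                partner = _COMPLEMENT[base]
            inner5.append((base, partner))
        motif = _draw_site(rng, motif_pwm, 0.6)
        if scramble_motif:
            perm = list(motif)
            for _ in range(50):
                rng.shuffle(perm)
                if score_window(motif_pwm, "".join(perm)) < 0.4 * motif_pwm.max_score:
                    break
            motif = "".join(perm)
        arm5 = "".join(b for b, _ in inner5)
        arm3 = "".join(p for _, p in reversed(inner5))
        fixed = "AAG" + arm5 + motif + arm3 + "CTGT"
        fixed_gc = fixed.count("G") + fixed.count("C")
        target_gc = rng.uniform(*config.locus_gc)
        # the residue closing the loop must not pair with the motif's first
        # base, else the annotated stem would extend past the designed pairs
        guard = "C" if motif[0] == "T" else "A"
        # place an exact G+C count in the loop so the locus composition hits
        # the configured band, not merely its expectation
        need = int(round(target_gc * length)) - fixed_gc - (guard in "GC")
        rest_len = loop_len - 1
        need = min(max(need, 0), rest_len)
        rest = np.where(rng.random(rest_len) < 0.5, "A", "T").astype(object)
        gc_idx = rng.choice(rest_len, size=need, replace=False)
        rest[gc_idx] = np.where(rng.random(need) < 0.5, "G", "C")
        loop = list(rest) + [guard]
        seq = "AAG" + arm5 + motif + "".join(loop) + arm3 + "CTGT"
        assert len(seq) == length
        stem = annotate_stem(seq)
        if stem.n_pairs != config.stem_pairs or stem.pairs[0][0] != 1:
            continue
        result = curate(seq, motif_pwm)
        if scramble_motif:
            if result.stem_ok and (result.terminus5_ok or result.terminus3_ok) \
                    and not result.motif_ok:
                return seq, motif
        elif result.passed:
            return seq, motif
    raise RuntimeError("failed to construct a locus meeting its own architecture")


@dataclass
class _Element:
    cls: str
    expressed: bool
    string: str          # transcript-oriented element (pad+DUSE+gap+locus+terminator)
    locus_off: int
    locus_len: int
    duse_off: Optional[int]
    duse_site: Optional[str]
    motif_site: Optional[str]
    sequence: str


def _make_element(
    rng: np.random.Generator,
    config: SynthConfig,
    cls: str,
    expressed: bool,
    duse_pwm: PWM,
    motif_pwm: PWM,
) -> _Element:
    pad = _draw_background(rng, 20, config.background_gc)
    duse_site = None
    motif_site = None
    if cls == DUSE_ONLY:
        locus_len = int(rng.integers(config.locus_length[0], config.locus_length[1] + 1))
        locus_seq = _draw_background(rng, locus_len, config.background_gc)
    else:
        locus_seq, motif_site = _make_class1_sequence(
            rng, config, motif_pwm, scramble_motif=(cls == SHUFFLED_MOTIF)
        )
    upstream = ""
    duse_off = None
    if cls != GENE_NO_DUSE:
        duse_site = _draw_site(rng, duse_pwm, 0.7)
        if cls == DUSE_WRONG_DISTANCE:
            spacing = config.wrong_spacing
        elif cls == TRUE and config.duse_jitter:
            spacing = config.duse_spacing + int(
                rng.integers(-config.duse_jitter, config.duse_jitter + 1)
            )
        else:
            spacing = config.duse_spacing
        if config.tgtg_mode and cls == TRUE:
            tgtg_gap = int(rng.integers(config.tgtg_gap[0], config.tgtg_gap[1] + 1))
            gap1 = _draw_background(rng, spacing, config.background_gc)
            gap2 = _draw_background(rng, tgtg_gap, config.background_gc)
            upstream = duse_site + gap1 + "AAATGTG" + gap2
        else:
            upstream = duse_site + _draw_background(rng, spacing, config.background_gc)
        duse_off = len(pad)
    else:
        upstream = _draw_background(rng, config.duse_spacing, config.background_gc)
    downstream = (
        _draw_background(rng, config.terminator_gap, config.background_gc)
        + "TTTT"
        + _draw_background(rng, 10, config.background_gc)
    )
    string = pad + upstream + locus_seq + downstream
    return _Element(
        cls=cls,
        expressed=expressed,
        string=string,
        locus_off=len(pad) + len(upstream),
        locus_len=len(locus_seq),
        duse_off=duse_off,
        duse_site=duse_site,
        motif_site=motif_site,
        sequence=locus_seq,
    )


def _scrub_spurious_duse(
    residues: list,
    entry_locus: Locus,
    genome_id: str,
    duse_pwm: PWM,
    rng: np.random.Generator,
    config: SynthConfig,
    window: int = 150,
) -> None:
    """Rewrite any chance DUSE match upstream of a no-DUSE decoy."""
    from .genome_io import upstream_window as _uw

    floor = 0.6 * duse_pwm.max_score
    for _ in range(20):
        genome = GenomeSequence(genome_id, "".join(residues))
        win, _trunc = _uw(genome, entry_locus, window)
        if win is None:
            return
        from .genome_io import extract_interval

        oriented = extract_interval(genome, win)
        scores = scan_scores(duse_pwm, oriented)
        if scores.size == 0 or scores.max() < floor:
            return
        offset = int(scores.argmax())
        if win.strand == "+":
            start = win.start + offset
        else:
            start = win.end - offset - duse_pwm.length
        replacement = _draw_background(rng, duse_pwm.length, config.background_gc)
        residues[start : start + duse_pwm.length] = list(replacement)


def generate_genome(config: Optional[SynthConfig] = None) -> tuple[GenomeSequence, TruthSet]:
    """Generate a synthetic contig and the labels of everything implanted.

    Fully reproducible from ``config.seed``; implanted elements never
    overlap, and a configured fraction of the true loci is placed in pairs
    less than ~500 nt apart (clusters).
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    duse_pwm = default_duse_pwm()
    motif_pwm = default_motif_pwm()
    genome_id = "synth_1"

    specs = [(TRUE, bool(rng.random() < config.expressed_fraction))
             for _ in range(config.n_true)]
    specs += [(GENE_NO_DUSE, False)] * config.n_gene_no_duse
    specs += [(DUSE_WRONG_DISTANCE, False)] * config.n_duse_wrong_distance
    specs += [(DUSE_ONLY, False)] * config.n_duse_only
    specs += [(SHUFFLED_MOTIF, False)] * config.n_shuffled_motif

    elements = [
        _make_element(rng, config, cls, expressed, duse_pwm, motif_pwm)
        for cls, expressed in specs
    ]

    # group true loci into clusters: pairs < ~500 nt apart in one orientation
    n_pairs = int(config.cluster_fraction * config.n_true / 2)
    true_idx = [i for i, e in enumerate(elements) if e.cls == TRUE]
    grouped: set[int] = set()
    groups: list[list] = []
    for p in range(n_pairs):
        a, b = true_idx[2 * p], true_idx[2 * p + 1]
        gap = int(rng.integers(50, 250))
        groups.append([elements[a], gap, elements[b]])
        grouped |= {a, b}
    for i, element in enumerate(elements):
        if i not in grouped:
            groups.append([element])
    rng.shuffle(groups)

    group_strings = []
    for group in groups:
        parts = []
        for item in group:
            parts.append(_draw_background(rng, item, config.background_gc)
                         if isinstance(item, int) else item.string)
        group_strings.append("".join(parts))
    total = sum(len(s) for s in group_strings)
    if total >= config.genome_length / 2:
        raise ValueError(
            f"implanted length {total} exceeds half the genome ({config.genome_length})"
        )
    free = config.genome_length - total
    n_groups = len(groups)
    cuts = np.sort(rng.integers(0, free + 1, size=n_groups))
    gaps = np.diff(np.concatenate([[0], cuts]))

    residues = list(_draw_background(rng, config.genome_length, config.background_gc))
    entries: list[TruthEntry] = []
    pos = 0
    for group, group_string, gap in zip(groups, group_strings, gaps):
        pos += int(gap)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = group_string if strand == "+" else reverse_complement(group_string)
        residues[pos : pos + len(group_string)] = list(placed)
        offset_in_group = 0
        for item in group:
            if isinstance(item, int):
                offset_in_group += item
                continue
            element = item
            if strand == "+":
                start = pos + offset_in_group + element.locus_off
            else:
                start = pos + len(group_string) - (
                    offset_in_group + element.locus_off + element.locus_len
                )
            locus = Locus(genome_id, start, start + element.locus_len, strand)
            duse_locus = None
            if element.duse_off is not None:
                if strand == "+":
                    ds = pos + offset_in_group + element.duse_off
                else:
                    ds = pos + len(group_string) - (
                        offset_in_group + element.duse_off + duse_pwm.length
                    )
                duse_locus = Locus(genome_id, ds, ds + duse_pwm.length, strand)
            entries.append(
                TruthEntry(
                    locus=locus,
                    cls=element.cls,
                    expressed=element.expressed,
                    sequence=element.sequence,
                    duse=duse_locus,
                    duse_site=element.duse_site,
                    motif_site=element.motif_site,
                )
            )
            offset_in_group += len(element.string)
        pos += len(group_string)

    for entry in entries:
        if entry.cls == GENE_NO_DUSE:
            _scrub_spurious_duse(residues, entry.locus, genome_id, duse_pwm, rng, config)

    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            if a.locus.overlaps(b.locus):  # pragma: no cover - construction guard
                raise RuntimeError(f"implanted loci overlap: {a.locus} / {b.locus}")

    return GenomeSequence(genome_id, "".join(residues)), TruthSet(entries=entries)


def generate_coverage(
    genome: GenomeSequence, truth: TruthSet, config: Optional[SynthConfig] = None
) -> CoverageTrack:
    """Poisson coverage emulating the RNA-seq validation signal.

    Expressed loci receive plateau coverage (mean 100 reads/base) with a
    sharp 5' edge over Poisson(0.5) background; unexpressed loci get
    background only.  Seeded from the same config seed (independent stream).
    """
    config = config or SynthConfig()
    rng = np.random.default_rng([config.seed, 104729])
    cov = rng.poisson(0.5, size=genome.length).astype(float)
    for entry in truth.entries:
        if entry.expressed:
            loc = entry.locus
            cov[loc.start : loc.end] = rng.poisson(100.0, size=loc.width)
            # crisp transcript boundaries: no read-through into the flanks
            if loc.strand == "+":
                cov[max(0, loc.start - 3) : loc.start] = 0.0
            else:
                cov[loc.end : loc.end + 3] = 0.0
    return CoverageTrack({genome.id: cov})


def benchmark_bundle(config: Optional[SynthConfig] = None, outdir="bench") -> dict:
    """Write the full benchmark to disk: genome, truth, coverage, site sets.

    Returns a dict of the written paths.
    """
    config = config or SynthConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(config)
    coverage = generate_coverage(genome, truth, config)
    paths = {
        "genome": outdir / "genome.fa",
        "truth": outdir / "truth.bed",
        "coverage": outdir / "coverage.bedgraph",
        "duse_sites": outdir / "duse_sites.txt",
        "motif_sites": outdir / "motif_sites.txt",
        "params": outdir / "params.json",
    }
    write_fasta([genome], paths["genome"])
    truth.to_bed(paths["truth"])
    write_bedgraph(coverage, paths["coverage"])
    write_sites([e.duse_site for e in truth.entries if e.duse_site], paths["duse_sites"])
    write_sites([e.motif_site for e in truth.entries if e.motif_site], paths["motif_sites"])
    with open(paths["params"], "w") as out:
        json.dump(asdict(config), out, indent=2, default=list)
    return paths
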