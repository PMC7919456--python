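import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from class1scan.genome_io import (
    CoverageTrack,
    GenomeSequence,
    Locus,
    extract_interval,
    read_bed,
    read_bedgraph,
    read_fasta,
    read_tblout,
    reverse_complement,
    sanitize_residues,
    upstream_window,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_tblout,
)

dna = st.text(alphabet="ACGTN", min_size=0, max_size=200)


@given(dna)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


@given(dna)
def test_reverse_complement_length_and_alphabet(seq):
    rc = reverse_complement(seq)
    assert len(rc) == len(seq)
    assert set(rc) <= set("ACGTN")


def test_locus_validation():
    with pytest.raises(ValueError):
        Locus("c", 10, 10)
    with pytest.raises(ValueError):
        Locus("c", -1, 5)
    with pytest.raises(ValueError):
        Locus("c", 0, 5, "*")
    with pytest.raises(ValueError):
        Locus("", 0, 5)


def test_locus_orientation_properties():
    plus = Locus("c", 10, 20, "+")
    minus = Locus("c", 10, 20, "-")
    assert plus.five_prime == 10 and plus.three_prime == 20
    assert minus.five_prime == 20 and minus.three_prime == 10
    assert plus.width == minus.width == 10
    assert plus.overlaps(Locus("c", 19, 30))
    assert not plus.overlaps(Locus("c", 20, 30))
    assert not plus.overlaps(Locus("other", 10, 20))


def test_sanitize_residues_maps_to_n():
    assert sanitize_residues("acgu") == "ACGT"
    assert sanitize_residues("AXGR") == "ANGN"


def test_fasta_round_trip(tmp_path):
    genomes = [GenomeSequence("a", "ACGT" * 30), GenomeSequence("b", "TTTTAAAA")]
    path = tmp_path / "x.fa"
    write_fasta(genomes, path)
    back = read_fasta(path)
    assert [(g.id, g.residues) for g in back] == [(g.id, g.residues) for g in genomes]


def test_fasta_duplicate_and_empty_errors(tmp_path):
    path = tmp_path / "dup.fa"
    path.write_text(">a\nACGT\n>a\nTTTT\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_fasta(path)
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(ValueError, match="no FASTA"):
        read_fasta(empty)


def test_extract_interval_minus_is_revcomp():
    genome = GenomeSequence("c", "AACCGGTTACGT")
    locus = Locus("c", 2, 8, "-")
    assert extract_interval(genome, locus) == reverse_complement("CCGGTT")
    with pytest.raises(ValueError):
        extract_interval(genome, Locus("c", 0, 99))


def test_upstream_window_strand_aware():
    genome = GenomeSequence("c", "A" * 100)
    win, trunc = upstream_window(genome, Locus("c", 50, 60, "+"), width=20)
    assert (win.start, win.end, win.strand) == (30, 50, "+")
    assert not trunc
    win, trunc = upstream_window(genome, Locus("c", 50, 60, "-"), width=20)
    assert (win.start, win.end, win.strand) == (60, 80, "-")
    assert not trunc


def test_upstream_window_truncation_and_edge():
    genome = GenomeSequence("c", "A" * 100)
    win, trunc = upstream_window(genome, Locus("c", 5, 15, "+"), width=20)
    assert (win.start, win.end) == (0, 5) and trunc
    win, trunc = upstream_window(genome, Locus("c", 0, 10, "+"), width=20)
    assert win is None and trunc
    win, trunc = upstream_window(genome, Locus("c", 90, 100, "-"), width=20)
    assert win is None and trunc


def test_tblout_round_trip(tmp_path):
    from class1scan.candidates import CandidateHit

    hits = [
        CandidateHit(Locus("c1", 10, 70, "+"), 21.5, source="external"),
        CandidateHit(Locus("c1", 100, 160, "-"), 17.0, source="external"),
    ]
    path = tmp_path / "hits.tbl"
    write_tblout(hits, path)
    back = read_tblout(path)
    assert [h.locus for h in back] == [h.locus for h in hits]
    assert [h.structural_score for h in back] == [21.5, 17.0]
    assert all(h.source == "external" for h in back)


def test_tblout_reversed_coordinates_imply_minus(tmp_path):
    path = tmp_path / "rev.tbl"
    path.write_text("c1 - q - cm 1 1 160 101 + no 1 0.3 0.0 9.5 1e-5 ! -\n")
    (hit,) = read_tblout(path)
    assert hit.locus == Locus("c1", 100, 160, "-")
    assert hit.predicted_tss == 160


def test_tblout_malformed_raises(tmp_path):
    path = tmp_path / "bad.tbl"
    path.write_text("c1 only three fields\n")
    with pytest.raises(ValueError, match="malformed"):
        read_tblout(path)


def test_bed_round_trip(tmp_path):
    loci = [Locus("c", 0, 10, "+"), Locus("c", 20, 35, "-")]
    path = tmp_path / "x.bed"
    write_bed(loci, path, names=["a", "b"], scores=[1.0, 2.5])
    records = read_bed(path)
    assert [r.locus for r in records] == loci
    assert [r.name for r in records] == ["a", "b"]
    assert [r.score for r in records] == [1.0, 2.5]


def test_bedgraph_round_trip(tmp_path):
    arr = np.array([0.0, 0.0, 3.0, 3.0, 1.0, 0.0, 2.0])
    path = tmp_path / "x.bedgraph"
    write_bedgraph(CoverageTrack({"c": arr}), path)
    back = read_bedgraph(path, contig_lengths={"c": 7})
    assert np.array_equal(back.per_base("c"), arr)


def test_bedgraph_overlap_and_negative_errors(tmp_path):
    path = tmp_path / "bad.bedgraph"
    path.write_text("c\t0\t10\t1\nc\t5\t15\t2\n")
    with pytest.raises(ValueError, match="overlapping"):
        read_bedgraph(path)
    path.write_text("c\t0\t10\t-1\n")
    with pytest.raises(ValueError, match="negative"):
        read_bedgraph(path)


def test_coverage_track_padding_and_missing():
    track = CoverageTrack({"c": np.arange(5, dtype=float)})
    assert track.per_base("c", 8).tolist() == [0, 1, 2, 3, 4, 0, 0, 0]
    assert np.array_equal(track.per_base("other", 3), np.zeros(3))
    with pytest.raises(KeyError):
        track.per_base("other")
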