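import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from class1scan.curation import (
    CurationConfig,
    StemAnnotation,
    annotate_stem,
    clusters,
    composition_stats,
    curate,
    find_terminator,
    max_pairing_structure,
    pair_kind,
    pair_table,
    paired_positions,
    pairedness_profile,
    shared_synteny,
)
from class1scan.defaults import default_motif_pwm
from class1scan.genome_io import BedRecord, GenomeSequence, Locus


def brute_force_stem(seq, max_offset=3, min_pairs=4, allow_GU=True, min_loop=3):
    """Reference implementation mirroring the documented stem rules."""
    seq = seq.upper()
    L = len(seq)
    best = (0, 0, 0)  # (run, i, j) with ties to smallest i then j
    for i in range(max_offset + 1):
        for j in range(max_offset + 1):
            k = 0
            while True:
                x, y = i + k, L - 1 - j - k
                if y - x <= min_loop or pair_kind(seq[x], seq[y], allow_GU) is None:
                    break
                k += 1
            if k > best[0]:
                best = (k, i, j)
    run, i, j = best
    if run < min_pairs:
        return 0, None
    return run, (i, j)


@given(st.text(alphabet="ACGT", min_size=20, max_size=30))
def test_annotate_stem_matches_brute_force(seq):
    ann = annotate_stem(seq)
    run, ij = brute_force_stem(seq)
    assert ann.n_pairs == run
    if run:
        assert (ann.pairs[0][0], len(seq) - 1 - ann.pairs[0][1]) == ij


def test_annotate_stem_known_construct():
    #  A A G C A G A ...loop... T C T G C T G T : designed 6-bp stem at i=1, j=2
    seq = "AAGCAGA" + "T" * 20 + "TCTGCTGT"
    ann = annotate_stem(seq)
    assert ann.n_pairs == 6
    assert ann.pairs[0][:2] == (1, len(seq) - 3)
    assert ann.five_prime_G_index == 2


def test_annotate_stem_requires_min_pairs_and_length():
    # (ACGT)x5 pairs inward from both ends until the loop floor stops it
    assert annotate_stem("ACGT" * 5).n_pairs == 8
    assert annotate_stem("A" * 30).n_pairs == 0
    with pytest.raises(ValueError):
        annotate_stem("ACGTACGT")


def test_annotate_stem_gu_toggle():
    # G:T wobble closes the outermost pair only when allow_GU is set
    seq = "GGGGG" + "A" * 15 + "CCCCT"
    assert annotate_stem(seq, allow_GU=True).n_pairs == 5
    assert annotate_stem(seq, allow_GU=False).n_pairs == 4


def test_curate_passes_on_generated_locus():
    from class1scan.synthetic import SynthConfig, _make_class1_sequence

    rng = np.random.default_rng(11)
    seq, motif = _make_class1_sequence(rng, SynthConfig(), default_motif_pwm())
    result = curate(seq)
    assert result.passed
    assert result.stem.n_pairs == 6
    assert result.terminus5_ok and result.terminus3_ok
    assert motif in seq


def test_curate_fails_without_stem():
    result = curate("A" * 60)
    assert not result.stem_ok
    assert not result.passed


def test_pair_table_compensatory():
    # two loci: modal pair GC at position 0; one locus has a compensatory AT
    s1 = "G" + "A" * 20 + "C"
    s2 = "A" + "A" * 20 + "T"
    a1 = StemAnnotation(n_pairs=1, pairs=((0, 21, "WC"),))
    a2 = StemAnnotation(n_pairs=1, pairs=((0, 21, "WC"),))
    table = pair_table([(s1, a1), (s1, a1), (s2, a2)])
    assert table.modal[0] == "GC"
    assert table.compensatory_count == 1
    frame = table.to_frame()
    assert frame.loc[frame.pair == "AT", "pairs_up"].all()


def test_composition_stats():
    summary = composition_stats(["ACGT", "AATT", "GGGGGG"])
    assert summary.median_length == 4
    assert summary.median_gc == pytest.approx(0.5)
    with pytest.raises(ValueError):
        composition_stats([""])


def test_max_pairing_structure_properties():
    s = max_pairing_structure("GGGGAAACCCC")
    assert s.count("(") == s.count(")") == 4
    # dot-bracket is balanced and respects the minimum loop
    stack = []
    pairs = []
    for i, c in enumerate(s):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    assert not stack
    assert all(j - i > 3 for i, j in pairs)
    assert paired_positions("(.)").tolist() == [True, False, True]


def test_pairedness_profile_counts_motif_positions():
    seqs = ["GGGG" + "A" * 11 + "TTTCCCC" + "A" * 8]
    profile = pairedness_profile(seqs, [4], motif_length=11)
    assert profile.shape == (11,)
    assert np.all((0 <= profile) & (profile <= 1))


def test_find_terminator_plus_and_minus():
    genome = GenomeSequence("c", "A" * 50 + "GG" + "TTTTT" + "A" * 43)
    term = find_terminator(genome, Locus("c", 20, 50, "+"))
    assert term == Locus("c", 52, 57, "+")
    # minus strand: terminator is an A-run at lower coordinates
    genome_m = GenomeSequence("c", "G" * 43 + "AAAAA" + "GG" + "C" * 50)
    term_m = find_terminator(genome_m, Locus("c", 50, 80, "-"))
    assert term_m == Locus("c", 43, 48, "-")


def test_find_terminator_gap_limit():
    genome = GenomeSequence("c", "A" * 30 + "G" * 40 + "TTTT" + "A" * 26)
    assert find_terminator(genome, Locus("c", 0, 30, "+"), max_gap=30) is None


def test_clusters():
    loci = [Locus("c", 0, 50), Locus("c", 200, 260), Locus("c", 5000, 5050),
            Locus("d", 0, 50)]
    groups = clusters(loci, max_gap=1000)
    assert len(groups) == 1
    assert [l.start for l in groups[0]] == [0, 200]


def test_shared_synteny_well_supported():
    loci_a = [Locus("a1", 1000, 1060)]
    genes_a = [BedRecord(Locus("a1", 0, 500), "gA1"), BedRecord(Locus("a1", 2000, 2500), "gA2")]
    loci_b = [Locus("b1", 1000, 1060)]
    genes_b = [BedRecord(Locus("b1", 0, 500), "gB1"), BedRecord(Locus("b1", 2000, 2500), "gB2")]
    omap = {"gA1": {"gB1"}, "gA2": {"gB2"}}
    report = shared_synteny(loci_a, genes_a, loci_b, genes_b, omap, flank=10_000)
    assert len(report.pairs) == 1
    assert report.pairs.iloc[0]["n_support"] == 2
    assert len(report.well_supported) == 1
    # dropping one ortholog demotes the pair
    report2 = shared_synteny(loci_a, genes_a, loci_b, genes_b, {"gA1": {"gB1"}})
    assert len(report2.well_supported) == 0
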