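import numpy as np
import pytest

from class1scan.candidates import (
    CandidateHit,
    SearchParams,
    builtin_candidate_score,
    dedupe_hits,
    find_candidates,
    shift_tss,
)
from class1scan.genome_io import (
    GenomeSequence,
    Locus,
    read_tblout,
    reverse_complement,
    write_tblout,
)


def test_polya_hand_score():
    # B=0, M=0, T5=2 (AA match AAG), T3=0, no length penalty
    assert builtin_candidate_score("A" * 60) == 4.0


def test_ctgt_truncation_additivity():
    # replacing the final T of CTGT with A loses one terminus match (-2);
    # poly-A elsewhere means no stem can form or change
    base = "A" * 56 + "CTGT"
    broken = "A" * 56 + "CTGA"
    assert builtin_candidate_score(base) - builtin_candidate_score(broken) == pytest.approx(2.0)


def test_length_penalty_term():
    assert builtin_candidate_score("A" * 70) == pytest.approx(4.0 - 0.2 * 10)


def test_score_length_bounds():
    with pytest.raises(ValueError):
        builtin_candidate_score("A" * 19)
    with pytest.raises(ValueError):
        builtin_candidate_score("A" * 201)


def test_candidate_hit_validation():
    with pytest.raises(ValueError):
        CandidateHit(Locus("c", 0, 60), float("nan"))
    with pytest.raises(ValueError):
        CandidateHit(Locus("c", 0, 60), 1.0, source="guess")
    hit = CandidateHit(Locus("c", 10, 70, "-"), 20.0)
    assert hit.predicted_tss == 70  # transcript 5' end on the minus strand


def test_shift_tss():
    hit = CandidateHit(Locus("c", 100, 160, "+"), 20.0)
    assert shift_tss(hit, 2).predicted_tss == 98
    minus = CandidateHit(Locus("c", 100, 160, "-"), 20.0)
    assert shift_tss(minus, 2).predicted_tss == 162


def test_search_params_validation():
    with pytest.raises(ValueError):
        SearchParams(min_len=90, max_len=40)


def _reference_find_candidates(genome, params):
    """Pure-Python exhaustive reference for the numba search kernel."""
    hits = []
    for strand in ("+", "-"):
        seq = genome.residues if strand == "+" else reverse_complement(genome.residues)
        L = len(seq)
        for p in range(L):
            for w in range(params.min_len, params.max_len + 1):
                if p + w > L:
                    break
                s = builtin_candidate_score(seq[p : p + w], params)
                if s >= params.min_report_score:
                    if strand == "+":
                        locus = Locus(genome.id, p, p + w, "+")
                    else:
                        locus = Locus(genome.id, L - (p + w), L - p, "-")
                    hits.append(CandidateHit(locus, s))
    return dedupe_hits(hits)


def test_find_candidates_matches_python_reference():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    residues = "".join(bases[rng.choice(4, size=500, p=[0.375, 0.125, 0.125, 0.375])])
    genome = GenomeSequence("g", residues)
    params = SearchParams()
    fast = find_candidates(genome, params)
    slow = _reference_find_candidates(genome, params)
    assert [(h.locus, round(h.structural_score, 9)) for h in fast] == [
        (h.locus, round(h.structural_score, 9)) for h in slow
    ]


def test_find_candidates_nonoverlap_per_strand():
    rng = np.random.default_rng(9)
    bases = np.array(list("ACGT"))
    residues = "".join(bases[rng.choice(4, size=3000, p=[0.375, 0.125, 0.125, 0.375])])
    hits = find_candidates(GenomeSequence("g", residues))
    for strand in ("+", "-"):
        strand_hits = sorted(
            (h for h in hits if h.locus.strand == strand), key=lambda h: h.locus.start
        )
        for a, b in zip(strand_hits, strand_hits[1:]):
            assert a.locus.end <= b.locus.start


def test_find_candidates_implanted_locus_recovered():
    from class1scan.defaults import default_motif_pwm
    from class1scan.synthetic import SynthConfig, _make_class1_sequence

    rng = np.random.default_rng(3)
    locus_seq, _ = _make_class1_sequence(rng, SynthConfig(), default_motif_pwm())
    bases = np.array(list("ACGT"))
    bg = lambda n: "".join(bases[rng.choice(4, size=n, p=[0.45, 0.05, 0.05, 0.45])])
    genome = GenomeSequence("g", bg(300) + locus_seq + bg(300))
    implant = Locus("g", 300, 300 + len(locus_seq), "+")
    hits = find_candidates(genome)
    covering = [h for h in hits if h.locus.strand == "+" and h.locus.overlaps(implant)]
    assert len(covering) == 1
    overlap = min(covering[0].locus.end, implant.end) - max(covering[0].locus.start, implant.start)
    assert overlap >= 0.8 * implant.width
    assert covering[0].structural_score >= 15.0


def test_score_invariant_under_context():
    seq = "AAG" + "C" * 10 + "A" * 30 + "G" * 10 + "CTGT"
    assert builtin_candidate_score(seq) == builtin_candidate_score(seq)
    # identical windows embedded in different genomes score identically
    g1 = GenomeSequence("a", "T" * 100 + seq + "T" * 100)
    g2 = GenomeSequence("b", "G" * 100 + seq + "G" * 100)
    from class1scan.genome_io import extract_interval

    w1 = extract_interval(g1, Locus("a", 100, 100 + len(seq)))
    w2 = extract_interval(g2, Locus("b", 100, 100 + len(seq)))
    assert builtin_candidate_score(w1) == builtin_candidate_score(w2)


def test_dedupe_examples():
    a = CandidateHit(Locus("c", 0, 60), 20.0)
    b = CandidateHit(Locus("c", 10, 70), 18.0)
    assert dedupe_hits([a, b]) == [a]
    c = CandidateHit(Locus("c", 100, 160), 18.0)
    assert dedupe_hits([a, c]) == [a, c]
    # equal scores, overlap -> keep lower start
    d = CandidateHit(Locus("c", 5, 65), 20.0)
    assert dedupe_hits([d, a]) == [a]
    # opposite strands may overlap freely
    e = CandidateHit(Locus("c", 0, 60, "-"), 10.0)
    assert dedupe_hits([a, e]) == [a, e]


def test_external_hits_survive_ingestion(tmp_path):
    hits = [
        CandidateHit(Locus("c", 0, 60, "+"), 15.0, source="external"),
        CandidateHit(Locus("c", 100, 160, "-"), 44.0, source="external"),
    ]
    path = tmp_path / "x.tbl"
    write_tblout(hits, path)
    back = read_tblout(path)
    assert [(h.locus, h.structural_score) for h in back] == [
        (h.locus, h.structural_score) for h in hits
    ]
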