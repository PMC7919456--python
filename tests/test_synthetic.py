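import json

import numpy as np
import pytest

from class1scan.curation import annotate_stem, curate
from class1scan.expression import call_expressed
from class1scan.genome_io import (
    extract_interval,
    read_bed,
    read_bedgraph,
    read_fasta,
)
from class1scan.synthetic import (
    DECOY_CLASSES,
    SynthConfig,
    benchmark_bundle,
    generate_coverage,
    generate_genome,
)


@pytest.fixture(scope="module")
def default_genome():
    config = SynthConfig(seed=7)
    genome, truth = generate_genome(config)
    return config, genome, truth


def test_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(locus_length=(70, 50))
    with pytest.raises(ValueError):
        SynthConfig(locus_gc=(0.5, 0.4))
    with pytest.raises(ValueError):
        SynthConfig(expressed_fraction=1.5)
    with pytest.raises(ValueError):
        SynthConfig(stem_pairs=2)
    with pytest.raises(ValueError):
        SynthConfig(n_true=-1)


def test_seed_determinism(default_genome):
    config, genome, truth = default_genome
    genome2, truth2 = generate_genome(SynthConfig(seed=7))
    assert genome2.residues == genome.residues
    assert [e.locus for e in truth2.entries] == [e.locus for e in truth.entries]
    cov1 = generate_coverage(genome, truth, config).per_base(genome.id)
    cov2 = generate_coverage(genome2, truth2, SynthConfig(seed=7)).per_base(genome.id)
    assert np.array_equal(cov1, cov2)


def test_different_seed_differs(default_genome):
    _, genome, _ = default_genome
    other, _ = generate_genome(SynthConfig(seed=8))
    assert other.residues != genome.residues


def test_class_counts_and_nonoverlap(default_genome):
    config, _, truth = default_genome
    counts = {cls: len(truth.of_class(cls)) for cls in ("true",) + DECOY_CLASSES}
    assert counts == {
        "true": 30, "gene_no_duse": 10, "duse_wrong_distance": 10,
        "duse_only": 10, "shuffled_motif": 10,
    }
    entries = truth.entries
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            assert not a.locus.overlaps(b.locus)


def test_true_loci_pass_curation_with_designed_stem(default_genome):
    _, genome, truth = default_genome
    for entry in truth.true_entries:
        assert extract_interval(genome, entry.locus) == entry.sequence
        result = curate(entry.sequence)
        assert result.passed
        assert annotate_stem(entry.sequence).n_pairs == 6


def test_composition_within_config(default_genome):
    config, _, truth = default_genome
    lo, hi = config.locus_length
    gc_lo, gc_hi = config.locus_gc
    lengths, gcs = [], []
    for entry in truth.true_entries:
        seq = entry.sequence
        lengths.append(len(seq))
        gcs.append((seq.count("G") + seq.count("C")) / len(seq))
    assert all(lo <= n <= hi for n in lengths)
    assert all(gc_lo - 0.05 <= gc <= gc_hi + 0.05 for gc in gcs)
    assert 55 <= float(np.median(lengths)) <= 65


def test_duse_spacing_by_class(default_genome):
    config, _, truth = default_genome
    for entry in truth.entries:
        if entry.duse is None:
            assert entry.cls == "gene_no_duse"
            continue
        tss = entry.locus.five_prime
        if entry.locus.strand == "+":
            gap = tss - entry.duse.end
        else:
            gap = entry.duse.start - tss
        if entry.cls == "duse_wrong_distance":
            assert gap == config.wrong_spacing
        else:
            assert abs(gap - config.duse_spacing) <= config.duse_jitter


def test_no_duse_decoys_have_clean_upstream(default_genome):
    from class1scan.defaults import default_duse_pwm
    from class1scan.genome_io import upstream_window
    from class1scan.motifs import scan

    _, genome, truth = default_genome
    pwm = default_duse_pwm()
    for entry in truth.of_class("gene_no_duse"):
        window, _ = upstream_window(genome, entry.locus, 150)
        hits = scan(pwm, genome, window, 0.6 * pwm.max_score)
        assert hits == []


def test_clusters_present(default_genome):
    from class1scan.curation import clusters

    _, _, truth = default_genome
    true_loci = [e.locus for e in truth.true_entries]
    assert len(clusters(true_loci, max_gap=500)) >= 1


def test_coverage_round_trip(default_genome):
    config, genome, truth = default_genome
    track = generate_coverage(genome, truth, config)
    for entry in truth.true_entries:
        call = call_expressed(track, entry.locus)
        assert call.expressed == entry.expressed


def test_strands_mixed(default_genome):
    _, _, truth = default_genome
    strands = {e.locus.strand for e in truth.entries}
    assert strands == {"+", "-"}


def test_infeasible_packing_raises():
    with pytest.raises(ValueError, match="implanted length"):
        generate_genome(SynthConfig(genome_length=10_000, seed=1))


def test_shuffled_motif_decoys_fail_motif_check(default_genome):
    _, _, truth = default_genome
    for entry in truth.of_class("shuffled_motif"):
        result = curate(entry.sequence)
        assert result.stem_ok
        assert not result.motif_ok


def test_benchmark_bundle(tmp_path):
    config = SynthConfig(seed=3)
    paths = benchmark_bundle(config, tmp_path / "bench")
    (genome,) = read_fasta(paths["genome"])
    records = read_bed(paths["truth"])
    assert len(records) == 70
    track = read_bedgraph(paths["coverage"], {genome.id: genome.length})
    assert track.per_base(genome.id).size == genome.length
    params = json.loads(paths["params"].read_text())
    assert params["seed"] == 3
    # bundle regeneration is byte-identical under the same seed
    paths2 = benchmark_bundle(SynthConfig(seed=3), tmp_path / "bench2")
    assert paths2["genome"].read_text() == paths["genome"].read_text()
    assert paths2["truth"].read_text() == paths["truth"].read_text()
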