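"""Packaged default motif models.

These are clearly-labelled stand-ins built from synthetic site alignments so
the pipeline is runnable and testable end-to-end without external motif
discovery.  They mirror the documented architecture of the real elements:

* DUSE: 11 columns with a C-rich core (three consecutive C residues).
* 11-nt Class I body motif: conserved T, C, C, A, A at positions 3, 6, 9,
  10 and 11 (1-based), moderate conservation elsewhere.
* TGTG box: fixed AAATGTG consensus.

Users analysing real genomes should supply their own site alignments
(``class1scan.motifs.read_sites`` / ``build_pwm``) or MEME minimal files.
"""
from __future__ import annotations

from functools import lru_cache

from .motifs import PWM, build_pwm

# Synthetic DUSE site alignment (consensus ATACCCATTTG, CCC core).
DUSE_SITES = [
    "ATACCCATTTG",
    "ATACCCATTTG",
    "ATACCCATTTG",
    "ATACCCATTTG",
    "ATACCCATTTG",
    "ATACCCATTTG",
    "ATACCCATTTG",
    "ATACCCATTTG",
    "ATACCCATTTG",
    "ATACCCATTTG",
    "TTACCCATTTG",
    "AAACCCATTTG",
    "ATCCCCATTTG",
    "ATACCCTTTTG",
    "ATACCCAATTG",
    "ATACCCATATG",
    "ATACCCATTAG",
    "ATACCCATTTT",
    "ATACCTATTTG",
    "ATACCCATTTG",
]

# Synthetic 11-nt body-motif alignment (consensus GATTACATCAA); positions
# 3, 6, 9, 10, 11 (T, C, C, A, A) are invariant across sites, the remaining
# six columns only weakly conserved (9/20 modal).  The weak conservation is
# deliberate: it bounds the maximum attainable built-in candidate score so
# that full gene architecture *without* a promoter cannot reach the
# classification threshold on structure alone.
MOTIF_SITES = [
    "GCTAACACCAA",
    "GCTAGCATCAA",
    "GCTCGCATCAA",
    "GATCGCATCAA",
    "GATCGCATCAA",
    "GATCTCATCAA",
    "GATGTCATCAA",
    "GATGTCCTCAA",
    "GATGTCCTCAA",
    "AATTCCCTCAA",
    "AATTCCCGCAA",
    "AATTCCTGCAA",
    "ATTTACTGCAA",
    "TTTTACTGCAA",
    "TTTTACTACAA",
    "TTTTACGACAA",
    "TGTTACGACAA",
    "CGTTACGACAA",
    "CGTAACACCAA",
    "CGTAACACCAA",
]

TGTG_CONSENSUS = "AAATGTG"


@lru_cache(maxsize=None)
def default_duse_pwm() -> PWM:
    return build_pwm(DUSE_SITES, name="DUSE", pseudocount=0.1)


@lru_cache(maxsize=None)
def default_motif_pwm() -> PWM:
    return build_pwm(MOTIF_SITES, name="classI_11nt", pseudocount=0.1)


@lru_cache(maxsize=None)
def default_tgtg_pwm() -> PWM:
    return build_pwm([TGTG_CONSENSUS], name="TGTG", pseudocount=0.1)
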