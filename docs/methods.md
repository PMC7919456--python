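# Methods note

This note records the scoring model, every numerical default and the reason
for it, what the synthetic generator does and does not emulate, and the known
limitations of the implementation.  No empirical claims are made here beyond
what the package itself computes.

## 1. Scoring model

### 1.1 Structural score

Candidates carry a structural score in bits.  Two sources are supported:

* **External**: bit scores of a covariance-model search ingested from tblout
  (1-based inclusive coordinates converted at the parsing boundary; a
  `seq from` greater than `seq to` implies the minus strand).
* **Built-in stand-in** (`builtin_candidate_score`): a transparent additive
  feature score over the family hallmarks,

  ```
  S = 2·B + M + 2·T5 + 2·T3 − 0.2·|len − 60|
  ```

  with `B` the base-pair count of the best terminal stem (capped at 8), `M`
  the best 11-nt motif PWM score starting within 3 nt 3′ of the 5′ stem arm
  (floored at 0), and `T5`/`T3` the per-position matches of the termini to
  `AAG` and `CTGT`.  The stand-in is *not* a covariance model; it exists so
  the downstream classifier is exercisable end to end without external tools.

### 1.2 Terminal stem (`annotate_stem`)

For every pair of start offsets (≤ 3 from either end) consecutive
Watson–Crick or G-U pairs are extended inward with no mismatches, keeping at
least 3 unpaired residues between the arms.  The longest run wins (ties to
the smallest 5′, then 3′ offset); runs shorter than 4 pairs do not qualify.
Offsets up to 3 accommodate the 1–2-nt start heterogeneity of the family's
5′ ends; minimum loop 3 is the standard steric floor.

### 1.3 Motif models

PWMs store pseudocounted column probabilities
(`(count + 0.1) / (n + 0.4)`) and score in log-odds bits against a
background (uniform by default).  `N` scores 0 (background policy)
everywhere.  Exact score p-values come from dynamic programming over
column scores discretized at 1e−3 bits — an error far below any decision
margin in the classifier.

The packaged DUSE (11 columns, C-rich core), 11-nt body motif, and TGTG
(`AAATGTG`) models are clearly-labelled synthetic stand-ins; real analyses
should supply site alignments (`read_sites`/`build_pwm`) or MEME minimal
files.  The body-motif alignment keeps positions 3, 6, 9, 10, 11
(T, C, C, A, A) invariant and the remaining columns weakly conserved
(9/20 modal; maximum 14.9 bits).  The weak conservation is deliberate: with
the scorer weights above, the maximum attainable structural score is then
2·6 + 14.9 + 2·3 + 2·4 ≈ 40.9 bits, so full gene architecture *without* a
promoter (total `S − 10`) cannot reach the decision threshold of 32 on
structure alone.  A sharper motif model would break that property.

### 1.4 Classifier

```
total = structural + DUSE + distance_adjustment
```

| constant | default | rationale |
| --- | --- | --- |
| upstream window | 150 nt | promoter search space upstream of the predicted TSS |
| DUSE reporting floor | 60 % of PWM max | permissive; the window's best hit is scored, no hard cutoff |
| canonical spacing | 60 nt | DUSE 3′ edge → TSS (or → TGTG box) |
| spacing tolerance | ± 10 nt | accommodates start heterogeneity and motif-edge ambiguity |
| distance bonus | +5 | DUSE at canonical spacing |
| wrong-distance penalty | −5 | DUSE present, spacing off |
| missing-DUSE penalty | −10 | no DUSE above the floor in the window |
| decision threshold | 32 | total required for classification |
| structural gate | 15 | minimum structural score considered |

The TGTG box contributes no score of its own.  It acts only as an
alternative distance anchor: when the DUSE→TSS spacing is wrong *and* an
AAATGTG hit lies between DUSE and the TSS with the DUSE at canonical
spacing upstream of it, the distance is measured to the TGTG box instead.

Distances are measured from the DUSE 3′ edge (configurable to the 5′ edge)
along the transcript orientation; on the minus strand "upstream" lies at
higher genomic coordinates.  All constants live in `ClassifierConfig` and
every decision boundary is recovered empirically by
`benchmark.measure_decision_boundaries`, which sweeps constructed inputs
through the real pipeline rather than reading the configuration back.

### 1.5 Expression validation

The expression criteria are three configurable metrics over per-base
coverage: mean coverage ≥ 10 reads/base; a distinct 5′ end (maximum within
± 2 nt of the TSS ≥ 0.5 of the locus maximum — the ±2 window matches the
1–2-nt start heterogeneity); and no read-through (flank mean ≤ 0.2 of the
locus mean over 50-nt flanks).  ROC curves sweep thresholds over the unique
scores with ties grouped; the AUC is the trapezoidal integral, which equals
the Mann–Whitney concordance probability with mid-rank tie correction (an
identity the tests enforce to 1e−12).

## 2. Synthetic generator

### What it emulates

* iid AT-rich background (GC 0.25 by default, matching the AT-richness of
  the genomes the family inhabits);
* true loci built exactly on the hallmark architecture:
  `AA + G`-opened terminal stem (6 bp: the conserved A:T and G:C pairs from
  the `AAG…/…CTGT` termini plus 4 sampled inner pairs, occasional G-U),
  an 11-nt motif drawn from the packaged model (redrawn until ≥ 60 % of the
  PWM max — implanted sites represent functional instances), a variable
  loop with an **exact** G+C count hitting a target sampled from the
  configured 0.32–0.41 band, lengths 50–70 nt (median ~60);
* a DUSE placed with its 3′ edge 60 ± 3 nt upstream of the locus start
  (jitter within the classifier's ±10 tolerance), optionally relayed
  through a TGTG box; a T₄ terminator a few nt downstream;
* four decoy classes probing each classifier component independently:
  `gene_no_duse` (architecture, no promoter; upstream windows are scrubbed
  of chance DUSE matches), `duse_wrong_distance` (spacing exactly 100),
  `duse_only` (promoter, unstructured downstream), `shuffled_motif`
  (motif scrambled until < 40 % of the PWM max);
* clusters: a configurable fraction of true loci placed in pairs < 500 nt
  apart; strands assigned at random; Poisson coverage (background mean 0.5,
  expressed plateau mean 100 with a sharp 5′ edge and zeroed immediate
  flanks).

Every construct is rejection-sampled until the annotation pipeline recovers
its designed architecture (stem of exactly the configured pair count,
curation hallmarks passing), so truth labels and pipeline semantics agree
by construction.  All randomness flows from the single config seed; no
global random state is touched.

### What it does not emulate

Phylogenetic divergence between species; transcriptional noise beyond iid
Poisson coverage; chromatin or replication context; read-level artifacts
(mapping, duplicates — coverage is generated directly); genome-scale
repeat structure; any correlation between background composition and gene
placement.

## 3. Numerical choices

* Coordinates are 0-based half-open everywhere internally; 1-based
  inclusive formats are converted only in `genome_io`.
* The exhaustive built-in search scores every window of every length in
  [40, 90] on both strands (numba kernels); greedy per-strand non-overlap
  resolution keeps the highest score (ties: lowest start, then plus
  strand).  Pure-Python reference implementations of both the scorer and
  the overlap resolution exist and the tests enforce exact agreement.
* The p-value DP discretizes column log-odds at 1e−3 bits; the worked
  examples that must be float-exact (the 32.0 total) use a DUSE model
  constructed so each matched column's log-odds is exactly 1.0 in binary
  floating point.
* Structure prediction for the motif pairedness profile is Nussinov-style
  maximum base pairing (WC + G-U, minimum loop 3) — a documented stand-in
  for thermodynamic folding; externally computed dot-bracket strings can be
  supplied instead.

## 4. Limitations

* The built-in structural score is deliberately simple, and its background
  null is hot: on 10 kb of iid GC-0.25 background it reports on the order
  of hundreds of non-overlapping windows above the 15-bit gate (chance
  4-bp terminal stems plus terminus matches are common in AT-rich
  sequence).  Specificity in this pipeline is therefore a property of the
  *classifier*, not of the structural gate: background windows lack an
  upstream DUSE, take the −10 adjustment, and cannot reach a total of 32
  (that would require ≥ 42 structural bits; the scorer's maximum is
  ≈ 40.9).  For real genomes, use an external covariance-model search and
  treat the built-in scorer as plumbing for tests and demonstrations.
* The benchmark's ROC comparison is computed over candidates matched to
  implanted elements.  Including the background windows would dilute both
  AUCs symmetrically (both scores rank them identically) and mask the
  comparison the decoy classes are designed to probe; the truth-label ROC
  over all candidates is reported separately.
* The packaged motif models are synthetic; none of the numbers produced on
  the synthetic benchmark are estimates of performance on real genomes.
* Expression calls encode qualitative criteria as three fixed
  thresholds; they are configurable but not fitted to any data.
* The shared-synteny procedure is O(|loci_a| · |loci_b|) and intended for
  the small locus sets typical of this family, not genome-scale gene sets.
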