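# Methods

This note documents the models and procedures implemented in `metavenom`,
the parameter choices that matter, and what the synthetic benchmarks do and
do not demonstrate.

## Library design

Precursor records carry CHAIN/PEPTIDE processing features with 1-based
inclusive coordinates (the UniProt convention); coordinates are converted
only at I/O boundaries.  Extraction emits one peptide per *resolved*
feature; records whose features have unresolved endpoints (`?`, `<1`)
are retained in the database but contribute nothing, mirroring how
precursors without processing annotations drop out of a designed library.
Overlapping features each yield their own peptide; duplicate mature
sequences arising from different parents are collapsed into a single
member keyed by sequence, with parent accessions accumulated — synthesis
pools are sequence-keyed, so a sequence-level member list is the natural
unit.  Sequences containing U, O, B, Z or J are rejected at parse time:
they cannot be reverse translated unambiguously.

The library length cutoff is ≤ 90 aa, the largest peptide a 270-base
coding region can carry.  Composition statistics partition members into
cysteine classes (none / odd count / even nonzero count) because an even
cysteine count is the prerequisite for a fully paired disulfide scaffold.

## Oligo encoding

Each member is encoded as `primer5 + coding + PAS-padding + primer3`,
exactly 300 bases with a 270-base insert.  Design choices:

* **Deterministic codon choice.**  Every residue takes the top-ranked
  codon of an *E. coli* K-12 usage table.  Sampled codon optimization
  would diversify synthesis pools slightly but makes designs
  irreproducible; determinism was preferred, and the ranked table leaves
  headroom for motif repair.
* **Restriction-site exclusion.**  The cloning sites EcoRI (GAATTC) and
  HindIII (AAGCTT) must not occur inside the insert or across primer
  junctions.  Repair demotes the leftmost possible codon to its next rank
  until the leftmost occurrence disappears, never revisiting a decision —
  each step strictly advances the earliest occurrence position, so the
  procedure terminates.  An exhaustive scan of all 400 dipeptides (tested)
  shows the default table never *forces* a site through the single-codon
  residues M/W, so encoding failures cannot occur with the default motif
  set.  Both default sites are palindromic; scanning the given strand
  therefore covers the double-stranded recognition site, and
  reverse-complement scanning is deliberately omitted.
* **Padding 3′ of the coding region, in frame.**  The displayed fusion
  runs peptide → linker → tag N-to-C, so PAS padding extends the inert
  linker side rather than prepending to the peptide.  Padding residues
  cycle P, A, S with rank-1 codons, repaired the same way (the already
  final coding region is never altered during padding repair).
* **Primer arms.**  The 300 − 270 = 30 remaining bases are split 15 + 15
  by default; arm sequences are configuration, since real pools use
  library-specific amplification arms.  Junction windows are re-scanned at
  assembly and a motif spanning a junction is a hard error naming the
  junction.

## Alignment and statistics

The local alignment engine reports the optimal Smith–Waterman alignment
under BLOSUM62 with affine gaps costing `gap_open + g * gap_extend`
(defaults 11, 1 — the protein-search convention).  The dynamic program is
delegated to Biopython's `PairwiseAligner`; identity, coverage, spans and
gapped strings are derived in this package from the returned path, and the
engine is verified against an independent pure-Python three-state DP in
the test suite (exhaustively for short sequences).  Ties among optimal
tracebacks resolve to the engine's first reported path, which is
deterministic for fixed inputs.

Two definitions are fixed explicitly to remove ambiguity:

* **identity** = identical columns / all alignment columns (gap columns
  included in the denominator);
* **coverage** = aligned span length / sequence length, computed per
  sequence; clustering requires the threshold on *both* sequences
  (bidirectional), the conservative reading of "sequence length overlap"
  and the default coverage mode of common clustering tools.

E-values use tabulated Karlin–Altschul parameters (λ = 0.267, K = 0.041
for gapped BLOSUM62) rather than per-search estimation:
bits = (λ·S − ln K)/ln 2, E = m·n·2^(−bits), with n the summed database
length.  No effective-length (edge) correction is applied; for the short
peptides handled here this makes reported E-values conservative, which
only tightens the E < 0.001 acceptance rules.  Score parity with blastp is
not a goal; the engine exposes the same thresholds, not the same numbers.

## Metavenome expansion

The cascade is: iterative homology search (accepted targets of round *r*
re-query the pool in round *r*+1, default 2 rounds — a bounded stand-in
for profile-iterative search that captures transitive recruitment at desk
scale) → removal of targets identical to a parent or longer than 100 aa →
greedy clustering (longest first, ties by id; a sequence joins the first
representative meeting identity ≥ 0.50 *and* bidirectional coverage
≥ 0.95, else founds a cluster) → removal of representatives meeting the
same thresholds against *any* parent → final ≤ 90 aa filter.  Both
thresholds are inclusive at the boundary.  All ordering rules are
canonical, so permuting the input changes nothing.

## Enrichment model

Counts for clone *i* in sample *j* are modeled NB with
Var = μ + φμ².  The analysis chain:

* **Normalization.**  Default: total-count scaling to the mean library
  size (factor = mean total / sample total).  A trimmed mean-of-ratios
  variant (ratios to the geometric-mean clone profile, 20% trimmed each
  tail, factors rescaled to geometric mean 1) is available for matrices
  dominated by a few clones.
* **Dispersion.**  Method of moments on within-group normalized replicate
  counts: pooling `s² − μ̄` over clones and groups against the unbiased
  `μ̄² − s²/n` estimate of μ² gives the common φ; per-clone ratios are
  shrunk toward the common value with weight 0.8 (three replicates carry
  almost no per-clone information, so shrinkage is heavy).  With no
  replicated group a prior φ₀ = 0.1 is used and logged.  This documented
  MoM + shrinkage estimator deliberately stands in for quantile-adjusted
  conditional maximum likelihood; the platform's contract is the
  three-threshold hit rule, not bit-parity with any particular
  differential-abundance package.
* **Exact test.**  Per clone, the normalized group sums (rounded to
  integers) are compared conditionally on their total *s*: under the null
  the target sum follows the distribution proportional to
  f_T(y)·f_C(s−y), where f_T, f_C are NB group-sum pmfs (a sum of *n*
  i.i.d. NB(μ, φ) counts is NB(nμ, φ/n)) with means splitting *s* by
  replicate numbers.  The p-value sums outcomes with y ≥ y_obs — one-sided
  in the enrichment direction, because biopanning asks only for enrichment
  over control.  At φ = 0 this reduces exactly to the conditional binomial
  (two-sample Poisson) test, which the tests verify against explicit
  summation.
* **Fold-change.**  (Σ target normalized counts + 0.5) /
  (Σ control normalized counts + 0.5), rescaled for unequal replicate
  numbers; the 0.5 pseudocount per group sum stabilizes zeros.
* **Hit rule.**  *p* < 0.001 AND fold-change ≥ 5 AND raw count ≥ 15 in at
  least 2 of the 3 target replicates.  Support deliberately uses raw
  counts ("read count", read literally); p and FC use normalized counts.
  A Benjamini-Hochberg column is emitted for reference but the rule
  thresholds the raw p-value.  Negative-control choice (parental cells vs
  isotype) is purely a sample-group label.

## Hit interpretation

Similarity networks connect peptides whose best local alignment reaches
E < 0.001, with bit-score edge weights.  Clusters are connected components
(≥ 3 members) — the minimal deterministic reading; community detection is
left to downstream tools.  Cluster alignments use a center-star
construction (center = maximal summed pairwise score; "once a gap, always
a gap" merging); parity with progressive aligners is not claimed, and the
consensus is a position-frequency matrix with a majority-vote string
(ties toward the lexicographically smaller symbol, sub-majority columns
marked `x`) plus the set of columns where cysteine is fully conserved — a
deterministic stand-in for statistical motif discovery.  Best-hit
annotation relaxes its acceptance threshold for queries ≤ 30 aa (best hit
kept regardless of E-value, reported verbatim) because short peptides
cannot reach conventional significance; longer queries require E ≤ 0.001.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (configuration, seed):

* **Parent records** — mature length log-normal (median 62 aa, σ 0.35)
  plus a log-normal pro/signal extension placing the parent median near
  110 aa; cysteine classes drawn at 8% none / 22% odd / 70% even (within
  the odd class, a single cysteine is rare), cysteines placed inside the
  mature window.  These figures mirror the composition of curated venom
  libraries.
* **Homolog pools** — per parent, Poisson(7) homologs at controlled
  identity (substitution-only by default, so identity is exact by
  construction; an indel model is optional), terminal residues anchored
  and end-to-end alignability verified so that "planted at full coverage"
  is guaranteed rather than merely likely (a dense terminal mismatch run
  would otherwise be trimmed by local alignment).  Cysteine positions can
  be preserved to emulate scaffold conservation.  Decoys are i.i.d. random
  peptides.
* **Screens** — baseline clone abundances log-normal (σ = 1, emulating
  the heavy skew of M13 libraries), counts NB with configurable φ
  (default 0.2, a typical replicate-level overdispersion for
  amplicon-sequencing screens), triplicate target and control samples at
  10⁵ reads each, spiked clones with known fold-changes applied to target
  means only.  Default benchmarks spike 20 of 2,000 clones — real screens
  yield tens of true binders, and the spiked mass then perturbs library
  totals by only a few percent.
* **Reads** — error-free FASTQ realization of a count matrix (each read
  is its clone's insert verbatim), which makes `count_reads` exactly
  invertible and is used for round-trip testing.

Not modeled: sequencing error and quality, PCR amplification bias,
phylogenetic structure among homologs (they are i.i.d. mutated copies),
and biological correlation between abundance and sequence.  Passing the
synthetic benchmarks therefore demonstrates the correctness and
calibration of the algorithms under the stated model — not performance on
real screens, where normalization stress, index hopping and
sequence-dependent amplification add noise the generators do not produce.

## Numerical and benchmark notes

* The NB exact test is computed in log space (`logsumexp`) and is exact
  for group sums into the tens of thousands; both-groups-zero clones are
  reported as p = 1, FC = 1.
* A 2,000-clone null cannot resolve a 10⁻³ type-I rate (the expected hit
  count is 2), so calibration checks pool five independent 2,000-clone
  nulls; the pooled empirical rate at α = 0.001 is ≈ 0.0009.
* With φ = 0.2 the fold-change estimate from triplicates has ≈ 37%
  coefficient of variation, so the FC ≥ 5 rule intrinsically misses
  roughly 5% of true 10-fold clones; long-run sensitivity for
  well-covered spikes (control mean ≥ 30 reads) is ≈ 0.95 with FDR well
  under 5%, but a single screen carries only ~10 such spikes, so
  per-seed estimates range from ~0.85 to 1.0.
* Benchmark problem sizes (100 parents / 500 planted homologs; 2,000
  clones per screen; 1,000 random peptides for encoder laws) were chosen
  to give stable desk-scale estimates; all generators scale to larger runs
  by configuration.
* Alignment-oracle checks are exhaustive over all sequence pairs up to
  length 3 on a reduced 4-letter alphabet and sampled up to length 8 on
  the full alphabet — exhaustive enumeration at length 8 would be ~10¹⁰
  pairs and adds nothing over sampling.

## Known limitations

* The greedy clustering order (length-descending) and the bidirectional
  coverage rule are conventions; a shorter-sequence-only coverage mode is
  a plausible alternative and both are configurable.
* Karlin–Altschul parameters are table-driven per scheme; custom matrices
  require supplying λ and K.
* The k-mer prefilter trades sensitivity for speed and is off by default;
  at 50% identity a shared 4-mer is likely but not guaranteed.
* `count_reads` requires exact (or exact-prefix) matches; real pipelines
  need upstream read trimming/merging to produce such reads.
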