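# metavenom

Design and single-round biopanning analysis of venom / "metavenome"
phage-display libraries.

Animal venom polypeptides — small, cysteine-dense, disulfide-locked
miniproteins — are a rich source of receptor ligands, but screening them at
scale requires encoding tens of thousands of peptides as a synthetic
oligonucleotide pool, displaying them (e.g. on M13 hyperphage), and reading
out a single round of affinity selection by deep sequencing.  `metavenom`
implements the computational side of such a platform, end to end, for
anyone building programmable display libraries from annotated protein
databases and metagenomic sequence pools:

* **Library design** (`metavenom.records`) — parse annotated precursor
  records, excise the mature/active peptides from CHAIN/PEPTIDE processing
  features (1-based inclusive coordinates), collapse duplicate sequences,
  keep members ≤ 90 aa, and summarize length and cysteine composition.
* **Oligo encoding** (`metavenom.encode`) — deterministic reverse
  translation with a preference-ranked *E. coli* codon table, in-frame
  Pro-Ala-Ser (PAS) linker padding to a 270-base insert, 15-base primer
  arms to a 300-base oligo, and exclusion of EcoRI/HindIII sites
  (GAATTC / AAGCTT) by minimal, leftmost codon rank demotion.
* **Metavenome expansion** (`metavenom.expand`) — iterative homology search
  of the parent library against a candidate pool, removal of identical or
  >100-aa targets, CD-HIT-style greedy clustering at 50% identity / 95%
  bidirectional coverage, and removal of representatives that still overlap
  a parent at those thresholds.
* **Alignment engine** (`metavenom.align`) — optimal local (Smith–Waterman)
  alignment under BLOSUM62 with affine gaps (a length-*g* gap costs
  11 + *g*), plus Karlin–Altschul statistics: bit score
  *S'* = (λ·*S* − ln *K*)/ln 2 and E-value *E* = *m·n·*2^(−*S'*), with
  λ = 0.267, *K* = 0.041.
* **Enrichment analysis** (`metavenom.enrich`) — perfect-match read
  counting into a clone × sample matrix, library-size normalization,
  method-of-moments negative-binomial dispersion with shrinkage
  (Var = μ + φμ²), a conditional two-group NB exact test of target vs
  negative-control replicates, and the three-threshold hit rule:
  *p* < 0.001, fold-change ≥ 5, and a raw count ≥ 15 in ≥ 2 of 3 target
  replicates.
* **Hit interpretation** (`metavenom.netgraph`) — sequence-similarity
  networks (edges at E < 0.001, weighted by bit score), connected-component
  clusters, center-star multiple alignments, position-frequency-matrix
  consensus motifs with conserved-cysteine columns, and length-aware
  best-hit annotation against an annotated reference.
* **Synthetic data** (`metavenom.simulate`) — generators for venom-like
  annotated records (parent length median ≈ 110 aa, mature ≈ 62 aa,
  ~8/22/70% no/odd/even cysteine classes), homolog pools at controlled
  identity, NB-distributed triplicate screens with spiked enrichments, and
  error-free FASTQ realization — every fixture carries its ground truth.

## Worked example

Simulate an annotated parent database, design and encode the library, run a
synthetic screen with ten clones spiked at 10-fold enrichment, and call
hits — all from the command line:

```sh
$ metavenom design-av --records records.tsv --out library.fasta
{"parents": 500, "mature": 500, "library": 426}

$ metavenom stats --records records.tsv
{"n_members": 426, "length_median": 60.0, "mature_length_median": 64.0,
 "frac_no_cys": 0.0939, "frac_odd_cys": 0.1948, "frac_even_cys": 0.7113,
 "frac_ge2_cys": 0.8944}

$ metavenom encode --peptides library.fasta --out-fasta oligos.fasta --out-table designs.tsv
{"designs": 426, "failures": 0}

$ metavenom simulate --n-clones 1000 --depth 100000 --n-spiked 10 \
      --spike-fc 10 --seed 7 --out-dir screen
{"clones": 1000, "spiked": 10, "out": "screen"}

$ metavenom call-hits --counts screen/counts.tsv --groups screen/groups.tsv --out results.tsv
{"clones": 1000, "hits": 10}
```

Of 500 parents, 426 unique mature peptides pass the 90-aa filter (89% carry
at least two cysteines, median length 60 aa); each becomes one 300-base
oligo.  The screen's ten spiked clones are recovered as exactly ten hits.
`results.tsv` holds, per clone, the normalized target/control means, the
maximum-likelihood fold-change, the NB exact-test p-value (plus a
Benjamini-Hochberg column for reference), replicate support and the hit
call — e.g. `clone00001: FC 12.6, p 5.5e-10, 3/3 replicates ≥ 15 reads →
hit`.

The same steps are available as library calls; see the module docstrings
(`build_metavenome`, `score_enrichment`, `build_graph`, `center_star_msa`,
...) for the programmatic interface, and `metavenom graph` / `metavenom
annotate` for hit-list interpretation.

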