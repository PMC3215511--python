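# Methods

## Model and assumptions

The package treats a gene as nothing but its set of atomic motifs —
short conserved promoter sequences obtained elsewhere by phylogenetic
footprinting.  Genomic coordinates, species metadata and the discovery
pipeline that produced the motifs are all out of scope; the algorithm
consumes sequences only.  The central assumption is that common
regulation leaves a surplus of short, degenerate shared sequence in this
conserved material, detectable as an excess of Simple Shared Motifs
(SSMs) relative to random gene pairs.

Matching is strand- and orientation-degenerate: a word is identified
with its orbit `{w, w_c, w_r, w_rc}` under complement, reversal and
reverse complement.  The four transforms form a Klein four-group, so
orbits are well defined (any member generates the same orbit, sizes 1,
2 or 4) and the min-over-members Hamming distance is zero exactly when
two orbits coincide.  The pure reversal `w_r` (reverse without
complement) is included deliberately — it is part of the method's
definition of degeneracy, unusual as it is biologically.

An `(l,d)`SSM for a gene pair is a maximal clique in the graph whose
nodes are the distinct orbits of all length-`l` motif windows of both
genes and whose edges join orbits within extended distance `d`, kept
only if its nodes jointly cover both genes.  Maximality is clique
maximality: a spanning clique extendable only by single-gene nodes is
*not* an SSM.  A node occurring in both genes is a valid singleton SSM
when isolated; at `d = 0` the graph has no edges between distinct
orbits, so the SSM count equals the number of exactly-shared orbits.

Two counting conventions coexist by design: graph nodes merge duplicate
windows, while the *potential* SSM count (the SSMC denominator) counts
windows positionally without deduplication — it is the product of the
two genes' window totals.

## Statistical machinery

* **Null distributions.** For each type, the SSMC null is the empirical
  distribution over `n_pairs` random unordered pairs of *distinct*
  genes, drawn uniformly with replacement across pairs.  One seeded pair
  list is shared by all types, so per-type and whole-grid builds agree
  exactly.  Degenerate pairs (no window material on one side) contribute
  SSMC = 0: absence of material is absence of evidence, and excluding
  such pairs would bias the null toward motif-rich genes.
* **Tail probabilities.** `p = (r + 1)/(n + 1)` with
  `r = #{null ≥ observed}` (ties count in the tail).  The add-one
  smoothing keeps p in `[1/(n+1), 1]` and avoids zero p-values from a
  finite sample.
* **cp-values.** The minimum p-value over the type grid, with no
  multiple-testing correction — deliberately, as the method defines it.
  cp-values are therefore anti-conservative as absolute probabilities:
  in the package's own synthetic experiments, CEXlists at t = 0.01
  typically hold 5–10% of candidate genes, not 1%.  They are ranking
  and thresholding scores, not calibrated error rates.
* **Enrichment.** Plain (unconditional) hypergeometric upper tails per
  category, no ontology-graph decorrelation and no multiple-testing
  correction; the 0.05 threshold of that test is also the inclusion gate
  of `c_score = Σ ln(1/p − 19)` (natural log; the anchor c_score = 0 at
  p = 0.05 holds in any base, natural log is the package's choice).
  Values above 0.05 approach the 1/19 singularity and are rejected as a
  caller error.  The Fisher in/out test is two-sided; the direction is
  carried by the separately reported enrichment ratio, which is 0 when
  the list holds no co-expressed gene.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| type grid | `l ∈ [6,14]`, `d ≤ min(5, ⌊l/3⌋)` | 36 types; distance budget at most a third of the window keeps chance alignments rare |
| `n_pairs` | 50 000 (CLI) | null sample size per type; 2 000 suffices for ~200-gene synthetic screens |
| thresholds `t` | 0.05, 0.01, 0.005, 0.001 | CEXlist cp-value cut-offs |
| `alpha` | 0.05 | hypergeometric over-representation gate; also the c_score inclusion gate |
| `n_lists` | 200 | random gene lists per c_score null |

## Synthetic data

The generator emulates the published corpus moments: 12.7 ± 8.9 atomic
motifs per gene and motif lengths 11.7 ± 4.1 nt, truncated to [6, 30]
(reconciling the "typically 6–12 bp" range with the reported moments).
Counts and lengths are rounded draws from truncated normals whose
pre-truncation parameters are *solved* (via `scipy.stats.truncnorm`
moments) so the truncated distribution reproduces the target mean and
sd — naive truncation at the nominal parameters would inflate the
realised means by ~1.4 motifs/gene and ~0.7 nt.  Background bases are
i.i.d. with configurable GC content (default 0.5); planted motifs are
inserted as standalone atomic motifs with an exact number of random
substitutions per copy, and the emitted truth object records every
instance.

What the generator does **not** model: positional structure inside
promoters, phylogenetic conservation artefacts, motif-length/count
correlations, compositional heterogeneity between genes, and the fuzzy
overlapping motif families of real footprint data.  Passing recovery
tests therefore demonstrate the machinery's correctness and power under
idealised i.i.d. backgrounds, not performance on real promoter corpora.

## Numerical and algorithmic choices

* Sequences are packed 2 bits/base into `uint64`; Hamming distances are
  popcounts of XOR bit planes, computed vectorised for whole node sets.
  Node distances use one representative per orbit against the four
  members of the other (Hamming distance is invariant under jointly
  applied transforms), not the 16 member cross pairs.
* Maximal cliques come from igraph's pivoting Bron–Kerbosch; output
  order is fixed by sorting nodes on canonical keys (lexicographically
  smallest orbit member, equivalently numerically smallest packed code),
  so all results are deterministic and parallelism-free by construction.
* The batch engine caches per-gene window profiles per length and reuses
  one node-distance matrix for every `d` of a length; pairs with no
  shared orbit and no cross-gene edge short-circuit to zero without
  clique enumeration.
* Degenerate cases: empty motif lists yield empty node sets and
  zero/degenerate counts (never division by zero — SSMC is `None`);
  empty databases report undefined summary statistics as `None`, not 0;
  an all-constant c_score null (σ = 0) raises rather than silently
  producing infinite z-scores.
* Sequence validation is strict by default (reject non-ACGT after
  uppercasing); a `drop` policy discards offending motifs with a
  warning.  Hamming distance and complementation are undefined for
  ambiguity codes, so they are never admitted.

## Problem sizes used in the shipped experiments

The end-to-end recovery experiment uses 200 genes with a 5-gene module
sharing an exact 10-mer, nulls from 2 000 random pairs over the full
36-type grid, and scores every second non-module gene as a control
query.  The mutation-degradation study runs at 60 genes over the
`(10,d)` types with 1 000-pair nulls, averaging over 10 seeds; it tracks
the continuous co-member cp-value rather than binary list membership,
which is noise-dominated once planted copies drift to chance-level
similarity.  The count-versus-potential correlation check uses 1 000
random pairs of a 150-gene database at type (6,1).

## Known limitations

* cp-values are anti-conservative (see above); comparisons across
  databases with different motif-content distributions are not
  calibrated.
* The SSMC correction removes most, not all, of the dependence of SSM
  counts on motif content; residual correlation means motif-poor or
  motif-rich query genes see mildly distorted false-positive rates.
* Empirical nulls are strictly that — no analytical SSMC model is
  provided, and resolution is limited to `1/(n_pairs + 1)`.
* SSMs are anonymous sets of degenerate sequences; the method does not
  map them back to known transcription-factor binding sites.
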