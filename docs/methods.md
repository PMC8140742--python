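# Methods

`pepbench` benchmarks sequence-based peptide encodings: functions f
mapping an amino-acid sequence s = (a_1, …, a_k), a_i one of the 20
natural amino acids, to a fixed-length numeric vector ŝ. A two-class
dataset D = {s_1, …, s_n} is encoded under many parameterisations, each
encoded dataset is evaluated with a classifier under repeated stratified
cross-validation, and the resulting models are compared statistically.
This note records the modelling choices, defaults and limitations.

## Dataset model and sanitization

A record is (id, sequence, label ∈ {0,1}); ids are unique, sequences are
uppercased and restricted to the 20-letter alphabet. Ambiguity codes
(B, J, O, U, X, Z) and gaps are rejected in strict mode (default) or
dropped with a log message in lenient mode. Labels live in the FASTA
header (`>id|label`) or a sidecar CSV (`id,label`), the sidecar winning.
Duplicate sequences across records are flagged but never removed — how a
benchmark should treat duplicated peptides is application-dependent, so
the library surfaces them and leaves the decision to the caller.

## Synthetic data generator

The generator emulates the one property of real two-class peptide data
that a compositional encoding can detect: a residue-composition bias in
the positive class. Negative sequences draw residues i.i.d.-uniformly
from the 20 amino acids; positive sequences move probability mass
`bias_strength` (default 0.3) from the uniform background onto
`bias_residues` (default {K, R}, spread evenly). Lengths are uniform over
`length_range`, default [3, 255] — the span typical peptide collections
cover. Class sizes are exact: round(imbalance·n) positives.

What the generator does **not** emulate: positional motifs, length–class
dependence, residue autocorrelation, phylogenetic redundancy and
near-duplicate sequences. Tests passing on this fixture therefore show
that the pipeline recovers a compositional signal end-to-end; they say
nothing about how encodings rank on real biomedical data.

## Encoders

All encoders are pure, deterministic and row-order preserving. A record
too short for a spec (lag, window, tuple span, λ) is dropped and logged,
never NA-filled; `len(rows) + len(dropped) = len(input)` always, and an
encoder that drops everything raises. Conventions worth recording:

* **k-mer families** (aac/dpc/tpc, grouped g-variants, ngram, psekraac):
  overlapping k-mer counts divided by the number of k-mers, so each row
  sums to 1 exactly. The 5-group partition is the standard
  aliphatic/aromatic/positive/negative/uncharged split.
* **cksaap/cksaagp**: pair frequencies at each gap g ∈ 0..gmax, each
  400- (or 25-) feature block normalised by its own pair count.
* **eaac/egaac**: per-window composition concatenated over sliding
  windows. The feature count depends on sequence length, so retained
  sequences must share one length (pre-aligned input); ragged input
  raises rather than padding silently.
* **Autocorrelation** (Moran, Geary, normalised Moreau–Broto): index
  tables are z-standardised over their 20 values (population moments);
  zero-variance indices are rejected. Moran and Geary are undefined on a
  sequence whose per-residue profile is constant; those entries are set
  to 0, a documented convention rather than a mathematical value.
* **CTD**: the classic seven three-class physicochemical attributes
  (hydrophobicity, van der Waals volume, polarity, polarizability,
  charge, secondary structure, solvent accessibility). Distribution
  landmarks use occurrence number max(1, ⌈qN⌉) for q ∈
  {0, .25, .5, .75, 1}, as a percentage of sequence length.
* **Conjoint triads**: the 7-class reduced alphabet; skip-k triads need
  length ≥ 2k+3; each 343-feature block is min–max normalised.
* **Sequence order** (socnumber/qsorder): coupling numbers
  τ_d = Σ_i d²(a_i, a_{i+d}) for two bundled 20×20 distance matrices —
  the Grantham distance, recomputed from the published
  composition/polarity/volume properties and constants, and a
  physicochemical dissimilarity built from range-normalised
  hydrophobicity and side-chain volume differences. The latter is a
  reconstruction in the spirit of the Schneider–Wrede matrix, not a copy
  of the original print; its qualitative structure (zero diagonal,
  symmetry, conservative pairs close) is what the descriptors rely on.
* **paac/apaac**: Chou's pseudo compositions with the classic
  hydrophobicity / hydrophilicity / side-chain-mass scales, standardised
  over the 20 residues. The normaliser uses the signed τ sum so each row
  sums to 1 exactly; a non-positive normaliser (only reachable with
  extreme weights) drops the record. The weight→0 limit reproduces aac
  in the first 20 features.
* **psekraac**: one bundled reduced-alphabet family (`type1`,
  hydrophobicity-ordered nested clusters at sizes 2–20); clusters=20 is
  the identity reduction, making psekraac(20, 1, 0) ≡ aac. A tuple of
  size t with gap g covers positions i, i+g+1, …, i+(t−1)(g+1).
* **Per-residue encoders** (binary, blosum62, zscale, aaindex) accept
  equal-length input or a pluggable aligner hook returning equal-length
  strings with `-` gaps (e.g. a MUSCLE/MAFFT wrapper); gap columns
  encode as zeros. No aligner is built in.
* **distance_frequency**: for each residue, the histogram over `bins`
  equal-width bins of the normalised position (i−1)/(L−1), divided by L.
  Summing a residue's bins recovers its aac value; bins=1 is exactly
  aac. This positional-histogram definition is the package's documented
  default for the family — published descriptions of this descriptor
  vary, so the reduction properties above are the contract.
* **fcgr**: the 20-letter alphabet reduced to 4 classes (default:
  hydrophobic / polar / positive / negative, configurable) mapped to the
  unit-square corners; the chaos-game trajectory starts at the centre
  and each step moves halfway to the current symbol's corner; occupancy
  over a 2^m × 2^m grid, row-major, normalised to sum 1.

## Grid expansion and redundancy filtering

The experiment set is the union over encoder groups of the Cartesian
product of each group's parameter axes; the count is the product-sum of
axis sizes (axes deduplicated first). Two greedy filters thin the set:

* **Index filter** — single-link clustering of amino-acid index tables
  at |Pearson r| ≥ threshold (default 0.8) on the 20-value vectors,
  keeping the highest-variance member per cluster (ties: lexicographic
  id). Greedy first-kept scanning makes the result deterministic and
  idempotent.
* **Probe filter** — every spec encodes a small probe dataset; scanning
  in input order, a spec is dropped when its matrix has an adjusted
  RV-coefficient ≥ threshold (default 0.95) with any already-retained
  spec. Specs failing on the probe are excluded with a log entry, not
  fatally. Greedy filtering is deliberately not globally optimal.

## Cross-validation and metrics

Stratified k-fold CV (k = 5) repeated 10 times gives 50 fold rows per
encoded dataset; repetition r shuffles with seed + r so the whole run is
reproducible from one integer. The classifier is pluggable
(`fit(X, y)` / `predict_probability(X)`); the default is a random forest
with library defaults and a fixed seed — robust without hyper-parameter
optimisation, which is intentionally out of scope. Class calls threshold
P(class 1) at 0.5, ties to class 1. Both probabilities and calls are
stored per fold, so threshold-free analyses remain possible downstream.

The paired two-group variant intersects the record ids of two encoded
datasets (e.g. when the structure step dropped sequences from one),
then applies the identical fold partition to both, making fold rows
traceable to the same sequences — the precondition for similarity
analysis.

Metrics per fold row: F1, MCC, precision, recall, specificity.
Zero-denominator conventions: precision/recall/specificity → 0; MCC → 0
when a confusion marginal is empty; F1 → 1 when there are neither true
nor predicted positives (perfect all-negative agreement), else 0 on an
empty denominator.

## Statistical comparison

* **Similarity**: disagreement D = (1/n)Σ|o_i − o_j| and the 2×2 Phi
  coefficient, computed per fold row on paired predictions and averaged
  over rows. Phi is undefined when a prediction vector is constant; such
  rows raise in the scalar API and are skipped (not zero-filled) in the
  pairwise average.
* **Friedman test**: per-fold ranks of the k models (rank 1 = best, ties
  averaged); χ²_F = (12N/(k(k+1)))[Σ R_j² − k(k+1)²/4] with the
  Iman–Davenport transform F = ((N−1)χ²)/(N(k−1) − χ²), F-distributed
  with (k−1) and (k−1)(N−1) degrees of freedom. Ranking is per fold row
  (N = 50 under the defaults). The χ² ceiling N(k−1) is flagged as
  degenerate, not silently clamped.
* **Nemenyi critical difference**: CD = q_α √(k(k+1)/(6N)); q_α is the
  Studentized-range quantile at infinite degrees of freedom divided by
  √2, evaluated at runtime from the scipy distribution for α ∈
  {0.05, 0.10} and any k ≥ 2 (the classic printed tables are reproduced
  to three decimals; the test suite cross-checks k = 2…10).
* **Encoded-dataset correlation**: adjusted squared Pearson
  r²_adj = 1 − ((n−1)/(n−2))(1 − r²) and the adjusted RV-coefficient
  RV_adj(X, Y) = Σ_ij r²_adj(x_i, y_j) / √(Σ r²_adj(x_i, x_j) ·
  Σ r²_adj(y_i, y_j)). Constant columns are excluded (r²_adj is
  undefined there); RV_adj(X, X) = 1 exactly. Because all-pairs
  correlation is expensive, the convenience wrapper ranks specs by mean
  F1 and correlates only the top k.
* **Class separation**: the Davies–Bouldin index over the two class
  clusters (euclidean centroids, mean point-to-centroid dispersion).
  The standard convention is used throughout: **lower = better
  separation**. Source descriptions of encoding benchmarks sometimes
  read as if a larger value meant better separation; this package
  follows the standard definition and makes no attempt to guess a
  different intent.
* **Cross-dataset ranking / clustering**: a group's representative is
  its best member by mean F1; groups are ranked per dataset (rank 1 =
  best, ties averaged; a group with no computable member scores 0), and
  datasets/groups are clustered by UPGMA (average linkage, euclidean)
  with Newick export.

## Structure approximation

Queries are searched against a database built from structure files (one
record per chain), guaranteeing every hit has coordinates. The best hit
is the one with the lowest e-value; ties break by higher identity, then
lexicographic database id. The matched database range is clipped and
returned as the query's approximate structure; the clip's residue
letters must equal the matched query subsequence for gap-free exact
hits (hard assertion), while hits with recorded mismatches keep the
database residues and carry the mismatch count. Queries without a hit
are listed as omitted, and len(clips) + len(omitted) = len(queries)
always. The search engine is pluggable: a deterministic exact-substring
engine (used by tests and small runs) and an adapter for an external
BLAST+ installation. Downstream structure-derived feature computation is
out of scope.

## Problem sizes used in the checks

The test-suite and acceptance-script runs use synthetic datasets of
60–200 records and 5×10 CV — large enough for stable fold statistics and
a clear signal/permutation separation, small enough that the whole suite
runs in minutes on one core. Exhaustive encoder verification covers all
sequences of length ≤ 6 over a 4-letter sub-alphabet chosen to span four
physicochemical classes in every bundled partition.

## Known limitations

* The AAindex-style bundle contains six classic scales, not the full
  database; the index-redundancy filter and index-based encoders accept
  user-supplied 20-value tables for anything further.
* One PseKRAAC reduction family is bundled; other published families
  plug in through the same table structure.
* The physicochemical distance matrix behind socnumber/qsorder is a
  reconstruction (see above); absolute coupling-number scales differ
  from implementations bundling the originally printed matrix, while
  within-run comparisons are unaffected.
* Per-residue encoders do not align; they require pre-aligned input or
  an external aligner hook.
* Binary classification only; multi-class labels are rejected at parse
  time.
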