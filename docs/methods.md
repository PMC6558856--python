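# Methods

This note documents the models, conventions and numerical choices behind
`stackppi`, in the order the pipeline runs.

## Sequence features (F1)

Each of the 20 essential amino acids carries 14 property-scale values
(module `physchem`, shipped as `data/aa_scales.tsv`; column order H11, H12,
H2, NCI, P11, P12, P2, SASA, V, F, A1, E, T, A2 is fixed so encodings are
bit-reproducible). One column of the transcribed table deserves a note: the
tyrosine row is internally consistent with the side-chain-volume column of
the other rows (Y volume 117.3 Å³, NCI 0.024), and the table was checked
against the standard published scales cell by cell.

The auto-covariance of scale *i* at gap *g* is the average product of
mean-centered scale values of residues *g* positions apart. Conventions:

- **Maximum gap G** defaults to 30 (the common choice in auto-covariance
  PPI encodings), is configurable, and is capped at
  (shortest training sequence − 1) with a logged warning so every protein
  yields a full-rank encoding.
- **Short proteins:** for `g ≥ L` the empty sum defines `AC = 0`, keeping
  the vector length at `14·G` for every protein.
- **Nonstandard residues** (B, Z, X, U, O, `*`) have no scale values; the
  default policy drops them with a warning (policy `error` rejects the
  sequence, reporting symbol and position).

AC vectors are standardized feature-wise (zero mean, unit SD) and min–max
scaled to [0, 1], both fitted on the training proteins only. A
zero-variance feature uses SD := 1 and a zero range maps to 0, so degenerate
columns pass through instead of crashing mid-pipeline; test-time values
outside the training range are clipped to [0, 1], which also bounds the
influence of outliers. The pair representation keeps both concatenation
orders as separate training instances (doubling the instance count) and
averages the two orders' probabilities at prediction, so
`predict(A, B) == predict(B, A)` holds exactly, not approximately.

## GO features (F2)

Hierarchical level of a term is the length of the *longest* path from the
root (the usual depth convention on GO DAGs). The LCA of a pair is taken
over the union of both proteins' term sets, with every term an ancestor of
itself; when a DAG admits several deepest common ancestors the
lexicographically smallest id wins, making the partition deterministic.
Distinct LCAs are processed deepest level first (matching the order in
which nested clusters must be carved out; ties again lexicographic), each
claiming its unassigned descendants. Consequences worth knowing:

- Terms outside every cluster (possible for test-time annotations) simply
  contribute nothing, because clusters are defined by training LCAs only.
- The encoding counts *distinct* terms on ascending paths restricted to
  the cluster, endpoints included; a term whose only routes to the cluster
  root leave the cluster contributes nothing, which the brute-force
  path-enumeration oracle in the tests confirms.
- `is_a` and `part_of` edges are traversed by default (configurable).
- The three subontologies are partitioned independently and their blocks
  concatenated; a config switch restricts to one ontology for the
  cross-dataset protocol. F2 (and F3) pass through the same
  fit-on-train standardize + min–max scaling as F1 so the blocks are
  commensurate.

## Network features (F3)

Information content uses natural log, `IC(t) = −ln p(t)`, with `p(t)` the
fraction of corpus proteins annotated to `t` or any descendant (ancestor
propagation); the corpus is the training-split annotation set by default.
Terms absent from the corpus are assigned the corpus maximum IC plus one
log unit — treated as maximally informative without producing infinities.
Protein-level Resnik similarity maximizes over the annotation cross
product and, for network construction, over the three subontologies, so a
single θ_R governs one network. θ_R is selected from the observed
similarity values (plus one value above the maximum, giving the empty
network) to minimize the absolute average-degree difference from the
positive-label reference network; ties prefer the larger threshold
(sparser network). Feature conventions: Adamic–Adar skips degree-1
neighbors (ln 1 = 0); 0/0 ratios are 0; the Otsuka–Ochiai denominator is
`sqrt(|N(Pi)|·|N(Pj)|)` (the cosine form); proteins absent from the
network are isolated nodes, so unseen test proteins degrade to zero
features. The network spans training proteins only — extending it over
test proteins would leak test-time information into the representation.

## Stacked classifier

Base learners (scikit-learn): random forest (500 trees), Gaussian naive
Bayes, one-hidden-layer MLP (100 units, early stopping when ≥ 100 training
rows — below that the 10 % validation split is too small to steer it) and
k-NN (k = 5, inverse-distance weights, k capped at the training size).
Meta-data are *out-of-fold* interacting-class probabilities from an
internal stratified 5-fold split assigned at the pair level, so both
concatenation orders of a pair share a fold and no base model ever scores
an instance it saw. The meta-classifier is an RBF SVM with sigmoid
probability calibration; C ∈ {0.1, 1, 10, 100} × γ ∈ {scale, 0.01, 0.001}
are chosen by internal CV maximizing MCC. All of these are configurable.

The decision threshold τ maximizes training MCC over the *midpoints*
between consecutive unique training meta-probabilities (plus the minimum,
i.e. predict-all-positive). Midpoints reach every achievable training
confusion — hence the same maximal training MCC as searching the observed
values themselves — but center the cut between the classes; a cut placed
exactly at an observed positive's probability misclassified held-out
positives lying marginally below it when the meta probabilities saturate.
Ties in MCC prefer the smaller τ (higher sensitivity).

Known limitation: base models are refit on the full training split for
inference while the meta-SVM was trained on out-of-fold probabilities, the
standard stacked-generalization compromise. The distribution shift is
visible in degenerate diagnostics — resubstitution (train = test) scoring
with a distance-weighted k-NN base produces probabilities of exactly 0/1 —
but does not affect held-out prediction, which is the supported use.

## Evaluation protocol

TPR, FPR, precision, accuracy, F-score and MCC are exact confusion-count
arithmetic; undefined ratios report 0 with a flag instead of aborting. AUC
is the rank-based (Mann–Whitney, tie-corrected) ROC area. Cross-validation
is stratified k-fold, repeated with seeds `seed + r`; the primary pooled
result is the mean of per-run metrics, with metrics of the pooled
predictions emitted as a secondary diagnostic (for 3×10 CV the two can
differ; the mean-of-runs is reported first). Paired t-tests are two-sided
on equal-length per-fold series from identical fold assignments;
zero-variance difference series return p = 1 with a warning. The ablation
driver evaluates all seven feature-block subsets on byte-identical fold
assignments (verified by hashing) so its series are directly comparable in
paired tests.

## Synthetic data

The generator emulates the structure the method assumes. A random rooted
DAG per subontology (each term attaching to 1–2 earlier terms) carries
functional *modules*: anchor terms at level ≥ 2 with disjoint descendant
subgraphs (disjointness makes modules distinct functional areas; overlap is
allowed only when the DAG is too small). Proteins are assigned to modules
round-robin; annotations are drawn from the module subgraph with a uniform
noise rate; interacting pairs come from one module and non-interacting
pairs from two, each with probability `signal`, so positives share deep
annotations (high Resnik similarity, shared LCA clusters) by construction.

Sequence signal: auto-covariance detects *serial correlation*, not
composition, so an i.i.d. sequence with one inserted motif is invisible to
F1. Module members therefore carry their module's motif *tiled* along the
sequence with random spacers (probability `motif_rate`), producing a
lag-correlated fingerprint; unstructured proteins have AC terms near zero.
With `signal = 0` pairs are sampled uniformly and labels are independent
of every feature — the null condition under which cross-validated AUC is
statistically 0.5, which the tests check. `generate_related_datasets`
draws several populations (disjoint proteins, own pairs) against one
shared ontology world — DAGs, anchors, motifs — emulating species annotated
against the same species-independent ontology with conserved modules, for
the cross-dataset protocol.

What the generator does not emulate: real interactome degree
distributions (no scale-free structure), annotation incompleteness bias,
shared evolutionary history between sequences beyond the module motif, or
realistic GO term-depth distributions. Passing tests therefore demonstrate
correctness of the machinery and sensible statistical behavior, not
benchmark-level performance on curated interactomes.

## Problem sizes and defaults used in the test suite

Tests and examples run the pipeline at generator scale: 40–80 proteins,
60–200 pairs, 60 terms per subontology, sequence lengths 50–150, high
signal 0.9/0.9 with 5 % annotation noise, and a light training
configuration (100-tree forest, 25-unit MLP, internal 3-fold meta-data,
C ∈ {1, 10} × γ = scale). The library defaults (500 trees, full grids,
5-fold) remain the recommended settings for real datasets. At test scale
the full stack reaches cross-validated AUC ≈ 0.93–0.95 on high-signal
draws and ≈ 0.5 on null draws; a fully separable draw
(signal 1.0, no noise) is classified perfectly held-out.
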