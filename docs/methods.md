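# Methods

This note records the models implemented in `corescan`, the choices
made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Binder classification and data model

Affinities are competition-assay IC50s in nM; a peptide is a *binder*
iff IC50 < 1000 nM, with 1000 nM itself a non-binder.  The 1000 nM
cutoff is the standard biologically motivated threshold for class II
epitopes.  Units are fixed as nM throughout — no auto-detection.
Sequences are restricted to the 20 standard residues; in strict mode
(default) anything else is an error, in lenient mode the offending rows
are skipped with a warning, because scoring matrices are defined only
over the 20-letter alphabet.  Duplicate sequences within an allele keep
the first occurrence (deterministic and order-stable; how replicate
measurements should be merged is not specified by the data sources
this dialect mirrors).  Coordinates are 0-based half-open internally
and 1-based in reports; core positions are reported 1–9.

Matrix files round-trip through a TSV dialect at 12 significant
digits, which is below every tolerance used anywhere in the package.

## Combinatorial-library matrix derivation

For a complete 180-mixture panel (9 core positions × 20 residues,
13-mer mixtures with alanine at template positions 1, 2, 12, 13 and the
core at positions 3–11):

1. `G` = geometric mean of all 180 IC50s; `r[p][a] = IC50[p][a] / G`;
2. `n[p][a] = r[p][a] / min_a r[p][a]` — the optimal (strongest,
   lowest-IC50) residue per position maps to exactly 1;
3. `ARB_p` = geometric mean of `n[p][·]`, `ARB_all` = geometric mean of
   all 180 normalized values, `w_p = ARB_all / ARB_p`;
4. final matrix `m[p][a] = n[p][a] · w_p` (weighted, default) or
   `m = n` (unweighted).

The position weighting is applied multiplicatively to the normalized
values.  The composition of the weighting step admits other readings
(replace rather than scale, log-space); we fix the multiplicative
form and expose `weighting=True/False`, since the two variants have
identical per-position rank structure and differ only in how much a
"flat" position can dilute the core product.  A position where every
residue binds about equally has `ARB_p ≈ 1` from below, hence a weight
near `ARB_all`; a highly selective position has a large `ARB_p` and is
down-weighted toward its informative residues.  All arithmetic is done
in log space; the derivation is exactly invariant to rescaling the
panel by any positive constant (absorbed by `G`).

Prediction multiplies the nine matrix entries along each 9-mer window
of a peptide and takes the minimum (best core), leftmost window on
ties.  The matrix is IC50-like, so lower products mean stronger
predicted binding; any aggregation other than the best core would need
a model of flanking-residue effects, which is out of scope here.
Panels with values censored at assay sensitivity must be pre-clamped
by the caller (suggested ceiling 50,000 nM): geometric means need
finite positive numbers, and how censoring is resolved is a property
of the assay, not of the derivation.

## Trainable best-core matrix predictor

The harness needs a method that *learns* from binding data.  The
baseline is an iterative best-core estimator of the same 9 × 20
product-form matrix:

* **E-step** — assign each training peptide the 9-mer window with the
  best current score (initially the leftmost window).
* **M-step** — re-estimate the matrix from the assigned cores by
  coordinate-descent backfitting in log space: the cell (p, a) is set
  to the geometric mean, over peptides whose core has residue a at
  position p, of `IC50_i / (G · fit_of_other_positions)`, with one
  pseudocount observation at ratio 1 so unobserved cells stay neutral.
  Ten sweeps per M-step are ample for the inner fit to settle.

The residual correction matters: a naive marginal geometric mean folds
the other eight positions' contributions into every cell, which under
a product-form ground truth blurs anchor preferences enough to cost
roughly 0.25–0.3 AUC on the synthetic benchmark.  Backfitting is the
consistent least-squares estimator of the same log-additive model and
costs nothing extra.  Iteration stops when core assignments are stable
or after `max_iterations` (default 50); `max_iterations = 0` yields
the single M-step on leftmost cores.  Training is fully deterministic:
identical data and configuration give bit-identical matrices.

Global rescaling of the training IC50s cancels in `IC50 / G` and
leaves the matrix unchanged, so predicted rank order is invariant to
assay units.

Every prediction method — derived, trained, or external — satisfies
one interface: `predict_many(peptides)` returns one record per peptide
in stable order, with per-record error entries (not a global failure)
for peptides shorter than 9 residues, and methods unavailable for an
allele are reported as *not available* rather than given a score.

## Peptide similarity and redundancy reduction

Two peptides are similar iff they share an identical 9-mer subsequence
or their ungapped identity strictly exceeds 0.80, where identity is
`M / min(L1, L2)` and `M` is the maximum number of identical aligned
residues over all ungapped relative offsets (any overlap ≥ 1 counts;
short overlaps cannot reach the threshold anyway, a fact the optimized
search exploits).  The 80% threshold is strict: identity exactly 0.80
is not similar.

The production similarity search hashes 9-mers into buckets for
condition 1 and evaluates condition 2 with a vectorized match count
restricted to offsets whose overlap can reach the threshold; it agrees
exactly with the all-pairs brute force (asserted in tests up to 200
peptides).

**Forward Hobohm-1.** Within each partition (binders and non-binders
split at 1000 nM, reduced independently, then merged preserving input
order): count each peptide's similar partners (`N_similarity`), sort
ascending, and keep each peptide in turn unless it is similar to an
already-kept one.  The kept set is independent (no similar pair) and
maximal (every discarded peptide has a kept similar partner), and the
procedure is deterministic.  Ties in `N_similarity` are broken by
lexicographic sequence order, then input position — a reported
deterministic selection needs *some* total order, and this one is
machine-independent.  Whether `N_similarity` should be counted within
the partition being reduced or across the whole dataset is ambiguous
in the procedure this mirrors; the default counts within the partition
(the unit actually being reduced) and a `scope="dataset"` switch gives
the other reading.  Cross-partition similar pairs may survive into the
merged SR set by construction.

**Random removal comparator.** The peptide list is shuffled with a
seed and the later member of each still-present similar pair is
removed.  Different seeds keep different numbers of peptides — the
instability that motivates the deterministic forward selection, which
also keeps at least as many peptides on average (asserted
statistically over ≥ 20 seeds, not per seed).

**Singular peptides (SP)** are those with zero similar partners in the
full set, extracted globally over ALL; with per-partition reduction
this guarantees SP ⊆ SR ⊆ ALL.

## Evaluation

Folds are assigned by seeded shuffle plus round-robin (sizes differ by
at most one, unstratified by default) and the same `FoldAssignment`
is reusable verbatim across methods, so competing predictors face
identical splits.  Trainable methods are evaluated by 5-fold
cross-validation — every peptide scored once, blindly, by a model fit
on the other folds.  Fixed methods (library matrices, published motif
matrices) are evaluated by direct prediction over the whole set.

ROC curves sweep the score threshold from best to worst with tied
scores grouped into one step; the trapezoidal AUC then equals the
Mann–Whitney U statistic with half credit for ties (asserted against
the pairwise count up to 500 points, and against scikit-learn).  AUC
is undefined on single-class label sets and raises.  Spearman rho uses
average ranks on ties, oriented so better prediction gives rho closer
to +1.  Reports round to 3 decimals; unavailable method/allele cells
stay blank, never zero, and summary averages skip them.

**Homolog impact.**  For each allele the analysis cross-validates on
ALL and on SR with shared seeds, extracts the SP peptides' blinded
predictions from each run, and reports `auc_sr`, `auc_all`, their
difference, and the peptide-count reduction `|ALL| − |SP|` with its
fraction of `|ALL|` (the sizes of all three sets are also reported, so
the reduction to SR is recoverable).  Differences across alleles are
compared with a paired two-tailed t-test.  SR-trained folds are drawn
on the SR set itself; SP predictions are taken from whichever folds
they land in.  Alleles whose SP set is empty or single-class are
skipped with a warning.  No sign is asserted for the difference: with
no homologs SR equals ALL and the difference is exactly zero; with
homologs either sign is a legitimate empirical outcome.

## Median-rank consensus

Raw scores from different methods are incomparable, so each method's
scores become percentile ranks within the evaluated set (average ranks
on ties, rank 1 = best after orientation, divided by n).  The
consensus score is the median of the per-method percentile ranks
(mean of the central pair for even counts); it is invariant to
monotone rescaling of any member and to method order, and a consensus
of copies of one method reproduces that method's ranking exactly.
Ranks are computed within the evaluated peptide set rather than
against an external background — that is the set over which AUC is
computed, making the two directly comparable.  Unavailable methods are
excluded per allele, not imputed.  The leave-one-out table re-runs the
consensus with each member removed; the best-subset consensus takes a
primary method list with per-allele fallback substitution and needs at
least two members after substitution.

## Synthetic worlds

The generator emulates the structure of real class II binding
datasets:

* **Truth matrix** — anchor positions (default 1, 4, 6, 9, the classic
  DR motif positions) draw `10**Normal(0, strength)` per residue,
  non-anchors `10**Normal(0, 0.05·strength)` (near-flat, and exactly
  flat at strength 0); each row is scaled so its minimum is 1.
  Default strength 1 (one log10 unit of anchor spread) produces
  motif-driven affinity ranges of 3–4 orders of magnitude, typical of
  well-characterized DR molecules.
* **Peptides** — a mix of 55% independent random 15-mers, 25%
  overlapping 15-mer tiles of synthetic proteins (step 5, overlap 10 —
  consecutive tiles share a 9-mer), 10% single-substitution scans of a
  reference peptide in cliques of 31 (reference + 30 mutants), and 10%
  variant clusters of 5 with 1–2 substitutions.  The proportions mirror
  how epitope-mapping, motif-mapping and cross-reactivity studies
  contribute homologs to real datasets.
* **Affinities** — `IC50 = scale × best-core product under the truth ×
  10**Normal(0, σ)` with σ = 0.3 log10 units of measurement noise by
  default, clamped to [0.1, 50,000] nM.  Unless a fixed scale is
  given, the scale is calibrated so the target binder fraction
  (default 0.5, central in the 0.27–0.70 range of real per-allele
  datasets) sits at the 1000 nM cutoff.
* **Panels** — mixture IC50 for (p, a) = panel scale × truth[p][a] ×
  lognormal noise; at σ = 0 matrix derivation recovers the truth's
  per-position rank order exactly.

Everything is reproducible from one master seed (sub-streams keep
matrix, dataset and panel draws independent).

What the synthetic benchmark does *not* emulate: allele-specific
biology of real DP/DQ motifs, peptide-flanking and length effects,
inter-laboratory assay variability, and censored measurements beyond
simple clamping.  Passing the benchmark therefore shows the machinery
is correct and well-calibrated under a product-form ground truth, not
that any particular real molecule will reach the same AUC.

## Benchmark problem sizes

The fixed benchmark uses one synthetic allele with n = 1,000 peptides,
4 anchors, strength 1, noise σ = 0.3 and master seed 42 — large enough
that 5-fold training sets (800 peptides) exceed the several-hundred
measurements per allele known to be needed for reliable matrix
training, while the whole suite runs in well under a minute.  Under
these conditions the trained predictor reaches 5-fold CV AUC ≈ 0.97
and the library-derived matrix ≈ 0.90 on the full set; oracle-
equivalence checks run at 200–500 instances where brute force is
exact and fast.

## Known limitations

* The similarity search is exact but quadratic in the number of
  peptides; datasets beyond ~10⁵ peptides would need a sharper
  prefilter.
* The baseline trainer fits a single 9-mer register per peptide and no
  flanking or length terms; it is a harness method, not a
  state-of-the-art predictor.
* The EM loop has no likelihood-based convergence criterion; core
  assignments can oscillate between equivalent optima, in which case
  the iteration cap ends training deterministically.
* Consensus combination is the simple median rank; learned or weighted
  combinations are deliberately out of scope.
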