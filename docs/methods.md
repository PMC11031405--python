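# Methods

This note records the statistical model behind `propde`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions that shape results at the margins.

## Study design and data model

The pipeline targets isobaric-label (TMT-style) peptide intensity tables from
factorial designs of the form *age × drug × genetic induction* with a small
number of biological replicates per cell (default 2 × 2 × 2 × 4 = 32
channels).  Samples carry a `batch` label for the dissection/labeling
grouping; batch is never treated as a condition.  Intensities are modeled on
the log2 scale; a missing cell is information ("not quantified"), never zero,
and is carried as an explicit mask through every stage.

## Normalization

Each peptide row is z-scored over its present values and rescaled to the
global moments of the log2 data: `y = z · SD_global + M_global`, where the
global mean and SD (ddof = 1 throughout) are computed over the present values
of the rows that take part in the normalization — rows with fewer than two
present values or zero variance are dropped and counted, and contribute
nothing to the rescaling target.  After the transform every retained row has
exactly the global mean and SD.

Two consequences worth being explicit about:

* **Equal weighting, distorted magnitudes.**  Mapping every row to the same
  spread gives each peptide equal influence in the protein roll-up, but it
  also means a downstream "log2 fold change" is a *pattern contrast in
  rescaled units*, not a raw log2 ratio: a planted shift of δ log2 units
  yields an estimate proportional to δ's z-pattern times `SD_global`, with
  the proportionality depending on each row's total variance.  Sign and
  ranking — which drive propagation, selection and enrichment — are
  unaffected; absolute effect sizes should not be read off these columns.
  In the fully degenerate limit (no baseline spread, no peptide offsets, no
  batch or measurement noise) the rescaling is the identity on the retained
  rows and the estimate equals δ exactly; the test suite pins that limit.
* **Roll-up.**  Proteins are the median of their normalized peptides
  (robust to a single aberrant peptide; the mean is available).  A
  protein-sample cell is missing iff all its peptides are missing there.

## Detection filter and imputation

A protein is kept iff it has at least `min_detected` (default 3) present
values in **every** condition cell — the strict reading of a
3-of-4-replicates-per-treatment rule.  The strictness is configurable in
principle by grouping on a different factor combination; the every-group
semantics change protein counts and are therefore reported in the
preprocessing log.

Remaining gaps are filled by k-nearest-neighbour imputation in protein space
(default k = 10, the convention of the imputation tool family commonly used
with moderated-t workflows): neighbours are ranked by RMS Euclidean distance
over mutually present samples (normalizing by the overlap size keeps
distances comparable across different missingness patterns), restricted to
proteins observed in the target sample, with distance ties broken by protein
id for determinism.  Rows missing more than half their samples fall back to
their row mean.  Observed values are never altered.

## Batch handling

Two distinct uses, mirroring standard practice:

* for **visualization/PCA** only, per-protein batch means are subtracted and
  the grand mean re-added (grand means are preserved exactly);
* for **inference**, batch enters the linear model as a covariate, so
  uncertainty is propagated rather than erased.

## Moderated differential expression

Per protein, OLS on a cell-means design (one coefficient per condition cell)
plus treatment-coded batch dummies; rank deficiency is an error that names
the aliased columns.  Residual variances s² with common df d are shrunk
toward a scaled inverse-χ²(d₀, s₀²) prior estimated by moment matching on
log s²:

    E[log s²]  = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2)
    Var[log s²] = ψ′(d/2) + ψ′(d₀/2)

d₀ solves the trigamma equation by a monotone Newton iteration (the inverse
is cross-checked against a bisection oracle in the tests); when the empirical
variance of log s² does not exceed ψ′(d/2) there is no excess dispersion and
d₀ = ∞, with all variances shrunk to s₀².  If all s² are identical the prior
is degenerate at that common value.  Nonpositive s² (zero-residual fits) are
flagged and excluded from the moment fit.  The moderated statistic uses
s²_post = (d₀s₀² + d·s²)/(d₀ + d) and a t reference with d₀ + d df (normal
when infinite; d₀ = 0 recovers the ordinary t-test and is allowed as a
limit).  p-values are two-sided and raw; Benjamini–Hochberg values are an
optional extra column, because the downstream rules are defined on raw
p < 0.05.  In a multi-plex study the prior can be estimated per plex/stratum
by calling the estimator on each stratum's fit; the single-experiment
pipeline estimates it on the pooled fit.

Contrasts are within-stratum cell-mean combinations ("A_vs_B" = mean(A) −
mean(B)), e.g. the drug effect within uninduced animals averaged over age, so
a drug contrast under induction is a different, directly comparable contrast.

## Gene-set operations

A gene set's shift is tested by a two-sided Wilcoxon rank-sum of set vs
complement log2 fold changes — exact enumeration when both groups have ≤ 10
members, normal approximation with tie correction otherwise.  Fold-change
matrices for display (e.g. antimicrobial-peptide panels) include only set
members detected in every supplied contrast (intersection rule, recorded in
the output metadata).

## Network propagation

Interactions come from a STRING-style edge list; edges are kept iff the
integer combined score is strictly greater than 899 (scores are integers, so
this keeps 900 and up), self-loops are dropped and duplicate or reciprocal
rows merge keeping the maximum score.  The default operator is the symmetric
normalization W = D^(−1/2) A D^(−1/2) on binary weights: its spectrum lies in
[−1, 1], which bounds the iteration error by α^t and makes the fixed number
of iterations well-defined; the row-stochastic mode and score/1000 weights
are provided and echoed in output metadata, since published descriptions of
propagation runs often leave the normalization unstated.  Scores follow

    x_{t+1} = α W x_t + (1 − α) x₀,  α = 0.5, 26 iterations (25 for the
    mouse-liver style integration),

run for exactly the stated number of iterations rather than to convergence,
matching how such analyses report themselves; the closed form
(1 − α)(I − αW)⁻¹x₀ is exposed separately as an oracle.  Unmeasured graph
nodes start at x₀ = 0; measured proteins absent from the graph take no part
in propagation or enrichment (the network is the analysis universe).

Selection takes nodes with more than four interactions (degree ≥ 5), then
the ⌈0.05·m⌉ highest- and lowest-scoring nodes (quantiles computed after the
degree filter, over the m eligible nodes).  Ties break toward the smaller
node id; the up set is removed before the down set is drawn so the two can
never overlap.

## Enrichment and signed scores

Background = degree-filtered network nodes with measured input.  For each
direction and each term with K ≥ 5 background genes, the one-sided Fisher
exact p is the hypergeometric tail P(X ≥ k) with X ~ Hypergeom(N, K, n).
Smaller terms are skipped and counted.  The signed significance score is
−log10 p signed + for up and − for down; a term tested in both directions
reports the direction with the smaller p (exact ties resolve to "up"; at
p = 1 the score is 0 either way, so the choice is cosmetic).  p = 0 cannot
occur from a hypergeometric tail but is capped at the smallest positive
float, with a warning, for robustness to imported tables.  An optional
two-column child→parent map up-propagates annotations over the is_a closure
(diamonds count ancestors once; cycles are an error); no ontology reasoning
beyond that is attempted.

## Classification rules and integration

All rules are pure functions of (p, direction) pairs; "log10_pvalue" is read
as −log10 p throughout, the only convention under which "at least 100× more
significant" equals a difference of +2.

* **age-related**: p < 0.05 in the old-vs-young contrast of untreated
  controls, with the term's direction.
* **activation-dependent drug terms**: (−log10 p_drug) − (−log10 p_drug-under-
  activation) > 2; **activation-independent**: −log10 p_drug > 2 without that
  gap.  Directions come from the drug-vs-vehicle table; terms absent from a
  table count as p = 1 (absence = no evidence).
* **knockdown-induced terms**: −log10 p > 2 in the RNAi-induction contrast —
  the same > 2 convention as the drug rules, adopted for internal consistency
  because no explicit threshold is conventional; it is a parameter.
* **protein-level kinase dependence**: p < 0.05 under both knockdown and
  drug, and p ≥ 0.05 for the drug under constitutive activation.
* **three-dataset concordance**: the differential tables are first restricted
  to genes present in all datasets; a term is shared iff p < 0.05 with the
  same direction in all three enrichment tables.  A term's direction is the
  selection in which it was tested (after best-direction collapse), not the
  mean propagated score of its genes.

## Synthetic data: what it emulates, and what it does not

The generator plants known truth at every level the pipeline tests:

* protein log2 abundances = baseline N(18, 1.2²) + planted contrast shifts +
  per-protein batch shifts N(0, 0.3²); peptides add a fixed offset
  N(0, 0.5²) and measurement noise N(0, 0.25²).  The 0.25 log2-unit
  replicate noise is a convention (true biological replicate variance in
  such studies is not published at this granularity) and is deliberately a
  config field;
* planted effects enter at the **protein** level (the estimand) and shift
  the samples in the positive cells of a named contrast, so the true
  contrast value is exactly δ for standard difference contrasts and the
  induced truth on any overlapping contrast is recorded;
* the interaction graph is a stochastic block model (default 10 modules ×
  20 nodes, within-module edge probability 0.4, between 0.01), edges scored
  uniformly in [900, 999] so every edge survives the read-path threshold;
  nodes left isolated are removed;
* annotations are one "true" term per module (members swapped out with
  probability `term_noise` = 0.05) plus size-matched decoy terms sampled
  uniformly from the graph nodes — decoys live inside the analysis universe,
  which is the harder null;
* missingness is MCAR (rate 0.02) plus logistic intensity-dependent dropout
  with midpoint 15 and slope 1 per log2 unit; a slope of 0 disables the
  intensity-dependent component entirely (a literal logistic at slope 0
  would drop half of everything);
* batches split the replicates of every cell (reps 1–2 vs 3–4), emulating
  two dissection sittings.  Making batch instead coincide with age would be
  closer to a two-plex age design but leaves the age contrast inestimable
  with batch as a covariate, so orthogonal batches are the default and a
  stratified analysis is the way to model fully nested plexes.

Not emulated: spectral/PSM-level effects (ratio compression, isotope
impurity, co-isolation), protein-group ambiguity (shared peptides are
excluded at read time), correlated peptide noise, and real topology of
interaction networks (hubs, degree distribution).  Passing the planted-truth
tests therefore demonstrates that the chain is correct and well-calibrated
under its stated model, not that any particular biological dataset will
yield stable terms.

All randomness flows from a single numpy PCG64 generator seeded once per
dataset and drawn in a fixed order, so a seed fully determines every output
across platforms.

## Numerical choices and degenerate inputs

* ddof = 1 for every SD (row, global, moment matching).
* Trigamma inversion: Newton from x ≈ 0.5 + 1/y, halving steps that would
  go nonpositive; tolerance 1e-10 relative.
* Fisher p via the survival function of the hypergeometric distribution
  (`sf(k−1, …)`), clipped to (tiny, 1].
* Deterministic tie-breaks everywhere ties can occur: protein-id order in
  imputation neighbours and node selection, "up" before "down" at equal p,
  mergesort (stable) for every sort that feeds an output file.
* TSV writers emit floats at 6 significant digits, missing as "NA", and
  sorted rows, so identical analyses give bit-identical files.
* Degenerate inputs fail loudly: empty graphs after thresholding,
  all-constant peptide tables, proteins with no present values, rank-
  deficient designs, selections that cannot be disjoint.

## Problem sizes used by the tests and the acceptance script

The single-study condition is 2000 proteins (10 modules × 20 network nodes),
δ = 1 on module 0, noise 0.25, 4 replicates per group, evaluated over 20
seeds; the three-dataset integration uses triplets of 800-protein datasets
(5 modules × 20 nodes) sharing the planted effect map but with their own
seeds, networks and decoy annotations.  The determinism check runs the full
pipeline twice at 300 proteins.  These sizes are the package's chosen study
conditions; recovery rates at them are computed, not assumed, by
`scripts/acceptance.py`.

## Known limitations

* Fold-change magnitudes after the z-rescaling are not raw log2 ratios (see
  Normalization); rank- and sign-based downstream steps are unaffected.
* Moderation assumes a common residual df across proteins (complete,
  imputed matrices); proteins with wildly different effective information
  content after imputation are not down-weighted.
* Propagation scores are not degree-bias corrected; hubs aggregate signal by
  construction.  The degree filter is a blunt guard, not a correction.
* The enrichment test conditions on the selection size; it inherits any
  selection bias present in the propagation step.
* No redundancy reduction across overlapping terms is performed; a planted
  module can legitimately surface several correlated terms.
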