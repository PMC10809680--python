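# Methods

## Deconvolution model

A bulk methylation profile is modelled as a linear combination of cell-type
reference profiles on the beta scale.  Given the M × K reference mean matrix
μ (rows: selected CpG sites; columns: cell fractions) and a bulk vector b,
proportions are estimated by least squares under non-negativity
(`scipy.optimize.nnls`).  No Σw = 1 or Σw ≤ 1 constraint is imposed by
default: purified references never tile a bulk tissue perfectly, and leaving
the sum free both mirrors common practice and makes the reported `weight_sum`
an informative diagnostic.  Optional `sumleq` / `sumeq` constraints are
solved with SLSQP on the same quadratic objective.  Missing bulk values are
dropped per sample from the objective; a warning is raised below 100% site
coverage and an error below 50%.  On small instances the solver is verified
in the test suite against an independent brute-force simplex grid search at
0.001 resolution (objective agreement within 1e-10).

CETYGO is the RMSE between the observed bulk vector and its reconstruction
μ·ŵ over the non-missing model sites.  It is 0 for a perfect fit and is
computed for any weight vector, but the fitted weights minimise it by
construction.  Scores above 0.1 are flagged as indicating an incorrect or
incomplete reference panel.

## Site selection

**Thresholded t-ranking ("ANOVA" method).**  For each panel fraction, a
row-wise pooled-variance two-sample t-test (fraction vs all other panel
samples, df = n1 + n2 − 2) is computed at every site.  Sites with two-sided
p < 1e-8 are candidates; the n/2 candidates with the largest positive t
(hypermethylated in the fraction) and the n/2 with the largest negative t
(hypomethylated) are taken, with `n_per_type` = 100 by default, so a
two-fraction panel selects at most 200 unique sites.  The union over
fractions, deduplicated, defines the model.  This is a per-fraction
one-vs-rest test, not a global F-test; an optional global-F prefilter
(`f_prefilter=True`) gates candidates additionally.  Ties are broken by
larger absolute mean difference, then lexicographic site id, making the
procedure fully deterministic and invariant to sample order.  If one
direction has too few candidates the deficit is backfilled from the other
direction with a warning; a fraction with zero candidates raises an error
naming it.  No multiple-testing correction is applied beyond the hard
threshold.

**IDOL.**  Applicable only for K > 2.  The candidate pool takes, per
fraction, the 150 sites with the largest and the 150 with the smallest
t-statistics.  Internal test mixtures are reconstructed from one randomly
chosen training sample per fraction combined over the full 0.1-step
composition grid.  Each iteration samples a `library_size` subset (default
50·K) of the pool according to per-site inclusion weights, deconvolves the
mixtures and scores the mean RMSE of estimated vs true proportions; the
incumbent library is replaced whenever the score improves.  Per-site
leave-one-out deltas then scale the weights multiplicatively (×1.1 for
beneficial sites, ×0.9 otherwise, renormalised).  The search runs at most
300 iterations and stops early after 50 non-improving ones; everything is
driven by one seed, so results are exactly reproducible.  The weight-update
magnitude, acceptance rule, library size and early-stop patience are this
package's own choices, recorded in the model's provenance.  Leave-one-out
scores are computed by rank-one downdates of the unconstrained normal
equations — mathematically the exact unconstrained solution — with a
per-column NNLS fallback whenever a downdated weight turns negative, which
keeps a full LOO pass at milliseconds instead of thousands of solver calls.

## Synthetic reference generator

The generator emulates a FANS reference study in two layers.

**Latent atomic types.**  Six atomic cell types: excitatory_upper,
excitatory_deep, inhibitory, oligodendrocyte, microglia, astrocyte.
Splitting excitatory neurons into two sub-populations reflects that the
SATB2 and NeuN gating strategies sample excitatory sub-populations with
different efficiencies — without it the SATB2Pos fraction would be an exact
linear sub-mixture of NeuNPos and no site could distinguish it from the rest
of an overlapping panel.  Background sites share a bimodal beta distribution
(components near 0.1 and 0.9, SD 0.05), matching the genome-wide shape of
methylation data.  Each atomic type carries `n_dmp_per_type` = 100
hypermethylated and 100 hypomethylated planted differentially methylated
positions (DMPs) with separation `delta` = 0.4 from all other types.  In
addition, lineage groups — neuronal (all neurons), excitatory (both
excitatory sub-types) and glial (all glia) — carry shared signature sites at
the same separation.  Lineage signatures are essential realism: in brain,
the dominant axis of methylation variation separates neurons from glia, and
negatively selected fractions (NeuNNeg, SATB2Neg) are only identifiable at
sites their member types share.  Default 3000 sites, of which 1800 are
planted.

**Fraction sampling.**  Ten fraction presets mix the atomic types
(e.g. NeuNPos = 0.48 excitatory_upper + 0.32 excitatory_deep + 0.2
inhibitory; SATB2Pos = 0.85/0.15 over the excitatory sub-types; NeuNNeg =
0.4 oligodendrocyte + 0.25 microglia + 0.35 astrocyte, the approximate
glial composition of cortex).  Per-fraction sample counts default to a
realistic sorted-nuclei study (28 NeuNPos down to 3 NeuNPos/SOX6Neg).  Each
sample is its fraction's expected profile plus additive Gaussian noise on
the beta scale (default SD 0.02), clipped to [0, 1]; a logit-normal noise
option exists.  Clipping rather than truncation keeps the generator simple
and the [0, 1] invariant exact; at interior sites the realised per-site SD
matches the nominal one (checked by Monte-Carlo in the tests).  One
individual contributes at most one sample per fraction; optional per-batch
constant shifts emulate chip effects.

**What the generator does not emulate** — probe chemistry (type I/II),
detection-p artifacts, normalisation residue, spatially correlated noise,
fraction-specific impurity gradients and real inter-individual biology.
Passing tests therefore demonstrate correctness of the algorithms and their
behaviour under the stated noise model, not performance on any particular
empirical dataset.

## Validation experiment

Composition grids enumerate all weight vectors in 0.1 steps with per-type
minimum 0.1, maximum 0.9, summing to 1 — C(9, K−1) mixtures (9, 36, 84, 126
for K = 2..5).  Per train/test split, one sample of each fraction is held
out (samples may recur across the 10 default splits; the within-split draw
is without replacement), a model is trained on the remainder, pseudo-bulk
profiles are reconstructed from the held-out samples over the full grid and
deconvolved.  A 2-fraction panel over 10 splits therefore evaluates 90
mixtures and a 5-fraction panel 1260.  Accuracy is reported per mixture
(CETYGO, weight RMSE) and per fraction (Pearson r pooled over mixtures and
splits, RMSE, median signed error with positive = overestimate).  r is
reported as NaN, never 0, when undefined (< 3 mixtures or zero variance).
Train and test share the synthetic batch unless batch effects are requested.

Benchmarking runs every applicable (panel, method) pair — the "ANOVA" method
for all 8 preset panels, IDOL for the 7 panels with K > 2, 15 models in
total — with a shared seed for comparability; per-pair failures are recorded
in the report metadata without aborting the run.

## FANS sample QC (maxSD)

PCA (top two components, full SVD, sites centred) is computed once over
complete-case sites.  PC scores are Studentized across all samples; samples
with |z| > 1.5 on either PC are excluded from the per-fraction summary
statistics.  Each sample's maxSD is the maximum over PC1/PC2 of its absolute
distance from its labelled fraction's mean in units of that fraction's SD.
Individuals whose median maxSD exceeds 5 are flagged as failed sorts and all
their samples dropped; Studentization and fraction summaries (not the PCA
itself) are then recomputed, and a sample is retained only within 2 SDs of
its fraction's mean on both PCs.  Re-running the PCA after exclusion is
available via `recompute_pca=True`.  Two geometric facts shape behaviour:
with population SDs a sample can sit at most (n−1)/√n SDs from its own
fraction's mean, so the retention step cannot drop members of fractions with
n ≤ 5; and a single planted outlier among n clean samples scores ≈ √n SDs,
so the failed-sort threshold of 5 presumes fractions of roughly 30+ samples,
as in a full array run.  Restricting input to autosomal sites is the
caller's responsibility, since site ids are opaque here.

## Numerical choices and problem sizes

Beta validity is enforced once at the I/O boundary ([0, 1] or missing;
unique ids).  Reference data used for training must be complete over model
sites.  Tolerances: round-trip I/O 1e-9; exact-recovery checks 1e-6 on
weights and CETYGO; grid rows sum to 1 within 1e-12.  Model seeds derive
from one run seed (seed + stage index, kept below 2^31).  The default suite
and the acceptance script run the full study-scale experiment (3000 sites,
123 reference samples, 10 splits, all panels and methods) in about a minute
on one CPU; the problem sizes were chosen as the package's own desk-scale
study conditions and are stated in the generator defaults.

## Known limitations

* Proportions, not abundances: a change in one estimated fraction can
  reflect compositional shifts elsewhere.
* The generator's linear-mixture fractions make some out-of-panel profiles
  exactly representable at the model sites; the incomplete-panel behaviour
  of CETYGO is therefore demonstrated with atomic types whose signature
  sites the panel lacks (e.g. astrocytes left out), the synthetic analogue
  of applying a cortical panel to a tissue with unmodelled cell types.
* The hard p < 1e-8 selection gate interacts with panel composition: a
  fraction distinguishable from the rest of its panel only through diluted
  or heterogeneous contrasts may yield no candidates, which is surfaced as
  an explicit selection error rather than silently degraded models.
* IDOL's internal mixtures reuse training samples, so its gains over the
  t-ranking baseline are modest on well-separated synthetic data, consistent
  with the two methods performing comparably in practice.
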