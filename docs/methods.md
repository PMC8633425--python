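# Methods

`netatrophy` analyses how regional brain atrophy progresses over a
longitudinal study and how that progression relates to brain connectivity
and regional transcriptomics.  Everything operates at the parcel level: a
brain is an ordered list of regions with spherical coordinates, hemisphere,
network and cortical-type labels, and all maps, matrices and expression
tables are keyed to that order.  This note documents the models, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices that were genuinely open.

## Normative W-scores

Regional deformation values (unitless expansion/contraction ratios from
deformation-based morphometry; values near 1, smaller = tissue loss) are
standardised against healthy controls.  For region *i*:

    W_i = (DBM_i − (β1·age + β2·sex + β3)) / SD_i

with β fitted by per-region OLS on baseline controls only and SD_i the
standard deviation of the control residuals.  Negative W means atrophy.
Choices:

- **Degrees of freedom.** SD uses denominator n − 3, unbiased under the
  three-parameter model.
- **Sex coding.** 0 = female, 1 = male, recorded in output metadata.
  Differences of W between sessions are invariant to this choice because a
  subject's sex term cancels.
- **No site term in the normative model.** Scanner site enters later, as a
  covariate of the progression test; W itself adjusts only age and sex.
- **Scale invariance.** Multiplying all deformation values by c > 0
  rescales residual SDs by c and leaves W unchanged; a test asserts this.

A known limitation, quantified during calibration: because β is estimated
from finite controls, subjects whose ages advance across sessions carry a
small shared session trend (β̂ − β)·Δage into W.  With ~150 controls the
induced repeated-measures noncentrality is negligible, but it is a real
property of W-score pipelines, not of this implementation.

## Progression maps and group tests

The progression score is the *decline* in W from baseline,
`score = −(W_followup − W_baseline)`, positive = atrophy accrued;
group maps average over subjects.  Regional inference uses a one-way
repeated-measures ANOVA across the four sessions (subjects as blocks),
with:

- **Covariate adjustment.** Sex and site are between-subject and
  session-constant, so their additive component is estimated from subject
  session-means and the same centred adjustment is subtracted from every
  session of a subject.  This removes covariate-related between-subject
  variance while commuting exactly with within-subject permutations — the
  permutation null stays exact.  (Residualising each session separately
  looks equivalent but silently perturbs exchangeability; an earlier
  variant did this and measurably inflated the family-wise error.)
- **FWE control.** Max-statistic permutation: session labels are permuted
  within subjects (the same permutation applied to all regions), the
  maximum F over regions forms the null, and each region's FWE p is its
  add-one rank.  Benjamini–Hochberg FDR over the parametric p-values is
  reported alongside.  Default 1000 permutations.
- **Post hoc.** One-tailed paired contrasts, baseline vs each follow-up,
  in the direction of declining W.
- **Time as factor.** Session is treated as a categorical factor (the
  natural reading for four fixed visits); a linear-trend alternative would
  be easy to add but is not required by any downstream statistic.

Cortical-type contrasts use a one-way ANOVA over regions grouped by the
four-level hierarchy (paralimbic / heteromodal / unimodal / idiotypic)
with Bonferroni-adjusted pairwise t-tests.  Clinical associations use
partial Spearman correlations (rank-transform everything, residualise the
ranked variables on ranked covariates, t-approximation with df = n − 2 − k)
with BH-FDR over the battery; one-way repeated-measures ANOVA with
Holm-adjusted paired contrasts handles longitudinal clinical measures.

## Spin nulls

Significance of any statistic defined on a spatial map must discount
spatial autocorrelation: nearby parcels are similar for uninteresting
reasons.  The null model rotates the parcel centroids on the unit sphere —
a uniform random rotation for the left hemisphere, its sagittal mirror for
the right — and reassigns each region the value of the nearest rotated
same-hemisphere centroid.  Rotations are isometries, so spun maps keep the
original autocorrelation structure.  Choices:

- **Assignment.** `nearest` (duplicates allowed) is the default;
  `bijective` (optimal one-to-one matching per hemisphere via the
  Hungarian algorithm) gives strict permutation semantics.  Nearest-ties
  break to the lowest region index, deterministically.
- **p-value convention.** `p = (1 + k) / (1 + N)` counting the observed
  statistic among the draws; p is never zero and its minimum is
  1/(1 + N).  A plain `k / N` convention is available by flag.
- **Label-mean tests.** Network labels are permuted by the spin assignment
  and label means recomputed; with `nearest` a label can vanish from a
  spun labelling, in which case that spin is skipped for that label and
  the denominator shrinks (logged).

Calibration (recomputed by `scripts/acceptance.py`): on independent
spatially autocorrelated map pairs the spin test's type-I error sits near
the nominal 5%, while a naive value shuffle on the same data rejects an
order of magnitude more often.

## Network-spread statistics

If atrophy propagates trans-neuronally, a region's progression should
track the progression of its connected neighbourhood.  Four neighbourhood
estimators are computed: unweighted mean over structural neighbours,
FC-weighted mean over structural neighbours, FC-weighted mean over
structurally *unconnected* regions, and FC-weighted mean over all other
regions (the latter two isolate the functional contribution).  Self is
always excluded; regions with an empty neighbourhood or |Σ weights| <
1e-8 are flagged missing, never zeroed.  Negative FC weights are kept by
default (`raw_fc`), with a clipped-at-zero mode available.  The statistic
is the Pearson correlation over unflagged regions between node values and
neighbourhood estimates; its spin null rotates the atrophy map and
recomputes *both* sides from the spun map with the network fixed.

Dependent correlations sharing the atrophy map are compared with Zou's
(2007) interval for the difference of two overlapping correlations, with
the sampling correlation between the two coefficients computed from the
observed correlation between the two neighbour-estimate vectors.  A
Maslov–Sneppen degree-preserving rewired graph serves as negative
control: it keeps the degree sequence but destroys the embedding that
carries the spread.

## Virtual histology and gene screening

Cell-class maps are regional means of marker-gene expression for the
seven canonical cortical classes (astrocytes, endothelial cells,
microglia, excitatory and inhibitory neurons, oligodendrocytes, OPCs);
each map's Pearson correlation with a progression map is tested against
the shared spin null.  The gene-wise screen correlates every gene with
the progression map (Pearson by default, Spearman by flag), requires
*both* BH-FDR-adjusted parametric p < 0.05 and spin p < 0.05 (joint
criterion), and splits survivors by correlation sign.  Overrepresentation
of a survivor list within annotation terms reports observed and expected
counts, fold enrichment = observed/expected, the hypergeometric
upper-tail p and the (identical-tail) one-sided Fisher exact p, Bonferroni
over tested terms; terms with fewer than 5 background genes are skipped
(degenerate folds).  The background is all genes present in the
expression matrix.

## The synthetic generator

The generator exists so that every stage can be validated against known
ground truth; its defaults *are* the study conditions of the analyses and
tests.

- **Atlas.** Fibonacci lattice on each unit hemisphere, mirror-symmetric;
  seven spatially contiguous network patches (nearest of seven seed
  parcels); cortical types by an equal-count latitude quantisation.
  Mirror symmetry forces even region counts, so the "219-region" scale of
  the validation experiments is realised as 110 per hemisphere (220).
- **Connectome.** Structural edges sampled with probability ∝
  exp(−d/λ), λ = 1.0 rad, rescaled to a target density of 0.15 and
  resampled until connected and within ±10% of target.  λ = 1.0 keeps a
  realistic share of long-range edges; a purely proximal graph (small λ)
  is statistically indistinguishable from spatial autocorrelation, and
  the spin test then rightly absorbs the network effect.  The functional
  matrix is the degree-normalised communicability of the structural graph
  plus symmetric Gaussian noise (SD 0.1), rescaled into [−1, 1].
- **Spread.** Linear accumulation on the structural graph:
  each step adds `η · vulnerability_i · Σ_j Â_ij load_j` with Â the
  receiving-degree-normalised adjacency, unit load on the epicentres
  (one paralimbic region per hemisphere), η = 0.3, two steps per study
  year.  Output is monotone in steps and η.  This is deliberately the
  simplest process guaranteed to produce connectivity-shaped atrophy; it
  is not an agent-based infection model.
- **Cohort.** 157 controls (baseline only — they are purely the normative
  reference) and 74 patients at baseline/1/2/4 years, ages uniform 45–80
  advancing with sessions, 70% male, three scanner sites.  Deformation =
  1.0 − 0.005·age + 0.03·sex + subject effect (SD 0.05) + site effect
  (SD 0.02) + scan noise (SD 0.08).  Patient follow-ups subtract a
  deficit: the spread load normalised to unit peak per session (raw
  multiplicative loads are incomparable across horizons) times years/4
  times `disease_effect_scale · noise_sd`.  The default scale 1.5 puts
  the peak 4-year decline at ≈1.3 control-SD in W units — a clearly
  expressed effect, chosen so the planted positive controls are
  recoverable with high power at these sample sizes.
- **Expression.** Each gene is a unit-variance Gaussian field on the
  sphere (squared-exponential kernel, lengthscale 0.5 rad) plus white
  noise (SD 0.4), z-scored per gene.  The seven cell classes are planted
  as shared latent fields (mixing 0.6, 20 genes each).  The protective
  effect ties regional vulnerability to the endothelial latent,
  `vulnerability = exp(−1.5 · z(latent))`, so endothelial-rich regions
  accrue less atrophy — mirroring the direction of the motivating
  finding.  Fifty genes additionally track the 4-year deficit pattern
  (mixing 0.7); the positive-control annotation term samples 15 of them,
  a size-matched random term is the negative control, and 18 random
  filler terms pad the Bonferroni family.

What the generator does **not** emulate: voxel-level structure, real
tractography or BOLD physics, realistic effect sizes of any particular
disease, missing visits, scanner drift, or clinical symptom scores.
Passing recovery tests therefore shows that the pipeline detects what it
is designed to detect under its own assumptions — not that those effects
are detectable in any given real cohort.

## Numerical and degenerate-input conventions

- Matrices must be symmetric within 1e-8 (then symmetrised by averaging);
  diagonals are forced to zero; functional weights are clipped to [−1, 1]
  after a 1e-8 slack check.
- Centroids are renormalised if within 1e-6 of unit norm, rejected
  otherwise; zero vectors are degenerate.
- Zero residual SD in any region aborts the normative fit ("degenerate
  control data"); single-sex control cohorts are rejected.
- Constant gene columns are excluded from the screen with a warning;
  constant maps are errors wherever a correlation is required.
- All stochastic functions accept an integer seed (or a Generator);
  pipeline stages derive child seeds from the master seed via
  `SeedSequence`, so a run is reproducible end to end and re-running a
  config yields byte-identical outputs.

## Validation experiment sizes

The experiments behind `tests/test_acceptance.py` and
`scripts/acceptance.py` use: 20 random small instances per operation for
oracle equivalence; 200 replicate map pairs at 220 regions with 500 spins
for spin calibration; 157 training / 500 held-out controls for the
W-score contract; 20 replicates at 220 regions with 1000 spins (spread
maturity: η = 0.3, 10 steps) for network recovery; 20 full synthetic
studies with 1000 spins for planted-effect recovery (4-year interval);
2000 trivariate-normal replicates at n = 200 for Zou coverage; and 200
null cohorts (40 patients, 114 regions, 500 permutations) for family-wise
error.  The whole battery completes in a few minutes on one CPU.
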