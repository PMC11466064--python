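# Methods

This note documents the models, conventions and numerical choices behind
`spincolocal`, and what its synthetic-data generators do and do not emulate.

## Object-based puncta analysis

**Detection.** One channel of an `ImageField` is binarized by a global
threshold (Otsu by default; triangle and fixed-value thresholds are
available) and 8-connected components become puncta, following the ImageJ
particle-analysis convention. No watershed splitting is attempted: two spots
whose footprints touch — even diagonally — are one object. A constant image
cannot support a data-driven threshold and yields an empty set with a
provenance flag rather than an exception.

All geometry is physical. A punctum's *equivalent diameter* is that of the
circle with its pixel area, `2·sqrt(A/π)`; pixel indices are 0-based with
the origin top-left, and a centroid in µm is the mean pixel index times the
pixel size. The immunohistochemistry size filter retains equivalent
diameters in the closed interval [0.2, 3.0] µm — exclusion is strict outside
the bounds, so the filter is idempotent and monotone in its bounds.
Densities count objects per µm² by the centroid-in-ROI rule, which makes
density additive over disjoint ROIs and avoids double counting at ROI
boundaries.

**Colocalization.** Both channels' puncta are first enlarged by a disk of
radius 0.1 µm (guarding against edge exclusion); a sub-pixel radius is
rounded up to one full pixel so the enlargement is never lost to
rasterization. A reference punctum is colocalized when the fraction of its
dilated footprint covered by the union of the other channel's dilated
puncta strictly exceeds 0.5. Normalizing by the *reference* area makes the
measure deliberately asymmetric — a small receptor-subunit cluster inside a
large gephyrin cluster is colocalized, the converse is not — and the
reporting direction is chosen by argument order. A punctum straddling
several partners sums its covered pixels and is counted once. Percent
reductions between group means are reported to one decimal,
`100·(control − test)/control`; group comparisons use the unpaired
two-sided t test with SEMs, flagging the degenerate zero-variance case
instead of raising.

An important property at tissue-like densities: object-based colocalization
has a nonzero *chance* rate (random spot placement yields a few percent of
colocalized calls at ~0.1 spots/µm²), and touching same-channel spots merge.
Both effects are inherent to the method, not implementation artifacts; the
oracle-equivalence tests pin the implementation to an independent per-pixel
Python-set computation, and the recovery tests quantify the residual bias
(≤ 0.05 absolute over the full range of true colocalized fractions under
the validation conditions below).

## RNAscope cell calling

Nuclei are Otsu-thresholded from the nuclear-stain channel, labeled with
8-connectivity, and filtered by a minimum area (default 3 µm²); touching
nuclei merge — the simulator places disjoint nuclei, so this is adequate
for its fields and documented as a limitation for real tissue. Each nucleus
is expanded by a Euclidean disk of radius 2 µm, and a cell is positive for
a marker when ≥ 3 detected dots have their centroid inside the expanded
area. Marker dots are detected with the plain puncta detector *without* the
0.2–3 µm size filter (that cutoff belongs to the immunohistochemistry
procedure; single-transcript dots are smaller). A dot lying in two cells'
overlapping expanded areas is assigned to the nearer nucleus centroid, ties
to the lower cell id. Background staining, which varies by fluorophore, is
handled only through the ≥3-dot rule; no background subtraction is applied.
Coexpression tables report P(target⁺ | conditioning⁺) per region, with
per-section means and SD when section ids are present.

## Hill-equation fitting

The concentration-response model is
`I(c) = baseline + I_max·c^n_h/(c^n_h + EC50^n_h)`; potentiation curves fix
the baseline to 0 and the plateau plays the role of E_max. Fitting is
nonlinear least squares (Levenberg–Marquardt) in `log10(EC50)` and
`log10(n_h)` so both remain positive, with tolerances 1e-14 so that data on
the model surface are recovered to ≲1e-6 relative error. The initializer is
deterministic and data-driven: EC50 at the concentration whose response is
nearest half-maximum, n_h = 1, I_max at the maximum response. Replicates
are pooled as independent observations (no per-cell weighting). Standard
errors come from the Gauss–Newton covariance with the delta method mapping
the log-scale parameters back to natural units. Non-convergence is a
flagged result with the solver message; all-equal responses are rejected as
degenerate. `EC_f` concentrations use the closed-form inverse
`EC50·(f/(1−f))^(1/n_h)`, verified in tests against numerical root-finding.

## %MPE

`%MPE(t) = 100·(E(t) − E_predrug)/(E_preCCI − E_predrug)` with all
thresholds in grams. The ratio is computed before scaling so the identities
(exactly 0 at the pre-drug threshold, exactly 100 at the pre-injury
threshold) hold in floating point. Values are not clipped: recovery beyond
the pre-injury baseline exceeds 100 %, further sensitization is negative —
clipping would bias window means. The reported statistic is the per-animal
arithmetic mean over a time window (default {0.5, 1} h post-drug), computed
per animal and then compared between cohorts with an unpaired t test;
Bonferroni correction multiplies p by the declared number of tests, capped
at 1.

## Synthetic-data generators

All generators take one integer seed; per-channel/per-marker sub-streams
are derived as `default_rng([seed, index])`, so identical parameters and
seed give bit-identical outputs.

**Puncta fields.** Spots are isotropic 2D Gaussians whose FWHM equals the
nominal diameter (diffraction-limited spots make "diameter" well defined),
at Poisson-random uniform positions, on a constant background with optional
additive Gaussian noise (images are clipped at 0). Default pixel size is
0.15 µm — typical for a 40× oil-immersion confocal — and fields are 2D
single planes. Default spot diameter is 0.45 µm (SD 0.06), typical of
synaptic puncta and safely inside the [0.2, 3] µm filter. The generator
rejects parameter sets whose Boolean-model expected object overlap within a
channel exceeds 20 %, since truth then stops being recoverable by component
labeling. True colocalization: a deterministic rounded fraction of
channel-2 spots is placed concentric with *distinct* channel-1 partners
(sampled without replacement — with replacement, two truth spots could
coincide exactly and merge into one detectable object, making the stated
truth unrecoverable in principle).

Validation conditions used in the recovery tests: noise-free rendering,
reference channel at 0.1/µm² and the other channel at 0.06/µm² (so
partners are never exhausted at a true fraction of 1), 80×80 µm fields.
Density-recovery checks use a sparse 0.01/µm² field where component
counting is unbiased; at study-like densities (0.2–0.6/µm²) merging biases
raw component counts downward by several percent, which is a property of
the counting procedure on any such image, simulated or real.

**FISH fields.** Disjoint disk nuclei (rejection-sampled with a 1 µm
margin; impossible packings are rejected), one dot channel per marker.
Each cell expresses a marker with the configured probability; positive
cells receive Poisson-many dots (default mean 12) uniform in the 2
µm-expanded nuclear disk, and background dots land uniformly at a
per-fluorophore rate (default 0.001/µm², i.e. ≪ 1 expected background dot
per expanded cell area). Regions are vertical strips of the field. Default
expression probabilities (0.44, 0.95) mirror the reported prevalence of
the two γ-subunit transcripts in the superficial dorsal horn.

**Dose-response and behavior.** Responses are the Hill curve plus additive
Gaussian noise. Behavioral cohorts draw a per-animal pre-injury baseline
(default 6 g, a typical electronic von Frey threshold in mice), apply a
fixed injury drop (default 60 %), and produce post-drug thresholds whose
drug-effect profile is 1 up to 1 h and decays as `exp(−(t−1))` after, so
the expected window mean over {0.5, 1} h equals the requested effect size.

**What the generators do not emulate:** 3D point-spread functions, optical
aberrations, channel bleed-through, tissue autofluorescence texture,
irregular nucleus shapes, or spatially clustered biological densities.
Passing recovery tests therefore demonstrates correctness of the
quantification rules under controlled truth, not robustness to every
property of real tissue images.

## Problem sizes

Tests and the acceptance script run at deliberately moderate scale chosen
as sufficient for the statistical assertions they make: 100 random 128×128
px fields for oracle equivalence; 3 fields × 5 truth levels for
colocalization-fraction recovery; 2 fields × 25 cells for FISH
sensitivity/specificity; 100 noisy fits (8 concentrations × 5 replicates,
σ = 5 % of I_max) for the EC50 error distribution; 1,000 random baselines
for the %MPE identities.
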