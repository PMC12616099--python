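# Methods

This note records the modelling choices behind `mechage`: the procedure and
its assumptions, the parameters that matter, what the phantom generator does
and does not emulate, and the numerical conventions adopted where the design
was genuinely open.

## The two-stage framework

The pipeline predicts chronological age from one to three registered 3D
channels per subject (shear stiffness μ, damping ratio ξ, optionally an
anatomical T1-like channel). All computation happens in voxel space; the
package assumes that skull stripping, bias-field correction and template
registration happened upstream (they are irrelevant for phantom data).

**Encoder.** Inputs are standardised channel-wise with the training set's
within-mask mean and SD (background stays zero); a `per_image_norm` flag
instead z-scores each image on its own, deliberately destroying the global
ageing trend to probe purely spatial signal. The default `small3dcnn`
encoder is three stride-2 3×3×3 conv blocks (widths 8/16/32 ×
`width_multiplier`), global average pooling and a linear projection to the
embedding dimension; embeddings are L2-normalised at extraction. A slim
residual variant (`resnet18_3d`) is available when more capacity is wanted.
The networks and their backward passes are implemented directly on numpy —
volumes at 8–32 voxels per side make explicit im2col convolutions fast
enough on one CPU — and every layer is finite-difference gradient-checked in
the test suite. Training is plain Adam; initialisation and batch order are
fully determined by the seed, and there are no stochastic layers, so
embeddings are a pure function of (weights, input).

**Adaptive contrastive loss.** For ages `y` and embeddings `f(x)`:

    L = − Σ_i Σ_{k≠i}  ŵ_ik · log[ exp(s_ik) / Σ_{t∈NN(i;e)} exp(s_it(1−w_it)) ],
    ŵ_ik = w_ik / Σ_{t≠i} w_it,    w_ik = exp(−(y_i−y_k)²/2σ²).

Conventions adopted where the formulation leaves room:

- The kernel is normalised to K(0)=1 (no density prefactor); only relative
  weights matter after row-normalisation, and the unit diagonal gives clean
  invariants.
- `s_ik` defaults to cosine similarity divided by a temperature τ; a dot
  product variant exists. Cosine keeps the loss scale-free in the embedding
  norm.
- The outer sum runs over all k≠i; the log-denominator runs over the
  neighbourhood exactly as written. The positive index k may fall outside
  NN(i; epoch); no term is forcibly added, so individual pair terms can be
  negative and the loss is reported as-is.
- Self-pairs are excluded everywhere (k≠i, and t≠i in the weight
  normaliser).
- Neighbourhoods rank candidates by *age* distance (ties broken by index)
  and keep the first ⌈ρ(epoch)·(n−1)⌉; ρ decays linearly from `rho_start`
  (1.0) to `rho_end` (0.25) across epochs. Ranking by age rather than by
  embedding distance reads the mechanism as age-driven focusing; the
  alternative is a one-line change in `select_neighbourhoods`.
- Neighbourhoods are formed within each mini-batch. Dataset-wide sets would
  need a full embedding pass per epoch for no benefit at these cohort sizes.
- The gradient is computed analytically (including the projection through
  the cosine normalisation) and verified against finite differences.

σ (default 2 y), τ (default 0.1), the ρ schedule and the optimiser settings
are package conventions exposed in `KernelConfig` / `NeighbourhoodSchedule`
/ `TrainConfig`; no published values exist for them at this granularity.

**Ridge head.** Closed form on mean-centred features and targets,
`w = (XᵀX + λI)⁻¹ Xᵀy`, λ = 1.0 by default with optional inner 5-fold CV
over a log grid. MAE is evaluated on the held-out 20% only. Multi-seed runs
re-randomise both the split and the training seed by default (a flag
decouples them); aggregates use the t-distribution CI over per-seed MAEs.

## Brain-age-gap statistics

Raw BAG is predicted − chronological age. Because shrinkage pulls
predictions toward the training mean, raw BAG correlates negatively with
age; the bias model is a Theil-Sen fit (median of pairwise slopes;
intercept = median(pred − slope·age), scipy's "joint" convention) of
predicted vs chronological age on healthy controls, and the corrected BAG
subtracts the line's prediction. Fitting predicted-vs-age rather than
BAG-vs-age is the common brain-age convention; the two are algebraically
equivalent up to a unit slope shift. After correction the controls'
Theil-Sen BAG-vs-age slope is exactly zero (a median identity, tested).

Group comparisons follow a normality-gated protocol: Shapiro-Wilk on each
group (or on paired differences) at α = 0.05 selects t-tests or their
rank-based counterparts; all tests are two-sided. Rank tests use exact
p-values when both groups have ≤ 12 samples and no ties, and the
tie-corrected normal approximation otherwise — exactness at phantom scale
keeps the calibration tests reproducible. No multiple-testing correction is
applied across regions; the number of tests is the caller's to log.

The disease protocol retrains the normative model on healthy subjects only,
excluding the matched controls, which are used solely to fit the bias
model; a guard rejects any overlap between the two sets.

## Occlusion saliency

Cubes of `cube_size`³ voxels (default 7, odd) are placed on a stride grid
(default stride = cube size, i.e. non-overlapping, for desk-scale cost;
stride 1 gives dense maps) and filled in all channels; the recorded value is
the per-subject change in absolute error. Per-subject maps are averaged
within quantile age bins (default 5) and min-max scaled to [0, 1] per bin —
the normalisation is a declared convention for group-level display.

Two fill values are implemented. `zero` matches the zero-padded background.
Note that inside the brain mask a zero is *not* neutral after
standardisation (it maps to −mean/SD), so zero-fill probes "what if this
tissue were missing" and perturbs the input wherever the cube overlaps the
mask. `training_mean` standardises to zero and is the neutral probe; the
localisation analyses in the tests and examples use it because it isolates
informative regions without the missing-tissue artefact.

## Regional models

Each region's pipeline trains on volumes masked to the region (atlas label ∩
brain mask), cropped to the region's bounding box and zero-padded to at
least 8 voxels per axis. Out-of-region voxels are zeroed before cropping,
which enforces the masking contract exactly: perturbing them cannot change
the regional prediction. Regions below a configurable voxel floor (default
50) are rejected rather than silently fitted. Cohort profiles are the
arithmetic mean of corrected BAGs per region; individual-to-cohort profile
similarity defaults to Pearson across regions (cosine available) — the
matching of "disease-like" healthy individuals is operationalised as
ranking by this similarity.

## Baselines

PCA + Gaussian-process regression flattens in-mask voxels, projects onto
≤ n_train−1 principal axes (default 20) and fits a GP with a constant ×
squared-exponential kernel plus white noise, hyperparameters by marginal
likelihood. The supervised CNN shares the encoder backbones with a linear
head and squared-error loss on mean-centred targets, so an untrained
network predicts ≈ the training mean age — a useful sanity floor.

## The phantom generator

The generator emulates the *statistical* structure of registered brain MRE
cohorts, not the physics. Head support is a sphere (radius 15 voxels at the
reference 32³ grid, scaled with the grid). Ten disjoint spherical
subcortical-analogue regions are laid out inside it with voxel counts
ordered like the real anatomy (cerebellum largest → nucleus accumbens
smallest; exact proportionality to published structure volumes is
impossible inside a 32³ sphere and only the ordering is claimed); the
remaining foreground splits into a deep "white matter" core and an outer
"grey matter" shell at 70% of the support radius.

Per subject and channel, in-brain values are

    baseline · (1 + slope/100 · (age_eff − age_ref)) · (1 + b) + ε,

with defaults: stiffness baseline 3.0 (arbitrary units), slope −0.33 %/yr;
damping baseline 0.20, slope +0.34 %/yr; optional T1-like channel baseline
1.0, slope −0.05 %/yr (a deliberately weak ageing signal standing in for
anatomical MRI's lower age sensitivity); ages uniform on [14, 90];
`age_ref` the mid-cohort age (overridable); voxel noise ε ~ N(0, 5% of
baseline) i.i.d.; and one multiplicative offset b ~ N(0, 2%) per subject
*and channel* — independent across channels so that a second channel
carries independent information, which is what makes two-channel fusion
beneficial as in real data. Percent slopes are linear rather than
exponential over the range; at ≤ 0.35 %/yr the difference is negligible and
linear matches the straight trend lines the slopes were read from. Regional
`extra_slope_pct` values add to the global slope inside their region,
enabling single-signal-region constructions for saliency tests.

Disease cohorts are realised as *effective-age shifts*: listed regions are
generated at age + Δ years (defaults: MCI = hippocampus +15 y, AD =
thalamus +30 y, echoing the early-hippocampal / thalamic-AD pattern the
regional analyses target). A `whole_brain` pseudo-region shifts every
voxel; the disease-protocol calibration uses it because a shift confined to
a small region is invisible to a whole-brain model by construction (the
affected voxel share is ~1%), whereas regional models recover regional
shifts. The effective-age parameterisation makes disease detection a
well-posed parameter-recovery problem.

What the phantom does **not** emulate: wave physics and realistic kPa
values, spatial noise correlation, site/scanner batch effects, registration
error, age-dependent heteroscedasticity, and anatomically shaped regions.
Passing tests therefore demonstrate that the algorithms recover the
structure they assume, at desk scale — not that the method attains any
particular accuracy on real MRE cohorts.

## Problem sizes and numerical conventions

Tests and examples run at 8³–32³ grids with 40–300 subjects, 2–15 epochs,
batch 8–16 — sizes chosen so the full suite and the acceptance script each
complete in a few minutes on a single CPU while leaving all qualitative
contrasts (signal vs null, strong vs weak channel, shifted vs unshifted
cohort) decisively detectable. Degenerate inputs fail loudly: constant
images cannot be z-scored, zero-norm embeddings cannot be cosine-compared,
zero-variance groups cannot pass the Shapiro-Wilk gate, empty age bins and
constant saliency maps raise. The loss uses a log-sum-exp stabilisation;
neighbour ranking breaks age ties by subject index so set construction is
deterministic; the 80:20 split is an unstratified seeded shuffle by default
(an age-stratified variant is available behind a flag, since nothing in the
method requires stratification).

## Known limitations

- The numpy networks are CPU-bound and meant for desk-scale grids; the
  architecture is capacity-matched to the phantom, not to full-resolution
  MNI grids.
- Exact rank-test p-values are limited to ≤ 12 per group (beyond that the
  tie-corrected normal approximation is used).
- The GP baseline's kernel hyperparameter search can hit its bounds on
  degenerate toy inputs; bounds are set wide enough for the shipped
  configurations.
- Saliency maps are reported at occlusion-centre resolution; nearest-
  neighbour upsampling to the input grid is for display only.
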