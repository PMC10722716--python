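# Methods

This note documents the models, defaults, numerical choices and known
limitations of the pipeline.  Nothing here states an empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Head model and lead field

The conductor is three concentric spheres (brain/skull/scalp radii
0.87/0.92/1.0 in arbitrary units, conductivities 1 : 1/80 : 1) with
current dipoles of fixed radial orientation.  The scalp potential of a
radial dipole is the Legendre series of the layered Poisson problem: per
harmonic degree *n* the radial profile in each layer is
`A r^n + B r^-(n+1)`; the dipole's primary field enters the innermost
layer, potential and radial current are continuous at both interfaces,
and the radial current vanishes at the scalp.  Sixty series terms are
kept (eccentricities stay below 0.87·0.85, where the series has converged
far beyond test tolerances).  Lead-field columns are average-referenced.

Electrodes sit at ideal 10–20 angular positions on the unit sphere:
the circumferential ring at 72° inclination, Fz/Pz/C3/C4 at 36°, and
F3/F4/P3/P4 as great-circle midpoints of (Fz, F7/F8) and (Pz, T5/T6) —
the geometric reading of the 10–20 construction, since only channel
names are standardized.

A physical subtlety: a radial dipole does **not** vanish as it approaches
the centre of the sphere (the degree-1 term survives), but the radial
direction is undefined exactly at the origin, so the forward model
rejects sources there; tests assert the true symmetry and
depth-attenuation properties instead.

The source grid is a cubic lattice clipped to 85% of the brain radius.
Its resolution is configurable; desk-scale analyses use 50–200 voxels,
with 6239 voxels at 5-mm spacing documented as the full-resolution
reference of the tomography literature.

## Weighted minimum-norm inverse

Depth weights follow the fixed-point iteration
`w_i <- sqrt(k_i' M k_i)` with `M = pinv(K W^-1 K' + αH)`, `H` the
average-reference centering matrix, iterated until the maximum relative
weight change is below 1e-6 (cap 100 iterations, convergence flagged).
`α` is specified relative to the mean Gram diagonal (default 0.05) so the
setting is scale-free; `max_iter = 0` recovers the classical unweighted
minimum-norm estimator, which the tests use as a closed-form oracle.
With `α = 0` the pseudoinverse handles the reference rank deficiency; a
Gram rank below `channels − 1` raises an error advising regularization.
The defining property — argmax of estimated power at the true voxel for
every noiseless point source — is asserted voxel-by-voxel on a 50-voxel
grid.

## Spectrocortical images

Source time series = inverse kernel × scalp.  Spectra are Welch
periodograms (2-s Hann windows, 50% overlap — unexceptional for 5-minute
records).  Band power integrates the density over `[lo, hi)` bins (the
last band closes at its upper edge), so the five bands partition total
2–60 Hz power exactly.  Power is carried under the conventional label
µV²/M⁴/Hz without unit conversion; whether power is integrated before or
after source projection is a free choice and we project first.

## Group ICA and network activities

The group matrix is `subjects × (5·N_voxels)`, band-major.  After
centering across subjects, FastICA (tanh contrast) runs on the whitened
*transpose*, so independence is imposed across the voxel-band dimension:
maps are the sources, subject loadings the mixing coefficients.  This is
identifiable because spatial maps are blob-like (heavy-tailed over
voxels), not because loadings are non-Gaussian.  Components are ordered
by total power (Σ loadings² · ‖map‖²), signs fixed so each map's
largest-magnitude weight is positive.  k defaults to 15.  Artifact
components are a configuration list (visual identification is out of
scope), empty by default.

Projection of a new subject is least squares of the centred image on the
fixed maps — exact for training subjects (the PCA truncation residual is
orthogonal to the retained subspace) and zero for the cohort mean.

Group comparison: pooled-variance two-sample t (MCI − HC) with a
one-tailed label-permutation p, `p = (1 + #{t* ≤ t}) / (n_perm + 1)`,
default 5000 permutations.  A permutation null is this package's declared
choice; the printed t/p pairing in the source literature is inconsistent
with a parametric two-sample null at the published group sizes, and no
attempt is made to reproduce those pairs.

## ERP branch

Epochs span −200…700 ms (450 samples at 500 Hz).  The ERP filter branch
is 0.1–30 Hz.  Artifact correction is infomax ICA (standard, not
extended — adequate for the stereotyped high-amplitude blink and ~5×
faster) on PCA-whitened concatenated epochs; components whose scalp
pattern correlates with a canonical frontal blink template above |r|=0.8
are zeroed.  Rejection windows slide one sample; "activity" is
peak-to-peak range within the window; the rule is evaluated on all 19
channels.  Peak picking is fully automatic: local-extremum search inside
the window with a flagged window-edge fallback, making the conventional
"semi-automatic" step reproducible.  N2 is searched as a local *minimum*
(its amplitudes are negative by definition) even though grand-average
tables conventionally speak of local maxima for both components.

## Statistics

Wilcoxon rank-sum: exact null enumeration when both n ≤ 10 without ties,
else normal approximation with tie and continuity corrections (scipy
backend; an independent full-enumeration oracle in the tests covers every
size pair to 7).  Chi-squared (2×2): Yates correction on by default with
the |O−E|−0.5 deviation floored at zero — this convention reproduces the
published example p-values (0.084, 0.158) from their printed counts to
3 d.p., which the uncorrected statistic does not.  Spearman uses average
ranks; Shapiro–Wilk only annotates reports (downstream tests are always
nonparametric).  Quantiles are type-7 (linear interpolation) throughout.

## Case definition

Global impairment: MMSE < 24 (excluded from both arms).  MCI: any domain
z ≤ −1.5 against age/education-stratified norms (inclusive boundary;
timed tests sign-flipped so higher is always better).  HC: no domain at
or below −1.5 SD.  The alternative reading "HC = below −1.5 SD in *all*
domains" contradicts the MCI rule itself and is not implemented.  The
exact stratification of real normative databases is unpublished, so norm
strata are configuration; synthetic norms equal the generator's HC
marginals.

## Discrimination

Rebalancing: `random_oversample` duplicates minority rows;
`rose_smoothed` / `combined_over_under` draw each output row's class with
probability ½, pick a donor row and perturb it with a diagonal Gaussian
kernel (per-feature Silverman bandwidth × shrink).  The combined mode
keeps total n fixed, so one draw turns 402:47 into roughly balanced
counts.

Composite score: z-score each significant network's loading (training
statistics only), cluster networks by complete linkage on 1 − |Spearman|
cut at 0.5, weight = 1/(cluster size × number of clusters) (weights sum
to 1; correlated networks share weight), align signs so higher = healthy,
and sum.  This construction is the package's own, since "weighted using
cluster analysis" admits many readings.

Cross-validation: Monte-Carlo 5-fold, 100 random partitions.  Metrics
are pooled over the 5 folds within an iteration and averaged over
iterations (another under-determined convention, made explicit here).
Two modes ship: `protocol_faithful` resamples once before CV (duplicated or
kernel-sibling subjects can straddle folds — reproduces the classical
protocol and its optimism) and `leak_safe` (default, recommended)
resamples and builds the composite inside each training split.
Classifiers: RBF-SVM (C = 1, gamma = "scale") and unpenalized logistic
regression, each behind a training-split StandardScaler; confounders for
models 4–6 are age, sex, education.  AUC is the normalized Mann–Whitney
statistic with half credit for ties.

## Synthetic cohorts: what they emulate, and deliberate calibrations

Protocol constants are generated verbatim: 150 trials (50 per condition),
24-trial practice block, 1500-ms ITI, colour→response mapping
(blue→right, red→left, yellow→none), 500 Hz, 19 channels, 900-ms epochs.
RT figures labelled "ms" in the source carry magnitudes like 0.574 and
are treated as seconds.

Resting networks: band-specific maps (round-robin primary band,
stratified spatial blobs with an anticorrelated lobe, unit norm) mixed by
per-subject Gaussian loadings; source series per band are band-limited
Gaussian noise scaled so each voxel's band power hits
baseline + Σ loading·map (floored at 0); scalp = lead field × source +
white sensor noise.  ERP epochs: Gaussian-bump N2/P3 with per-subject
latency/amplitude draws around the published condition × group
grand-average medians, white 2-µV epoch noise, and optional planted
artifacts (step, flatline, frontal blink).  Behaviour: Bernoulli
accuracy per condition, lognormal RTs (within-subject σ 0.13,
between-subject σ 0.08 on the log-median).  Cognition: HC draws clipped
away from the −1.5 SD boundary and MCI draws forced across it, so
generator labels agree with the case-definition rule; volumes are drawn
identically in both groups.

Two desk-scale calibrations are deliberate and documented here rather
than hidden in defaults:

* the default cohort is 40 + 40 subjects (the published 402/47 sizes and
  the published group means/SDs verbatim are available via
  `published_cohort_spec` / `table_network_effects`);
* planted group deficits (network loadings, no-response Cz N2) are sized
  at 0.8 pooled SD, so a 40/40 cohort retains roughly the detection
  power the full-size cohort had; at the published effect sizes a 40/40
  cohort would be underpowered and every recovery test would measure
  sample size, not correctness.

What passing tests therefore show: the pipeline recovers *its own
generative structure* — planted maps, loadings, peaks, labels, effect
directions — with calibrated error rates under the null.  What they do
not show: robustness to real-EEG nuisance structure (1/f background,
non-stationarity, volume-conduction correlations between true networks,
electrode artifacts beyond the planted templates), realistic head
geometry, or transfer of the classifier metrics to any real cohort.

## Problem sizes

Unit tests run on 30–100-voxel grids, 12–80-subject cohorts, and reduced
permutation/iteration counts; the acceptance checks use 200 permutation
replicates, 100 null CV cohorts, 20 network-power and 10–12 ERP-power
replicate cohorts at 40/40.  These sizes are the package's choices for a
single-CPU desk run; every routine scales to larger settings through its
parameters.

## Known limitations

* Spherical geometry and radial-only sources; no realistic MRI-derived
  head model, no anatomical (Brodmann/network-name) labelling of
  components — names like SMN/DAN are generator metadata.
* Artifact-component identification in the group ICA is configuration,
  not computation.
* The EDF writer is minimal (16-bit, 1-s records, zero-padded tail);
  reading goes through MNE, which doubles as the independent check.
* `protocol_faithful` CV intentionally reproduces a leaky protocol; its
  metrics are expected to be optimistic relative to `leak_safe`.
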