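# Methods

This note documents the models, parameter choices and numerical conventions
behind `lffconn`, and what the synthetic validation does and does not show.

## Generative model of a BOLD run

Each rat-session run is a 4D array (x, y, z, t) built voxel-wise as

```
s(v, t) = B + σ ε(v, t) + a(R(v), H(v), c) · L_{R(v)}(t)
          + m (t − T/2) + Σ_k A_k cos(2π f_k t·TR + φ_k)  [+ q((t − T/2)/(T/2))²]
```

* **Baseline** `B = 100` signal units — an arbitrary positive EPI intensity
  so that percent-signal-change is well defined.
* **Noise** `ε` is i.i.d. unit Gaussian per voxel and frame; `σ = 1` sets
  the unit of amplitude.
* **Coupled LFF**: one latent series `L_R` per region (SI, Hp) per run,
  band-limited Gaussian noise on 0.01–0.08 Hz (white spectrum projected
  onto the in-band Fourier bins, standardized to exactly zero mean and unit
  SD). Both hemispheres of a region add the *same* latent at amplitude
  `a(region, hemisphere, condition)`; this is the simplest mechanism that
  produces homotopic synchrony with tunable detection power. Defaults:
  `a = 1.2` everywhere except the right hemisphere on days 1 and 3, where
  `a = 0`; day 9 restores the preoperative amplitude (configurable, since
  the recovery is only "almost normal").
* **Drift**: one linear slope per run, uniform on ±0.01 units/volume
  (≈ ±1.2 units over a 120-volume run, comparable to the signal scale);
  removed exactly by detrending.
* **Physiological components**: global-phase sinusoids at 1.2 Hz
  (respiration, amplitude 0.5) and 4.9 Hz (cardiac, amplitude 0.3),
  evaluated at the sampling times so frequencies above the 0.25 Hz Nyquist
  alias naturally (to 0.2 and 0.1 Hz respectively). The rates sit near the
  species-typical ~1 and ~5 Hz; exactly 1.0/5.0 Hz would alias to DC at
  TR 2 s, a degenerate placement, so the defaults are offset so the aliases
  land above the LFF band — where the low-pass filter removes them, which
  is the standard argument for why such aliases do not masquerade as
  connectivity at these settings.
* **Outlier drift** `q = 5` (units of σ): a quadratic baseline added to all
  runs of one cohort rat when requested, emulating the kind of large
  nonlinear drift that forces a subject's exclusion.
* **Dummy frames**: the first 5 frames additionally carry a decaying
  saturation transient (20% of baseline, τ = 1.5 frames), confined to the
  frames the pipeline discards; it is a stylized stand-in for
  pre-steady-state magnetization.

Whole-cohort generation is a pure function of `(config, seed)`: a
`SeedSequence` spawns one child stream per rat-session plus one for
outlier-rat selection, and every run is written with a JSON ground-truth
sidecar (coupling, drift, physio phases, and the latent series themselves).

### Geometry and atlas

The grid covers a fixed 50 × 41 × 20 mm field of view at any resolution
(96×96×20 native; 48×48×10 and coarser grids carry proportionally larger
voxels), centred at (0, 0, −0.3) mm so the midline x = 0 and the plane
z = −0.3 are voxel boundaries. The toy atlas has four axis-aligned boxes of
5.2 × 4.3 × 3.0 mm (10×10×3 voxels at native resolution; extents are in mm
so the atlas is resolution-independent). The SI and Hp stereotaxic seed
points are < 0.7 mm apart, so boxes centred on both cannot be disjoint: the
SI box extends dorsally from its seed slice and the Hp box ventrally from
its — the cortex-above-hippocampus arrangement — with each box still
containing its seed point. Right-hemisphere boxes are exact voxel mirrors
of the left across x = 0. Seed ROIs (2×2 pixels, one slice) are voxelized
with a floor rule and extend medially from the seed voxel, which makes
negating the X coordinate map to exactly the mirrored voxel set.

## Preprocessing

Fixed order: **drop dummies → smooth → detrend → low-pass.** (The upstream
tooling the design imitates is ambiguous about detrend/filter order; both
are linear projections that commute on their common fixed subspace, and the
fixed order makes results deterministic.)

* **Smoothing**: per-volume Gaussian, FWHM in mm per axis, nearest-edge
  replication at boundaries. The default FWHM of 7.8 mm is interpreted
  under the ×10 rodent-to-human-template voxel-size convention
  (`voxel_scale = 10`), i.e. ≈ 1.5 in-plane voxels. Interpreting 7.8 mm in
  true rat-brain millimetres would smear signal across the ~8 mm gap
  between homotopic SI boxes and manufacture spurious interhemispheric
  correlation — the scaled convention is what rodent studies processed in
  human-template software actually apply.
* **Detrending**: exact least-squares line removal per voxel; output has
  zero temporal mean and the operation is idempotent.
* **Low-pass**: zero-phase *ideal* frequency-domain filter — Fourier
  coefficients with |f| > 0.08 Hz set to zero. Chosen over an IIR design
  because only a cutoff is specified, the filter is then exactly linear,
  zero-phase and idempotent, and the effective-df bandwidth argument below
  becomes exact rather than approximate.

### Outlier-run exclusion

The global (all-voxel-mean) timecourse of the steady-state frames is fit
with a quadratic in normalized time; the score is the quadratic component's
end-of-window amplitude divided by the series SD, and a run is excluded
above `quad_threshold = 1.0`. The criterion is this package's construction
(no quantitative rule is published for "large nonlinear baseline drift"):
a pure linear drift scores ~0 because the quadratic coefficient is fit
jointly with the line, in-band LFF contributes negligibly to a global mean,
and the planted outlier (q = 5σ) scores ≈ 3, so detection is reliable with
no false positives across seeds (asserted over 20 cohorts in the tests).
Exclusion is per rat: any flagged run removes the rat, matching how such
subjects are handled in practice.

## Connectivity statistics

* **Seed reference**: mean of the (preprocessed) ROI voxel timecourses; no
  variance normalization (Pearson r is scale-invariant). A zero-variance
  reference is an error, not a silent zero.
* **Correlation map**: voxel-wise lag-0 Pearson r; voxels with
  zero-variance timecourses are NaN ("undefined"), never 0, and never
  counted.
* **Effective degrees of freedom**: `ν = N·(2 f_c TR) − 2`. The ideal
  filter retains exactly the fraction `2 f_c TR` of the spectrum, so the
  filtered series live in a subspace of ≈ `N·2 f_c TR` real dimensions and
  the Pearson null behaves like a correlation of that many independent
  samples. At N = 120, TR = 2 s, f_c = 0.08 Hz: ν = 36.4 (the exact
  mean-removed in-band subspace has 38 dimensions, i.e. a t with ~37 df —
  the rule's tail error is a few percent, well inside the Monte-Carlo
  bands asserted in the tests: 3 binomial SEs at 10⁵ replicates for
  p ∈ {0.01, 0.001} and at 10⁶ replicates for p = 2.5×10⁻⁵).
* **Threshold**: one-sided positive (the analysis counts *synchronized*
  voxels); two-sided available behind a flag. Ties at `r == r_critical`
  count as significant. `ν < 3` is rejected as a parameter error.
* **Counting masks**: supra-threshold voxels are counted inside the
  anatomical region masks (SI/Hp per hemisphere) rather than whole-brain
  clusters, since per-structure counts are the tabulated quantity; counts
  are normalized per rat by the preoperative count of the same mask, with
  a NaN flag (excluded from means) when the preoperative count is zero.
* **Group maps**: Fisher z per rat, voxel-wise one-sample t against 0
  across rats, one-sided, thresholded at P < 0.001 uncorrected. A
  "one-sample t-test against 1" on r maps is not implementable as printed
  (r = 1 is the boundary of the parameter space); the z-against-0 decision
  is recorded in the run metadata. Zero-between-rat-variance voxels are
  NaN unless identically zero (then t = 0, p = 1).

## Spectra and behavior

Homotopic traces are extracted from smoothed, dummy-free data as ROI means,
converted to percent signal change about the raw temporal mean, then
detrended and filtered (percent change is affine, so correlations are
unchanged by the ordering). Amplitude spectra are one-sided, rectangular
window, with energy-preserving scaling (Σ amplitude² equals the time-domain
energy exactly — Parseval).

Y-maze trials-to-criterion are drawn per session from a rounded,
truncated-at-1 normal at the published means/SDs (27±5 preop, 77±18 day 1,
70±14 day 3). The day-9 value is not published (only that it was not
significantly different from preop, p ≈ 0.4); the default 29 ± 6 reproduces
that behavior at n = 18. The omnibus test is a one-way ANOVA; pairwise
preop-vs-day contrasts are unadjusted two-sample t tests (no adjustment
procedure is published for the starred comparisons).

## Problem sizes used in validation

The validation cohort runs 18 simulated rats × 4 sessions on the 48×48×10
grid (same 50×41×20 mm anatomy, ~2× voxels) with one planted drift rat, so
17 rats are analyzed — the analyzed cohort size of the original design.
This grid preserves every geometric relationship (seeds inside regions,
mirror symmetry, midline separation) at a quarter of the native voxel
count; unit tests use a 24×24×6 version of the same anatomy. The
Monte-Carlo null calibration uses 10⁵ filtered-noise pairs at moderate
tails and 10⁶ at the mapping threshold; outlier-exclusion reliability uses
20 seeded cohorts; behavioral power uses 100 seeded replicates.

## What the synthetic validation does and does not show

Passing tests demonstrate that the *statistical machinery is calibrated*
(the threshold's null exceedance matches nominal p) and that the *pipeline
recovers the designed effect* (normalized counts ≈ 0 where coupling was
abolished, ≈ 1 where it was present or restored, left hemisphere stable,
outlier excluded). They do not validate the neurobiological claims: the
generator has no hemodynamic response function, no spatially structured
(1/f or motion-related) noise, no partial-volume or registration error, no
anatomical variability between rats, and its homotopic coupling is a single
shared latent rather than a network. Real-data effect sizes near the
detection boundary would behave less cleanly than the default a = 1.2
coupling, which is deliberately placed well above threshold to emulate the
all-or-none pattern of the tabulated counts (day-1 normalized counts of
0.01–0.02 against preoperative).

## Known limitations

* Only diagonal (axis-aligned) affines; no registration, slice timing or
  motion correction — synthetic data is generated aligned and motion-free.
* The ideal filter assumes stationary sampling at fixed TR; no support for
  censored/irregular designs.
* The ×10 scaling convention is applied to kernel interpretation only; the
  optional `scale10` read flag changes recorded geometry, not statistics.
* Whether the published ×10 scaling acted on voxel sizes or intensities is
  unstated; both leave correlation statistics unchanged, so the choice here
  (voxel sizes) is cosmetic and documented rather than inferred.
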