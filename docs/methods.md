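# Methods

## Phantom model

The left ventricle is a half-ellipsoid shell: hemispheric apex, open base,
long axis along the slice axis (slice 0 = apex).  End-diastolic cavity
semi-axes (a, c) follow from the requested cavity volume V = (2/3)·π·a²·c
with a fixed long-to-short axis ratio (default 2.0).  The base plane is
snapped to a slice boundary so the most basal wall slice is fully covered.

Per frame k (cycle angle θ_k at the midpoint of bin [k, k+1)·360/N — gating
integrates over a bin), each AHA segment's wall thickness is

    w_s(θ) = wall_mm_ed + thickening_mm · (1 − cos(θ − delay_s)) / 2,

so thickness peaks at 180° + delay_s; that angle is the ground-truth time to
end-systole.  Cavity volume follows the canonical fundamental drive
V(θ) = EDV·(1 − EF·(1 − cos θ)/2), hitting the EF target exactly at θ = 180°.
The drive deliberately ignores the segmental delays: delays model *regional
thickening timing* in the small-delay regime of a normal database, and
keeping the volume curve delay-independent prevents global cavity motion
from leaking a second phase reference into regional curves (the order-2 TES
argmax sits on a flattened peak and amplifies sub-percent waveform
perturbations roughly eighteen-fold).  Only the in-plane semi-axis is scaled
per frame, a(θ) = a·√(V(θ)/EDV); the long axis and base stay fixed.

Rasterization uses a first-order analytic signed distance to the endocardial
surface, d = (q − 1)/|∇q| with q = √((ρ/a)² + (u/c)²); the shell is the band
0 < d < w with half-pixel anti-aliased edges.  An analytic distance (rather
than a binary mask plus a distance transform) keeps the shell smooth in the
frame parameter, so the noise-free phantom carries no voxelization phase
jitter.  Activity is a uniform concentration in the shell, weighted by
per-segment uptake; apparent counts arise *only* by Gaussian blurring
(default FWHM 12 mm) — the partial-volume mechanism — after which the stack
is scaled so the noise-free maximum equals `max_counts` (default 123) and,
optionally, Poisson-sampled.  Computation is restricted to a bounding crop
around the heart.

Key parameters (units, default, rationale):

| parameter | default | meaning |
|---|---|---|
| matrix_size / pixel_mm | 64 / 6.4 mm | acquisition matrix of resting normal databases; pixel size an explicit assumption (configurable) |
| n_slices / slice_mm | 24 / 6.4 mm | stated assumption; fits a ~150 mm field |
| n_frames | 16 | frames per cardiac cycle in the emulated databases |
| edv_ml / ef_true | 74.7 mL / 0.69 | pooled normal-database means |
| wall_mm_ed / thickening_mm | 10 / 5 mm | normal end-diastolic thickness and systolic thickening |
| psf_fwhm_mm | 12 mm | reconstructed SPECT resolution |
| max_counts | 123 | maximum myocardial counts/pixel in the emulated databases |
| delay_deg / uptake | 0 / 1 per segment | ground-truth dyssynchrony and perfusion knobs |

## Cohort generator

Per-sex EDV and EF are drawn from truncated normals with normal-database
statistics (36 males: EDV 84.4 ± 15.7 mL, EF 66.5 ± 6.1%; 33 females:
64.1 ± 12.1 mL, 72.0 ± 5.7%).  Segmental delays are jittered with SD 5°
(a small physiologic heterogeneity; normal subjects are nearly synchronous).
Two physiologic couplings close the loop to the observed metric dependences:

- **counts_scaling** (default on): maximum counts scale inversely with
  myocardial shell volume, normalized to 123 at the cohort mean — larger
  hearts spread the same injected activity over more tissue.  This is the
  count-statistics mechanism for the sex difference in phase metrics; there
  is *no* intrinsic sex term in contraction timing, and setting
  `counts_scaling="none"` tests the null.
- **thickening ∝ EF**: per-subject thickening is scaled by EF/0.69, the
  physiologic coupling of systolic thickening to global function.  Lower-EF
  subjects then have lower TAC amplitude, hence noisier phases.

## Measurement pipeline

Sampling: per-slice count-weighted centroids (smoothed along the axis),
36 radial rays per slice, sample value = maximum interpolated count within a
±20 mm annulus centred on the ray's peak radius in the time-mean image (the
polar-map convention; a mean-count mode exists for sensitivity analysis).
Angle 0° is the anterior wall, increasing counter-clockwise viewed from the
apex.  The automatic base cut removes basal-zone slices whose mean sample
amplitude falls below half the mid-ventricular mean (never more than 40% of
slices); a manual mode removes named slices.  Optional phase-map smoothing
is a circular-aware Gaussian on the (slice, angle) grid.

Harmonics: order-1/2 cosine-series fits are computed as DFT coefficients
(the least-squares solution on uniform frames); amplitudes are reported
nonnegative with phases in [0, 360).  A sample's phase counts as defined
only when a₁ exceeds 2% of a₀ (configurable) — an explicit version of the
silent exclusion of non-contracting samples.  TES is the argmax of the
order-2 fitted curve on a 0.1° grid with local quadratic refinement; ties
resolve to the smaller angle.

Metrics: PSD recenters the samples so their circular mean sits at 180°
before taking the population SD (a flag disables recentring for emulation
studies).  Bandwidth is the shortest circular arc covering 95% of samples,
swept over sorted positions; a tail-trimming alternative is provided since
vendor definitions differ.  Below 20 samples the 95% notion is ill-defined
and the full-coverage arc is returned with a warning.  Entropy is histogram
entropy (1° bins by default) normalized by log(n_bins), with 0·log 0 = 0;
the summation carries the minus sign needed for the documented 0–1
order-to-disorder range.  TES statistics rotate the 17 values to a 180°
circular mean before max − min / SD / lateral-minus-septal differences
(all divided by 360° and reported in %); lateral = segments {5, 6, 11, 12},
septal = {2, 3, 8, 9}, an explicit overridable mapping.  Normal limits are
mean ± 2·sample SD (ddof = 1), unrounded; PSD/SDTES use the population SD
(descriptors of a fixed sample set).

Volumes/EF: a deliberately simple threshold estimator stands in for the four
proprietary edge-detection algorithms.  Per frame, slice and angle the
endocardial radius is the innermost sub-pixel crossing of a threshold set at
one third of the cavity-floor-to-peak count range; referencing the floor
(rather than the peak alone) keeps small blur-filled end-systolic cavities
from collapsing to zero radius, and the 1/3 level was calibrated once on
noise-free phantoms of known volume (EF errors ≤ 3 points over EF 0.40–0.80;
absolute volumes remain biased low, as expected from so coarse a boundary
model).  Cohort analyses can bypass the estimator entirely
(`volumes="truth"`) so dyssynchrony-versus-volume relations are not
confounded by estimator error.

Statistics: sex contrasts use one-way ANOVA (two groups ≡ t test); subgroup
contrasts use the rank-sum (Wilcoxon/Mann–Whitney) test, exact by
enumeration when both groups have ≤ 10 untied values, otherwise the
tie-corrected normal approximation; correlations are Pearson r with 95%
Fisher-z intervals; regressions are ordinary least squares.  The
volume-matched contrast compares males below the male median EDV with
females at or above the female median, reporting the EDV balance check
first.

## What the generator does and does not emulate

It reproduces the acquisition envelope (frames, matrix, count level), the
thickening-to-counts mechanism, per-segment timing and uptake control,
heart-size count statistics, and sex-structured volume/EF distributions.
It does **not** simulate projection/reconstruction (FBP streaks, attenuation,
scatter), longitudinal shortening or valve-plane descent, right-ventricular
or extracardiac activity, perfusion defects beyond uniform segment scaling,
or gating errors.  Passing tests therefore show that the *measurement chain*
is correct and that count statistics alone reproduce the directional
sex/volume/EF dependences; they do not certify behaviour on real
reconstructed images, and absolute metric values are not comparable across
software implementations.

## Numerical and design notes

- Phase convention: peak-of-counts (end-systole) phase of the positive-
  amplitude cosine.  All histogram metrics are invariant under a global
  phase rotation, so the choice of onset versus peak does not affect them.
- Frame-midpoint sampling shifts all fitted phases by half a frame
  (−11.25° at 16 frames); differences and spreads are unaffected.
- Problem sizes: recovery tests use single default-geometry phantoms; the
  directional replication uses 20 seeded cohorts of 69 subjects, the sizes
  of the emulated study design.
- Degenerate inputs: constant TACs carry an undefined-phase flag and are
  excluded from histograms rather than raising; all-zero slices are dropped
  by the centroid finder; empty phase lists, mixed table schemas, negative
  kernels and out-of-range specs raise validation errors.
- Determinism: every stochastic step flows from one integer seed through
  `numpy.random.default_rng`; equal seeds give byte-identical studies.

## Known limitations

- Absolute EDV/ESV are underestimated by the threshold boundary model; only
  EF and orderings are validated.  Real programs disagree on absolute
  volumes for the same reason in kind.
- At very wide PSFs relative to cavity size, myocardial-compaction signal
  mixes into the thickening signal; partial-volume monotonicity holds in
  the quasi-static regime.
- The apical-cap segment is measured from the single most apical usable
  slice and is the least reliable TES entry, mirroring clinical practice.
- Entropy depends on bin width (1° default); comparisons require a fixed
  binning convention.
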