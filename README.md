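# spectsync

Phase-dyssynchrony analysis for ECG-gated myocardial perfusion SPECT, with a
synthetic gated phantom and a cohort-statistics stage.

In gated MPI the apparent counts of the left-ventricular wall track wall
thickness through the partial-volume effect, so a regional time–activity
curve (TAC) rises and falls with thickening over the cardiac cycle.  Fitting
the fundamental Fourier harmonic

v(k) = a₀ + a₁·cos(2πk/N − φ₁),  k = 0 … N−1 frames,

assigns each myocardial sample a **phase** φ₁ (degrees of the cycle at which
its counts peak, i.e. regional end-systole).  The distribution of phases over
the ventricle quantifies mechanical dyssynchrony:

- **PSD** — wrap-safe standard deviation of the phase distribution (°),
- **95% bandwidth** — shortest circular arc holding 95% of the samples (°),
- **entropy** — normalized histogram entropy, E = −Σ fᵢ·log fᵢ / log n ∈ [0, 1]
  (0 = complete order, 1 = complete disorder; reported in %),
- **TES family** — per AHA-segment time to end-systole from a fundamental +
  second-harmonic fit, summarized as the maximum difference (MDTES), SD
  (SDTES) and lateral-minus-septal contrast (DTES-LS), each in % of the cycle.

Because normal-database images are not redistributable, the package ships a
first-class phantom: a half-ellipsoid LV shell with per-segment contraction
delays and uptake, rasterized, blurred by a Gaussian PSF and Poisson-sampled
under a realistic acquisition envelope (16 frames, 64×64 matrices, maximum
myocardial counts ≈ 123/pixel).  Ground truth (volumes, EF, per-segment
timing) is known analytically, so phase recovery, a threshold EF estimator,
and cohort-level statistics (sex contrasts, EDV/EF regressions, normal
limits, volume-matched subgroups) can all be validated end to end.

Intended users: researchers studying dyssynchrony metrics and their
dependence on acquisition statistics, and anyone needing a controllable
gated-SPECT test bench.

## Worked example

```python
import spectsync as ss

study = ss.generate_study(ss.PhantomSpec(seed=11))   # Poisson-noisy default
res = ss.analyze_study(study, ss.PipelineConfig())
print(f"PSD        {res.psd_deg:.2f} deg")
print(f"bandwidth  {res.bandwidth_deg:.2f} deg")
print(f"entropy    {res.entropy_pct:.2f} %")
print(f"DTES-LS    {res.dtes_ls_pct:.2f} %   EF {res.ef_pct:.1f} %")
```

prints

```
PSD        9.31 deg
bandwidth  36.91 deg
entropy    60.38 %
DTES-LS    2.70 %   EF 70.1 %
```

All 396 accepted samples share the true contraction timing, so the spread
here is pure count-statistics noise: a PSD near 9°, a 95% bandwidth near 37°
and a mid-scale entropy are what Poisson noise alone produces at ~123 max
counts/pixel — the mechanism by which larger (count-poorer) hearts score
"more dyssynchronous" on these indices.  The EF of 70.1% recovers the
phantom's true 69%.

The same pipeline runs from the shell:

```
spectsync simulate --config spec.json --out study.nii.gz --seed 1
spectsync analyze --study study.nii.gz --outdir out/
spectsync cohort run --outdir cohort/          # 36 M / 33 F default cohort
spectsync report --table cohort/subjects.csv
spectsync config show-defaults
```

Studies are 4-D NIfTI (x, y, slice, frame) with a JSON sidecar carrying
pixel size, slice thickness and frame timing; tables are plain CSV.

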