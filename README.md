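# geldose

3D polymer-gel dosimetry analysis for radiotherapy dose verification,
built around a fully synthetic, testable reproduction of a breast-phantom
experiment: a MAGIC-f gel phantom with a tissue-expander **metal port**
is irradiated with two opposed 6 MV tangential beams, read out by
multi-echo MRI, and the measured 3D dose is compared with the planned
distribution to quantify the underdose cast in the port's beam shadow.

## Who this is for

Medical physicists and methods researchers who want a tested, end-to-end
reference implementation of the gel-dosimetry analysis chain — R2
relaxometry, calibration, registration, gamma analysis, profile
statistics — together with a phantom/scanner simulator that generates
every input, so each stage can be validated against known ground truth
without scanner data.

## The analysis chain

1. **Relaxometry** — each voxel of the 4D multi-echo magnitude volume
   (8 echoes, TE = 35, 70, …, 280 ms) is fitted with the
   mono-exponential decay S(TE) = S₀·exp(−R2·TE) by signal-weighted
   least squares on log S (weights S², the near-ML estimator at high
   SNR), with optional Rician noise-floor subtraction
   S ← √max(S² − 2σ², 0).
2. **Bias correction** — a second, uniform gel phantom is scanned under
   the same conditions; its smoothed R2 map, normalized to unit mean, is
   divided out of the measurement.
3. **Calibration** — nine vials at 0.5–4.5 Gy give a linear response
   R2(D) = R2₀ + α·D, fitted by inverse-variance WLS, with diagnostics:
   Pearson r, mean dose uncertainty (mean of σ_D/D), and dose resolution
   D<sub>Δp</sub> = k_p·√2·σ_D.
4. **Dose reconstruction** — D = (R2 − R2₀)/α, rigid registration into
   the planned frame from fiducial points (orthogonal Procrustes), and
   normalization of each distribution to its own robust maximum (%).
5. **Gamma analysis** — 3D global gamma (3% / 3 mm, 10% low-dose
   threshold) with a radially-sorted early-terminating search,
   per-slice pass-rate profiles, and connected-component fail maps.
6. **Profile statistics** — matched dose profiles through the slice
   containing the port and its mirror-image port-free slice; the
   pointwise deficit 100·(planned − measured)/planned over the shadow
   region, and the pairwise difference of with/without-metal deficits:
   the **metal-attributed dose reduction**.

The simulator (`geldose.phantom_sim`) provides the ground truth: a
hemiellipsoidal gel shell (0.282 L fill) over a water-filled inner dome
carrying a 17.9 mm × 3.9 mm metal disk, an analytic two-beam planned
dose normalized to 3 Gy at the isocenter, a delivered dose with a ~4.5%
near-wall polymerization deficit and a 9.8% total deficit in the port
shadow, Rician-noise echo volumes with a smooth scanner bias field, and
calibration vials whose noise level reproduces a 3.0% mean dose
uncertainty.

## Worked example

```python
from geldose.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1), out_dir="run1", make_figures=True)
p = report.summary["profiles"]
print(f"calibration r      : {report.summary['calibration']['pearson_r']:.4f}")
print(f"mean uncertainty   : {report.summary['calibration']['mean_uncertainty_pct']:.2f} %")
print(f"with-metal deficit : {p['with_metal_horizontal_pct'][0]:.2f} %")
print(f"no-metal deficit   : {p['without_metal_horizontal_pct'][0]:.2f} %")
print(f"metal-attributed   : {p['metal_attributed_reduction_pct']:.2f} %")
print(f"gamma pass overall : {report.summary['gamma']['pass_rate_overall_pct']:.1f} %")
```

prints (seed 1):

```
calibration r      : 1.0000
mean uncertainty   : 3.03 %
with-metal deficit : 10.31 %
no-metal deficit   : 5.24 %
metal-attributed   : 4.29 %
gamma pass overall : 99.6 %
```

The with-metal profile reads ~10% below the plan inside the port shadow
while its mirror-matched port-free profile sits at the ~5% near-wall
baseline; their difference is the dose reduction attributable to the
metal port alone (single seeds scatter around the 5.3% seed-averaged
value — see below).  The per-slice gamma pass-rate profile dips over the
slices containing the port; `run1/` holds the volumes, tables and
figures (calibration curve, slice maps, pass-rate profile, profile
overlays).

The same stages are scriptable from the shell:

```bash
geldose simulate --out sim/ --seed 1
geldose run --out run1/ --seed 1
geldose gamma --ref planned.nii.gz --eval measured.nii.gz --dd 3 --dta 3 \
    --threshold 10 --out gamma.nii.gz --rates rates.csv
```

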