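# tracerflow

Does a tracer injected into brain tissue spread faster than diffusion can
explain? `tracerflow` is a quantitative transport-analysis pipeline for
serial contrast-enhanced MRI that answers this question, the central test
of the *glymphatic* hypothesis that cerebrospinal fluid is driven through
the brain's interstitial and perivascular spaces by convective bulk flow.

The package compares two independent estimates of a high molecular-weight
tracer's mobility in a region of interest:

1. **Boundary-propagation pseudo-ADC (ADC\*).** Serial T1-weighted volumes
   are segmented inside a manual ROI with Otsu's threshold; the tracer
   region's surface is extracted at each timepoint, and every surface point
   contributes

   ADC\* = dist² / (2 · d · t),  d = 3,

   where *dist* is the distance (mm) to the closest point of the next
   surface and *t* the elapsed time (ms). ADC\* responds to diffusion
   **plus** any convective bulk flow.

2. **Tortuosity-scaled DTI prediction.** A diffusion tensor is fit voxelwise
   by log-linear least squares (b-value in s/mm², ≥ 6 unit gradient
   directions), scalar maps FA, ADC, D<sub>axi</sub> = λ₁ and
   D<sub>rad</sub> = (λ₂+λ₃)/2 are derived from the sorted eigenvalues, and
   the region's water ADC is converted to the tracer's purely diffusive ADC
   through the tortuosity relation λ² = D_free/ADC, assuming the tracer
   shares water's tortuosity:
   ADC_tracer = ADC_water · (D_albumin / D_water) ≈ ADC_water · 0.0276.
   This prediction responds to diffusion **only**.

A pooled-variance two-sample t-test and a symmetric percent difference,
100·(a−b)/((a+b)/2), compare the two across subjects per region; ADC\*
significantly exceeding the diffusive prediction is evidence of bulk flow.

Because no in-vivo data are distributed, a synthetic advection–diffusion
phantom with known ground truth (isotropic "striatum" ball, anisotropic
"callosum" slab, point-like infusion source, optional velocity field,
T1-like and Rician-noise DW imaging models) exercises the pipeline end to
end. See `docs/methods.md` for the model, parameter defaults, and known
limitations of the ADC\* estimator.

## Worked example

```python
from tracerflow import run_pipeline

results = run_pipeline({"mode": "phantom", "n_subjects": 5, "base_seed": 10})
for region, r in results.items():
    g = r["group"]
    print(f"{region}: ADC* {g.mean_adcstar:.3e} vs scaled {g.mean_adc_dti:.3e}"
          f" mm^2/ms, pct_diff {g.pct_difference:.1f}%, p {g.p_value:.4f}")
```

prints (default study: bulk flow at 0.1 mm/min in the striatum experiment,
none in the callosum experiment):

```
striatum: ADC* 2.545e-08 vs scaled 1.717e-08 mm^2/ms, pct_diff 38.9%, p 0.0004
callosum: ADC* 2.231e-09 vs scaled 1.975e-08 mm^2/ms, pct_diff -159.4%, p 0.0000
```

In the region with convective flow the measured ADC\* significantly exceeds
the diffusion-only prediction — the bulk-flow signature. In the flow-free
region ADC\* falls *below* the prediction: the boundary of a purely
diffusing blob advances only as √t, so the contour-based ADC\* understates
true diffusivity at these scan times (quantified in `docs/methods.md`);
the detection contrast is therefore conservative.

The same stages are available from the shell:

```bash
tracerflow simulate --out phantom/            # volumes, masks, manifests
tracerflow segment  --volume phantom/t1_24min.nii.gz \
                    --roi phantom/roi_striatum.nii.gz --out mask.nii.gz
tracerflow adcstar  --manifest phantom/series.csv \
                    --roi phantom/roi_striatum.nii.gz --out adcstar.json
tracerflow dti      --manifest phantom/dwi.csv --out maps/ \
                    --roi phantom/roi_striatum.nii.gz
tracerflow scale    --adc-water maps/adc_roi.json --out scaled.json
tracerflow compare  --config study.yaml --out report/
```

Real data enter through the same interfaces: NIfTI volumes with a CSV
manifest `path,time_min` (minutes post infusion-end), {0,1} NIfTI ROI
masks, and a DWI manifest `path,bval,gx,gy,gz` with one `bval = 0` row.
Volumes are assumed co-registered.

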