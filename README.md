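# relaxmap

Quantitative-MRI relaxometry for ex vivo bladder tissue: pixel-wise T1/T2
mapping, digital tissue phantoms, ROI relaxation indices, three-group
statistics, and photodynamic-therapy (PDT) light dosimetry.

## The problem

Non-muscle-invasive bladder cancer (NMIBC) recurs frequently, and 5-ALA
photodynamic therapy is a candidate organ-sparing treatment whose tissue
response needs an objective, non-invasive readout. T1 and T2 relaxation
times measured on a clinical 1.5 T scanner change markedly between healthy
bladder tissue, untreated NMIBC, and NMIBC after 5-ALA-PDT, which makes
quantitative relaxometry a candidate therapy-response biomarker. This
package implements the full analysis chain for that study design:

1. **simulate** — digital tissue phantoms with known per-region T1/T2 are
   forward-modelled into multi-TR / multi-TE fast-spin-echo magnitude
   series and corrupted with Rician noise (patient DICOMs for such studies
   are typically not shareable, so the synthetic cohort is the test
   surface; real DICOM/NIfTI series are read too);
2. **fit** — every foreground pixel is fitted with a three-parameter
   relaxation model, giving T1 or T2 maps plus per-pixel R² quality maps;
3. **roi** — the mean relaxation time over a segmented region of interest
   is each sample's T1/T2 index;
4. **stats** — one-way ANOVA across the three groups with Tukey HSD (or
   Bonferroni) post hoc pairs, a summary-statistics ANOVA oracle, and a
   paired pre-/post-PDT test;
5. **dose** — irradiance and fluence of the PDT light delivery.

## Models

Variable-TR saturation recovery (12 TRs from 50 to 15,000 ms, TE = 3 ms):

    S(TR) = a · (1 − b · e^(−TR/T1))

with amplitude `a`, recovery fraction `b`, and longitudinal relaxation time
T1. Variable-TE decay (11 TEs from 10 to 260 ms, TR = 10,000 ms):

    S(TE) = a · e^(−TE/T2) + c

with baseline `c` absorbing the magnitude noise floor. Both are fitted per
pixel by bounded trust-region nonlinear least squares with deterministic
initialisation; R² = 1 − SS_res/SS_tot flags fit quality.

Light dose: irradiance = P/A (mW/cm²), fluence = P/A · t / 1000 (J/cm²).

## Worked example

Noiseless recovery of a healthy-tissue T1 on the default protocol grid:

```python
from relaxmap import (T1ModelParams, default_acquisition_grids,
                      fit_t1_pixel, t1_signal)

t1_grid, _ = default_acquisition_grids()
signals = t1_signal(t1_grid.variable_ms, T1ModelParams(1000.0, 1.0, 1351.7))
res = fit_t1_pixel(signals, t1_grid)
print(round(res.params.t1_ms, 4), res.converged)   # 1351.7 True
```

Full synthetic cohort (25 samples per group, 64 × 64 phantoms, Rician
noise at SNR 50):

```python
from relaxmap import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(output_dir="scratch/run", seed=7))
a = result.stats["t1_index_ms"]["anova"]
print(f"T1: F({a['df_between']}, {a['df_within']}) = {a['f_stat']:.1f}, "
      f"p = {a['p_value']:.2g}")
# T1: F(2, 72) = 236.8, p = 2.2e-32
```

All three Tukey pairs (healthy vs NMIBC, healthy vs NMIBC_PDT, NMIBC vs
NMIBC_PDT) come out significant at p < 0.001, and the group means order as
healthy > NMIBC > NMIBC_PDT for both T1 and T2 — the treatment-response
signature the index is meant to detect. The run directory contains
`cohort.csv` (per-sample indices), `stats.json` (ANOVA, post hoc, Levene,
paired PDT delta), box-plot figures, a JSON-lines log, the resolved config
and a checksummed manifest.

The same chain is scriptable from the shell:

```bash
relaxmap dose --power-mw 350 --area-cm2 6.25 --duration-s 600
# irradiance: 56 mW/cm^2
# fluence:    33.6 J/cm^2
relaxmap run --out scratch/run --seed 7
```

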