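# qmapsynth

Synthetic T1rho maps from T2 maps for quantitative knee MRI — phantom
simulation, mono-exponential relaxometry, U-Net map synthesis with a
cartilage-weighted loss, and Bland–Altman agreement analysis.

## The problem

T1rho relaxation of knee cartilage tracks proteoglycan loss and is a
promising quantitative biomarker for early osteoarthritis, but the
acquisition is slow and rarely part of clinical protocols.  T2 mapping is
widely available.  If T1rho maps can be synthesized from T2 maps with
compartment-level quantitative fidelity, existing T2-only datasets gain a
biomarker and protocols shrink by roughly half the mapping time.  This
package implements that synthesis pipeline end to end and — equally
important — the agreement analysis that decides whether the synthetic maps
are quantitatively trustworthy, including under acquisition shift
(different coil or scanner).

It is aimed at researchers in quantitative musculoskeletal MRI who want a
tested, seedable reference implementation to experiment with at desk scale
(synthetic phantoms) or to apply to their own NIfTI map data.

## What it computes

**Relaxometry.**  Voxelwise mono-exponential fits
`S(t) = S0 · exp(−t/T)` of multi-echo series (spin-lock times TSL
0/10/40/80 ms for T1rho; T2-preparation times TE 0/12.9/25.7/51.4 ms) by
vectorized Levenberg–Marquardt with log-linear initialization, bound
clamping, convergence flags and optional background suppression.

**Synthesis.**  A 2D U-Net (ReLU, batch norm, skip connections; pure-numpy
implementation with verified analytic gradients) maps T2 slices clipped to
[0, 150] ms to T1rho slices, trained with the region-weighted objective

    loss = 1.5 · MSE(cartilage) + MAE(rest of slice)

under a strictly subject-wise 65:15:20 split, early stopping, 4-fold
cross-validation and grid hyperparameter search.

**Evaluation.**  NMSE (`100·Σ(ŷ−y)²/Σy²`), PSNR (range 150 ms), Gaussian
SSIM, and Pearson r per region (whole volume, cartilage, and the MF / LF /
MT / LT / PAT / TRO compartments); Bland–Altman bias and 1.96·SD limits of
agreement of compartment means; and the quantification-error rate judged
against the 6.42 % clinically-significant-change threshold.

**Phantoms.**  A generator for stylized knee subjects with six labelled
cartilage compartments, tissue-realistic (T1rho, T2) statistics in which
T1rho is a learnable function of (T2, compartment), focal OA-like lesions
that carry T1rho-excess contrast, mono-exponential echo simulation, and a
domain-shift operator (coil bias field, SNR scaling, relaxation-time
offset).  See `docs/methods.md` for the model and its limits.

## Worked example

```python
import qmapsynth as q

cfg = q.RunConfig(
    domain_shift=q.DomainShiftSpec(bias_field_amplitude=0.10,  # 10% coil field
                                   snr_scale=2.0,              # SNR halved
                                   global_offset_ms=3.0,       # T1rho offset
                                   seed=77),
    seed=1,
)
result = q.run_pipeline(cfg, "runs/demo")
for stratum, ag in result["agreement"].items():
    print(stratum, round(ag["bias_ms"], 2), "ms bias,",
          round(ag["quantification_error_pct"], 1), "% qerr,",
          "r=", round(ag["pearson_r"], 3))
```

This simulates 30 phantom subjects (8 slices of 64×64), fits their T1rho
and T2 maps from noisy echoes, trains the tiny U-Net preset on 20 training
subjects, and evaluates the 6 held-out subjects twice — as acquired, and
after the domain-shift corruption.  On one CPU core it takes a few
minutes and prints:

```
in_distribution -0.91 ms bias, 2.6 % qerr, r= 0.948
shifted -3.98 ms bias, 8.7 % qerr, r= 0.947
```

Reading: in distribution, synthetic T1rho compartment means track the
ground truth closely (r ≈ 0.95), with sub-millisecond bias and a
quantification error well inside the 6.42 % clinical threshold — mean
held-out cartilage NMSE is ≈ 0.31 %.  Under the simulated coil/scanner
change the maps stay visually faithful (cartilage NMSE rises to ≈ 1.0 %)
but the bias grows fourfold and the quantification error crosses the
clinical threshold: the synthesis is quantitatively stale for the new
acquisition.  That asymmetry — images fine, numbers not — is exactly the
failure mode the stratified agreement analysis exists to expose.

The same stages are available as a CLI:

```bash
qmapsynth simulate --config cfg.yaml --out cohort/
qmapsynth fit --echoes cohort/S001_echoes_t2.nii --out S001_t2.nii
qmapsynth run --config cfg.yaml --out runs/demo
qmapsynth evaluate --pred-dir pred/ --truth-dir truth/ --labels-dir labels/ --out eval/
```

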