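# washsem

Accelerated dynamic gas wash-out lung MRI analysis: digital phantoms,
retrospective Cartesian under-sampling, joint compressed-sensing
reconstruction with a stretched-exponential signal prior, and regional
fractional-ventilation mapping.

## The problem

Dynamic inhaled-gas MRI (hyperpolarized ³He/¹²⁹Xe or thermally polarized
fluorinated gases) maps regional **fractional ventilation** — the fraction
`r` of a lung voxel's gas replaced per breath — from a series of images
acquired over successive wash-out breaths.  Fluorinated-gas imaging is
cheap and repeatable but SNR-starved, so acquisitions must be accelerated
by under-sampling k-space; at acceleration factors (AF) of 10–14 only 5–7
of 64 phase-encode lines per image survive, and per-frame reconstruction
collapses.  The remedy studied here is to reconstruct the *whole breath
series jointly*, using the known monotone decay of the signal — the
stretched-exponential model (SEM) — as prior knowledge, and then to
estimate ventilation two ways:

* the classical two-parameter fit `S(n) = S0 (1 − r)^n`;
* the SEM fit `S(n) = S0 exp(−(n r′)^β)`, whose heterogeneity index
  `β ∈ (0, 1]` encodes a distribution of underlying turnover rates.
  Inverting the Laplace-type relation `S(n)/S0 = ∫₀¹ P(r) e^(−nr) dr`
  turns each fitted `(r′, β)` into a rate density `P(r)`, whose
  expectation **rSEM** is the SEM-based mean fractional ventilation.

The package is aimed at pulmonary-MRI methods researchers who want a
self-contained, testable implementation: every stage runs on synthetic
phantoms with known ground truth (real animal data for this protocol are
not redistributable), and user data can be supplied as NIfTI stacks (one
volume per breath) with a binary lung mask.

## Worked example

```python
import washsem as w

# ¹⁹F-like phantom: 64×64, baseline + 9 wash-out breaths, SNR 20
truth = w.make_phantom_truth(r_mean=0.2, r_sd=0.02, beta_mean=0.9,
                             beta_sd=0.02, snr=20.0, n_images=10,
                             gas="F19", seed=1)
series = w.simulate_washout(truth, model="sem")
print("empirical SNR:", round(w.snr_estimate(series.frames[0], truth.lung_mask), 1))

# retrospective AF = 14 under-sampling: 5 of 64 lines, varying per breath
mask = w.make_sampling_mask(10, 64, af=14, scheme="fgre", seed=1)
ksp = w.apply_mask(w.forward_kspace(series), mask)
recon = w.cs_sem_recon(ksp, mask)         # joint CS + SEM reconstruction

den = w.fit_deninger(recon, truth.lung_mask)
sem = w.add_rsem(w.fit_sem(recon, truth.lung_mask))
for name, arr in [("r", den.r_map), ("r'", sem.rprime_map),
                  ("beta", sem.beta_map), ("rSEM", sem.rsem_map)]:
    m, s = w.summarize_map(arr, truth.lung_mask)
    print(f"{name:5s} mean (SD): {m:.3f} ({s:.3f})")
rep = w.absolute_difference(den.r_map, sem.rsem_map, truth.lung_mask)
print(f"mean |r - rSEM| / r: {rep.mean_abs_diff_pct:.1f}% over {rep.n_voxels} voxels")
```

prints

```
empirical SNR: 19.9
r     mean (SD): 0.152 (0.023)
r'    mean (SD): 0.168 (0.033)
beta  mean (SD): 0.934 (0.090)
rSEM  mean (SD): 0.190 (0.055)
mean |r - rSEM| / r: 23.1% over 1112 voxels
```

Reading the numbers: at AF = 14 the joint reconstruction smooths the decay
curves, so both ventilation estimates land below the generating `r′ = 0.2`;
the two-parameter `r` sits lowest, `r′` in between, and `rSEM` highest —
the ordering `r < r′ < rSEM` is structural whenever `β < 1`, because the
rate density carries a heavy high-rate tail.  The pixelwise `r`-vs-`rSEM`
difference is dominated by that ordering, and shrinks toward ~10% as the
fitted `β` approaches 1 (mono-exponential decay).

The rate-density machinery is also available directly:

```python
d = w.eval_density(0.24, 0.90)   # calibrates B, C against the Laplace relation
print(f"B={d.B:.3f} C={d.C:.3f} maxdev={d.max_laplace_dev:.4f} "
      f"rsem={d.expectation():.3f}")
# B=0.615 C=0.541 maxdev=0.0073 rsem=0.278
```

A CLI mirrors the library: `washsem {phantom, undersample, recon, fit,
pdensity, compare, experiment}` (see `washsem --help`).

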