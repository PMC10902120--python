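# desst2

Quantitative T2 mapping of peripheral nerves and muscles from the
double echo steady state (DESS) sequence, with the statistical toolchain
used to study nerve and muscle denervation.

## The problem

Peripheral neuropathy and the muscle denervation that follows axonal
injury elevate tissue T2. 3D-DESS acquires two echoes per TR — a FID-like
echo S+ and a more heavily T2-weighted echo S− — at high isotropic-plane
resolution (0.3 × 0.3 × 1.6 mm), so a T2 map and the anatomical
neurography images come from a single acquisition with no registration
step. The echo ratio carries the T2 information:

    S− / S+ ≈ exp( −2 (TR − TE) / T2 )

Inverting this gives an *approximate* T2 that slightly underestimates the
T2 implied by the full steady-state signal equations. The package builds a
dictionary over a T2 grid from 3 to 300 ms in 0.1 ms steps (2,971
entries), computed from the closed-form SSFP-FID/SSFP-Echo signals at an
assumed T1 (nerve 1600 ms, muscle 1400 ms), and corrects each voxel's
approximate value by monotone nearest-neighbor lookup. A brute-force
isochromat simulation of the steady state validates the closed forms to
better than 0.1%.

Because magnitude images carry Rician noise, weak signals — especially the
small S− echo — are inflated, biasing DESS-T2 upward at low SNR. The
package quantifies this bias and the effect of denoising on it using a
synthetic phantom generator and a surrogate (classical) denoiser standing
in for vendor deep-learning reconstruction; only the *direction* of the
effect is claimed to be comparable.

Also included:

* **B1+-corrected MESE fitting** — conventional multi-echo spin-echo T2
  with imperfect refocusing pulses generates stimulated echoes; the fit
  matches measured trains to extended-phase-graph (EPG) decay curves over
  a (T2, B1) grid, against a naive log-linear baseline.
* **ROI quantitation** — per-ROI mean T2 and mean-normalized SD, with the
  three-non-consecutive-slices protocol validator, and nerve-to-B0 angles
  via the cosine rule (magic-angle analysis).
* **Cohort statistics** — Pearson inter-rater agreement, one-way
  repeated-measures ANOVA over the four within-subject conditions
  (normal/abnormal × standard/DLR reconstruction), Bonferroni-adjusted
  pairwise paired t-tests, Kendall tau-b and linear (identity-link
  Gaussian) associations with electromyography grades, and the paired-t
  sample-size computation via the noncentral t distribution.
* **Synthetic cohort generator** — per-subject condition tables drawn at
  the study's reported condition means/SDs, with two raters, EMG grades
  linked to muscle T2 at a configurable slope (default 9.10 ms per motor
  unit recruitment grade), and nerve angles.

## Worked example

Simulate the demo phantom (nerve cylinders of T2 35 and 76 ms inside
muscle blocks of 27 and 38 ms), add Rician noise at SNR 20, map T2 with
and without surrogate denoising, and summarize the ROIs:

```python
from desst2 import AcquisitionParams
from desst2.synthetic_data import (default_phantom_spec, make_phantom,
                                   simulate_dess, add_rician_noise_pair,
                                   NoiseSpec, surrogate_denoise)
from desst2.t2_mapping import compute_dess_t2_map
from desst2.roi_analysis import RoiMask, roi_stats

acq = AcquisitionParams(tr_ms=20.0, te_ms=5.0, flip_deg=20.0)
maps = make_phantom(default_phantom_spec())
s_plus, s_minus = simulate_dess(maps, acq)
noisy = add_rician_noise_pair(s_plus, s_minus,
                              NoiseSpec(snr=20.0, seed=42), maps.labels)
den = tuple(surrogate_denoise(v) for v in noisy)

for name, (sp, sm) in {"noisy": noisy, "denoised": den}.items():
    t2map = compute_dess_t2_map(sp, sm, maps.labels, acq)
    mask = RoiMask(maps.labels.labels)
    for label, tissue, truth in [(1, "normal muscle", 27.0),
                                 (2, "abnormal muscle", 38.0),
                                 (3, "normal nerve", 35.0),
                                 (4, "abnormal nerve", 76.0)]:
        st = roi_stats(t2map, mask, label)
        print(f"{name:9s} {tissue:16s} true T2 {truth:5.1f}  "
              f"mean {st.mean_t2_ms:6.2f} ms  nSD {st.normalized_sd:.3f}")
```

prints

```
noisy     normal muscle    true T2  27.0  mean  27.83 ms  nSD 0.187
noisy     abnormal muscle  true T2  38.0  mean  39.06 ms  nSD 0.172
noisy     normal nerve     true T2  35.0  mean  36.19 ms  nSD 0.190
noisy     abnormal nerve   true T2  76.0  mean  79.53 ms  nSD 0.220
denoised  normal muscle    true T2  27.0  mean  27.67 ms  nSD 0.039
denoised  abnormal muscle  true T2  38.0  mean  38.80 ms  nSD 0.044
denoised  normal nerve     true T2  35.0  mean  33.66 ms  nSD 0.053
denoised  abnormal nerve   true T2  76.0  mean  67.71 ms  nSD 0.116
```

Rician noise biases every ROI's mean T2 upward (e.g. muscle 27.0 → 27.83
ms), and denoising moves the large muscle ROIs back toward truth while
sharply reducing the mean-normalized SD. On the thin nerve cylinders the
spatial-filter surrogate also blurs in surrounding muscle signal, pulling
nerve T2 *below* truth — a partial-volume limitation of small structures
that parallels why denoising effects are harder to establish in nerves
than in muscles.

The command-line interface exposes the same pipeline
(`desst2 simulate-phantom | add-noise | denoise | map-dess | roi-stats |
simulate-cohort | analyze | fit-mese | power | run`); for example

```
$ desst2 power
delta=5.5 ms, sd=6.9 ms, alpha=0.05, target power=0.8: n = 15 (achieved power 0.819)
```

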