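# gaitvae

Foot-worn IMU gait analysis for stroke rehabilitation research: from raw
two-minute walk test (2MWT) recordings to gait speed, a learned
low-dimensional representation of the gait signal, and the psychometric
properties (reliability, group differences, responsiveness) of the resulting
features.

Gait speed is the standard clinical summary of a 2MWT, but it says little
about *how* someone walks. This package implements an unsupervised
alternative: the 6-channel foot IMU signal (triaxial accelerometer ±8 g,
triaxial gyroscope ±500 °/s) is segmented into 512-sample epochs (5.12 s at
100 Hz) and compressed by a convolutional variational autoencoder (VAE) into
12 latent features whose per-measurement averages serve as candidate
outcome measures alongside gait speed. Because clinical IMU datasets are
rarely shareable, the package ships a synthetic two-foot gait generator with
exact ground truth (contacts, stance phases, walked distance, generative
gait factors), so every stage is testable end to end.

## What is inside

| module | role |
| --- | --- |
| `gaitvae.synthetic` | two-foot IMU cohorts with analytic ground truth: stride-periodic raised-cosine templates, stroke-like vs healthy-like variants, 14-m shuttle path with turns, test-retest and longitudinal sessions |
| `gaitvae.preprocessing` | resample to 100 Hz → gyro offset correction → segmentation into stance-anchored 512×6 epochs with ~50% overlap → 0.01–10 Hz first-order Butterworth band-pass → zero start → dataset-level \|z\|>5 outlier removal → min–max normalization by sensor range |
| `gaitvae.events` | foot contacts and stance/swing phases from the sagittal angular velocity (adaptive thresholds, scale invariant) |
| `gaitvae.speed` | dead-reckoning gait speed: complementary-filter orientation, gravity removal, integration with zero-velocity updates (ZUPT) in mid-stance and linear drift de-trending |
| `gaitvae.vae` | the convolutional VAE (encoder 32/64/128 filters, kernel 3, tanh, temporal lengths 256/128/64, 12 latent dimensions, mirrored decoder), pure numpy with hand-derived gradients and Adam |
| `gaitvae.features` | per-measurement, per-foot averaging of latent scores; join with gait speed |
| `gaitvae.psychometrics` | ICC(2,1) with 95% CI, SEM, MDC; pooled t-test and Hedges' g; MDC-based individual change classification |
| `gaitvae.pipeline` / `gaitvae` CLI | the stages as a reproducible, manifest-writing pipeline |

The statistical layer implements, for test/retest vectors paired by subject,

- ICC(2,1) = (MS_R − MS_E) / (MS_R + MS_E + 2(MS_C − MS_E)/n), the two-way
  random-effects, absolute-agreement, single-measure intraclass correlation;
- SEM = sd_pooled·√(1 − ICC) and MDC = 1.96·√2·SEM ≈ 2.772·SEM;
- Hedges' g = J·(m_b − m_a)/s_p with the small-sample factor
  J = 1 − 3/(4(n_a+n_b) − 9).

## Worked example

```sh
python examples/02_gait_speed.py
```

```
estimated gyro offset:  (+0.86, -0.68, +0.57) deg/s
detected strides:       90 (truth: 90)
estimated distance:     68.5 m
estimated gait speed:   0.571 m/s
true gait speed:        0.566 m/s  (+0.7% error)
ZUPT anchors used:      91
```

A simulated slow walker (0.6 m/s nominal) is processed blind — the gyroscope
offset is estimated from the standing lead-in, every stride's stance phase
anchors a zero-velocity update, and the integrated distance lands within 1%
of the generator's ground truth.

```sh
python examples/04_psychometrics.py
```

```
gait speed ICC(2,1) = 0.948 [0.89, 0.97] (excellent)
SEM = 0.047 m/s, MDC = 0.130 m/s (the smallest individual change beyond measurement error)
stroke 0.53(0.23) vs healthy 1.21(0.14) m/s: t = -13.3, p = 5.4e-20, Hedges' g = 3.36
responsiveness: 6 of 12 subjects increased gait speed beyond the MDC, 6 unchanged
```

The other examples cover the generator (`01`), VAE training with
encode/reconstruct/perturb-and-decode (`03`), and the full pipeline with
byte-identical reruns (`05`). The same chain runs from the shell:

```sh
gaitvae all --seed 5 --outdir demo_out
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data assumptions, the
numerical choices and the known limitations.
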