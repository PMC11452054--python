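"""Train a small VAE on synthetic gait epochs and explore the latent space.

Simulates a small stroke cohort, preprocesses it into normalized 512 x 6
epochs, trains a reduced convolutional VAE (few filters, few passes — this
is a demo, not the full model), then shows the three inference primitives:
encode (posterior mean = the latent feature scores), reconstruct, and
perturb-and-decode (nudge one latent feature, observe the signal change).
"""

import numpy as np

from gaitvae import (CohortSpec, VaeConfig, build_model, encode,
                     finalize_epochs, perturb_and_decode, preprocess_recording,
                     reconstruct, simulate_cohort, train)
from gaitvae.core import epochs_to_array
from gaitvae.vae import reconstruction_mae_units

spec = CohortSpec(n_stroke=10, n_healthy=0, sessions=("test",), duration=90.0, seed=3)
records, _ = simulate_cohort(spec)
epochs = []
for r in records:
    for foot in ("left", "right"):
        eps, _, _ = preprocess_recording(r[foot])
        epochs += eps
kept, removed, _ = finalize_epochs(epochs)
print(f"epochs: {len(epochs)} segmented, {len(removed)} outliers removed")

subjects = sorted({e.subject_id for e in kept})
test_ids = set(subjects[:2])
x_train = epochs_to_array([e for e in kept if e.subject_id not in test_ids])
x_test = epochs_to_array([e for e in kept if e.subject_id in test_ids])

cfg = VaeConfig(filters=(8, 16, 32), max_epochs=30, early_stop_patience=15, seed=0)
model, report = train(build_model(cfg), x_train, x_test, cfg)
print(f"trained {report.n_epochs} passes; "
      f"train MSE {report.train_mse[0]:.4f} -> {report.train_mse[-1]:.4f}, "
      f"KL {report.train_kl[-1]:.2f} nats")

code = encode(model, x_test)
print(f"latent scores: per-dim mean in [{code.mu.mean(0).min():+.2f}, "
      f"{code.mu.mean(0).max():+.2f}], SD in [{code.mu.std(0).min():.2f}, "
      f"{code.mu.std(0).max():.2f}] (KL-regularized; a fully trained model approaches N(0,1))")

x_hat = reconstruct(model, x_test[:64])
mae = reconstruction_mae_units(x_test[:64], x_hat)
print(f"reconstruction MAE: {mae['mae_normalized']:.3f} normalized "
      f"= {mae['mae_acc_g']:.2f} g / {mae['mae_gyro_dps']:.1f} deg/s")

one = encode(model, x_test[0])
base = perturb_and_decode(model, one, dim=0, delta=0.0)
moved = perturb_and_decode(model, one, dim=0, delta=2.0)
print(f"perturbing latent dim 0 by +2.0 changes the decoded signal by "
      f"{np.abs(moved - base).mean():.4f} (mean abs, normalized units)")
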