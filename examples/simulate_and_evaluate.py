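"""Monte-Carlo performance evaluation: ROC curves and timing accuracy.

Generates synthetic trials — Poisson trains (20 events/s, 27 ms refractory
ignored in 20% of cases, 215 ms trials) of unit-peak EPSC templates in
scaled library noise — and sweeps the detection threshold from mu - 2 sigma
to mu + 3 sigma at several SNRs.  Printed: one (Pcd, Pfa) operating point
per threshold and SNR, and the arrival-time error of correct detections.
A scaled-down trial count keeps the run short; increase ``N_TRIALS`` for
smoother curves.
"""

import numpy as np

from matchedpsc import (
    DetectionConfig, SimulationSpec, score_trials, simulate_trials,
    synth_noise_library, synth_template_library, train_bank_from_library,
)

N_TRIALS = 25

root = np.random.default_rng(0)
lib_rng, noise_rng, trial_rng = root.spawn(3)
library = synth_template_library(10, rng=lib_rng)
noise = synth_noise_library(20, rng=noise_rng)
bank = train_bank_from_library(library)
print(f"synthetic bank: mu_cmax={bank.mu_cmax:.3f}, "
      f"sigma_cmax={bank.sigma_cmax:.3f} (unit-peak template scale)")

for snr in (3.0, 6.0, 9.0):
    config = DetectionConfig(amplitude_cutoff=noise.amplitude_cutoff(snr))
    trials = simulate_trials(SimulationSpec(snr=snr, n_trials=N_TRIALS),
                             library, noise, trial_rng)
    cells = []
    errors = []
    for k in (-2.0, -1.0, 0.0, 1.0, 2.0, 3.0):
        point, matches = score_trials(trials, bank, k, config)
        cells.append(f"k={k:+.0f}: Pcd={point.pcd:.2f} Pfa={point.pfa:.2f}")
        if k == -1.0:
            errors = [e for m in matches for e in m.errors]
    err = np.asarray(errors)
    print(f"\nSNR {snr:g} ({N_TRIALS} trials):")
    for c in cells:
        print("  " + c)
    print(f"  arrival-time error at mu-sigma: "
          f"{err.mean():+.2f} +/- {err.std(ddof=1):.2f} ms "
          f"(n={err.size} correct detections)")

print("\nLower thresholds trade false alarms for sensitivity; at SNR 9 the "
      "operating points cluster near the ideal (Pfa=0, Pcd=1) and timing "
      "errors are a fraction of a millisecond.")
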