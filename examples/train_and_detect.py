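"""Train a matched-filter bank on marked EPSCs and detect events.

Builds a synthetic training recording with clean evoked EPSCs of varied
amplitude, trains the bank from mouse-click-style marks, then runs the
automated detector on a fresh trace containing a photostimulation direct
response (slow, large, starting at the laser onset) with synaptic events
riding its tail.  Printed: the bank statistics that set the thresholds, and
each detected event's timing and measurements.
"""

import numpy as np
import pandas as pd

from matchedpsc import (
    DetectionConfig, MarkedEvent, Trace, build_bank, detect, train_template,
)


def epsc(rise_ms, decay_ms, fs=10_000.0):
    t = np.arange(0.0, 8 * decay_ms, 1000.0 / fs)
    w = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    w /= w.max()
    return -w[np.abs(w) >= 0.05]


rng = np.random.default_rng(0)
fs = 10_000.0

# --- training recording: 12 clean EPSCs, amplitudes 25-90 pA --------------
train_samples = rng.normal(0.0, 2.0, 40_000)  # 4 s of 2 pA background noise
marks = []
for i in range(12):
    w = epsc(rng.uniform(1.0, 2.0), rng.uniform(2.5, 4.0)) * rng.uniform(25, 90)
    pos = 1500 + i * 3000
    train_samples[pos : pos + w.size] += w
    marks.append(MarkedEvent(pos - 1, pos + w.size))
train_trace = Trace(samples=train_samples, sampling_rate=fs)

bank = build_bank([train_template(train_trace, m) for m in marks])
print(f"bank of {bank.n_filters} filters: "
      f"mu_cmax = {bank.mu_cmax:.1f} pA, sigma_cmax = {bank.sigma_cmax:.1f} pA")
print(f"mean lead {bank.mean_lead:.1f} ms, mean trail {bank.mean_trail:.1f} ms")
print(f"detection threshold (mu - 1.2 sigma): "
      f"{bank.mu_cmax - 1.2 * bank.sigma_cmax:.1f} pA")

# --- test trace: direct response at the laser onset + three EPSCs ---------
test = rng.normal(0.0, 2.0, 10_000)  # 1 s
laser_ms = 200.0
t = np.arange(10_000) / fs * 1000.0
direct = -120.0 * np.clip((t - laser_ms) / 15.0, 0, None) \
    * np.exp(-np.clip(t - laser_ms, 0, None) / 40.0)
test += direct
for pos_ms, amp in ((245.0, 55.0), (252.0, 40.0), (330.0, 70.0)):
    w = epsc(1.5, 3.0) * amp
    i0 = int(pos_ms * 10)
    test[i0 : i0 + w.size] += w
trace = Trace(samples=test, sampling_rate=fs, laser_onset=laser_ms)

events = detect(trace, bank, DetectionConfig(amplitude_cutoff=20.0))
rows = [{"t_p (ms)": round(e.t_p, 1), "latency (ms)": round(e.latency, 1),
         "amplitude (pA)": round(e.peak_amplitude, 1),
         "rise (ms)": round(e.rise_time, 1),
         "summed input (pA*ms)": round(e.summed_input, 1)} for e in events]
print(f"\n{len(events)} events detected after the direct response "
      f"(planted at 245, 252 and 330 ms):")
print(pd.DataFrame(rows).to_string(index=False))
print("\nThe direct response itself is excluded by the 10 ms direct window "
      "and the outlier threshold; the two overlapping events near 245/252 ms "
      "are split at their shared boundary.")
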