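"""Monte-Carlo trial generator for detector performance evaluation.

Each trial is a short (default 215 ms) current trace assembled from three
ingredients that emulate the experimental libraries used to benchmark the
detector:

* a *template library* of EPSC-shaped test waveforms, each normalized to
  unit peak magnitude (L-infinity norm) so a single SNR describes a trial;
* a *noise library* of background traces (colored Gaussian noise carrying
  sparse spontaneous-EPSC-like transients), each standardized to mean 0 and
  SD 1;
* a Poisson event train (default 20 events/s over 215 ms) with a 27 ms
  refractory constraint that is ignored in 20% of cases, so overlapping
  events occur at realistic rates.

Templates are drawn uniformly per arrival and centered (midpoint) at the
arrival time; a random contiguous noise segment is scaled by 1/SNR (peak
amplitude over noise SD) and added.  The ground truth records both the raw
arrival times and the actual planted peak times; the latter are the time
reference the detector estimates (t_p), so accuracy statistics compare like
with like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .filterbank import FilterBank, build_bank, train_template
from .trace import MarkedEvent, Trace


@dataclass
class SimulationSpec:
    """Study conditions for one Monte-Carlo batch.

    Defaults are the benchmark conditions: 20 events/s, 27 ms refractory
    period ignored with probability 0.2, 215 ms trials, 200 trials per SNR.
    """

    rate: float = 20.0                    # events/s
    refractory: float = 27.0              # ms
    ignore_refractory_prob: float = 0.2
    trial_duration: float = 215.0         # ms
    snr: float = 9.0
    n_trials: int = 200
    seed: Optional[int] = None
    sampling_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not 0.0 <= self.ignore_refractory_prob <= 1.0:
            raise ValueError("ignore_refractory_prob must be in [0, 1]")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if not self.trial_duration > 0:
            raise ValueError("trial_duration must be positive")


@dataclass
class TemplateLibrary:
    """EPSC-shaped test waveforms, each with unit peak magnitude."""

    waveforms: List[np.ndarray]
    peak_indices: List[int]
    durations: List[float]        # ms, support above 5% of peak
    sampling_rate: float = 10_000.0

    def __len__(self) -> int:
        return len(self.waveforms)


@dataclass
class NoiseLibrary:
    """Background traces standardized to mean 0, SD 1.

    ``spont_amplitudes`` records the peak amplitudes (in standardized trace
    units) of the spontaneous transients injected into the traces; they
    play the role of the spontaneous-EPSC amplitudes assessed during
    training, from which the detection amplitude cutoff is derived.
    """

    traces: List[np.ndarray]
    sampling_rate: float = 10_000.0
    spont_amplitudes: List[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.traces)

    def amplitude_cutoff(self, snr: float, n_sd: float = 2.0) -> float:
        """Amplitude-gate cutoff for trials at a given SNR.

        Mean + ``n_sd`` standard deviations of the spontaneous-transient
        amplitude, rescaled to trial units (the noise is multiplied by
        1/SNR when composing a trial).  Falls back to 2/SNR (twice the
        background SD) when the library carries no transients.
        """
        if not self.spont_amplitudes:
            return 2.0 / snr
        arr = np.asarray(self.spont_amplitudes)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return (float(arr.mean()) + n_sd * sd) / snr


@dataclass
class TrialTruth:
    """Ground truth of one simulated trial.

    ``arrival_times`` are the Poisson arrivals (template midpoints);
    ``peak_times`` are the actual planted template peak times, the reference
    against which detected peak times are scored.
    """

    arrival_times: np.ndarray     # ms
    peak_times: np.ndarray        # ms
    template_ids: np.ndarray
    trial_snr: float


def generate_arrivals(spec: SimulationSpec, rng: np.random.Generator,
                      max_redraws: int = 100) -> np.ndarray:
    """Poisson event times with a partially enforced refractory period.

    The event count is Poisson with mean rate x duration.  Events are placed
    uniformly one at a time; a placement closer than ``refractory`` to an
    already accepted event is, in ``ignore_refractory_prob`` of cases,
    accepted anyway (this is what produces overlapping events) and otherwise
    re-drawn.  An event is dropped only if no placement is accepted within
    ``max_redraws`` attempts, which is vanishingly rare; the mean count per
    trial therefore stays at rate x duration (4.3 at the defaults).
    Returns sorted times in ms.
    """
    dur = spec.trial_duration
    n = rng.poisson(spec.rate * dur / 1000.0)
    if n == 0:
        return np.empty(0)
    accepted: List[float] = []
    for _ in range(n):
        for _attempt in range(max_redraws):
            t = float(rng.uniform(0.0, dur))
            ok = all(abs(t - s) >= spec.refractory for s in accepted)
            if ok or rng.random() < spec.ignore_refractory_prob:
                accepted.append(t)
                break
    return np.sort(np.asarray(accepted))


def _double_exponential(tau_rise: float, tau_decay: float, dt_ms: float,
                        support_frac: float = 0.05) -> Tuple[np.ndarray, int]:
    """Inward difference-of-exponentials EPSC shape with unit peak magnitude.

    Trimmed to the support where |waveform| >= ``support_frac`` of the peak.
    Returns (waveform, peak_index); the waveform is negative-going.
    """
    if not 0 < tau_rise < tau_decay:
        raise ValueError("require 0 < tau_rise < tau_decay")
    t_end = 8.0 * tau_decay
    t = np.arange(0.0, t_end, dt_ms)
    w = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    w /= np.max(np.abs(w))
    keep = np.abs(w) >= support_frac
    first, last = int(np.argmax(keep)), int(len(keep) - np.argmax(keep[::-1]) - 1)
    w = w[first : last + 1]
    return -w, int(np.argmax(np.abs(w)))


def synth_template_library(
    n: int = 10,
    rise_range: Tuple[float, float] = (0.8, 1.8),
    decay_range: Tuple[float, float] = (2.2, 3.5),
    rng: Optional[np.random.Generator] = None,
    sampling_rate: float = 10_000.0,
) -> TemplateLibrary:
    """Synthesize a library of EPSC-shaped test templates.

    Shapes are differences of exponentials with rise and decay constants
    drawn uniformly from the given ranges (ms).  The defaults give supports
    of roughly 8-13 ms (mean ~11 ms) and onset-to-peak (lead) times of
    1.5-2.5 ms, the waveform scale of photostimulation-evoked EPSC test
    events.  Keeping the supports short also keeps the waveforms' spectral
    content well above the 10 Hz detection high-pass, as for real EPSCs.
    Every waveform has peak magnitude exactly 1.
    """
    if n < 1:
        raise ValueError("need at least one template")
    if not (rise_range[0] < rise_range[1] and decay_range[0] < decay_range[1]):
        raise ValueError("kinetic ranges must be non-degenerate (lo < hi)")
    rng = rng or np.random.default_rng()
    dt = 1000.0 / sampling_rate
    waveforms, peaks, durations = [], [], []
    for _ in range(n):
        tr = float(rng.uniform(*rise_range))
        td = float(rng.uniform(*decay_range))
        w, pk = _double_exponential(tr, td, dt)
        waveforms.append(w)
        peaks.append(pk)
        durations.append(w.size * dt)
    return TemplateLibrary(waveforms=waveforms, peak_indices=peaks,
                           durations=durations, sampling_rate=sampling_rate)


def synth_noise_library(
    n: int = 20,
    duration: float = 400.0,
    spectral_spec: Optional[dict] = None,
    spont_rate: float = 2.0,
    rng: Optional[np.random.Generator] = None,
    sampling_rate: float = 10_000.0,
    spont_amplitude_range: Tuple[float, float] = (2.0, 4.0),
) -> NoiseLibrary:
    """Synthesize standardized background traces with spontaneous transients.

    The background is Gaussian noise shaped by ``spectral_spec``: a
    first-order autoregressive component (``"ar"``, default phi = 0.3,
    mild low-frequency membrane/seal correlation on top of flat
    thermal/electrode noise) followed by a zero-phase Butterworth
    low-pass (``"lowpass_hz"``, default 2000 Hz) that emulates the
    anti-alias filtering of the acquisition chain — recorded background is
    band-limited, not white at a 10 kHz sampling rate.  Spontaneous
    EPSC-like transients are injected at ``spont_rate`` events/s with peak
    amplitudes drawn from ``spont_amplitude_range`` times the background SD
    — these create realistic false-alarm challenges.  Each trace is
    standardized to mean 0 and SD 1 after injection.  Use
    ``spectral_spec={"ar": 0.0, "lowpass_hz": None}`` for white noise.
    """
    if n < 1:
        raise ValueError("need at least one noise trace")
    rng = rng or np.random.default_rng()
    spec = dict(spectral_spec or {})
    phi = float(spec.get("ar", 0.3))
    lowpass_hz = spec.get("lowpass_hz", 2000.0)
    dt = 1000.0 / sampling_rate
    m = int(round(duration / dt))
    sos = None
    if lowpass_hz is not None:
        from scipy.signal import butter
        sos = butter(4, lowpass_hz, btype="lowpass", fs=sampling_rate,
                     output="sos")
    traces = []
    spont_amps: List[float] = []
    for _ in range(n):
        eps = rng.standard_normal(m)
        if phi != 0.0:
            from scipy.signal import lfilter
            x = lfilter([1.0], [1.0, -phi], eps)
        else:
            x = eps
        if sos is not None:
            from scipy.signal import sosfiltfilt
            x = sosfiltfilt(sos, x)
        base_sd = float(np.std(x))
        n_spont = rng.poisson(spont_rate * duration / 1000.0)
        amps = []
        for _ in range(n_spont):
            tr = float(rng.uniform(0.5, 1.5))
            td = float(rng.uniform(3.0, 6.0))
            w, _pk = _double_exponential(tr, td, dt)
            amp = float(rng.uniform(*spont_amplitude_range)) * base_sd
            start = int(rng.integers(0, max(1, m - w.size)))
            end = min(m, start + w.size)
            x[start:end] += amp * w[: end - start]
            amps.append(amp)
        final_sd = float(x.std())
        x = (x - x.mean()) / final_sd
        traces.append(x)
        spont_amps.extend(a / final_sd for a in amps)
    return NoiseLibrary(traces=traces, sampling_rate=sampling_rate,
                        spont_amplitudes=spont_amps)


def compose_trial(
    arrivals: Sequence[float],
    library: TemplateLibrary,
    noise: NoiseLibrary,
    snr: float,
    rng: np.random.Generator,
    trial_duration: float = 215.0,
    return_components: bool = False,
):
    """Assemble one simulated trial: template train + scaled library noise.

    A template is drawn uniformly per arrival and centered (midpoint) at the
    arrival time, truncated at trial edges; a random contiguous noise
    segment is multiplied by 1/SNR (noise SD for unit-peak events) and
    added.  Events whose peak sample falls outside the trial are excluded
    from the truth (they are undetectable in principle).

    Returns (trace, truth) or, with ``return_components``,
    (trace, truth, clean, scaled_noise).
    """
    if len(library) == 0:
        raise ValueError("empty template library")
    fs = library.sampling_rate
    dt = 1000.0 / fs
    m = int(round(trial_duration / dt))
    clean = np.zeros(m)
    arr_kept, peak_times, ids = [], [], []
    for t_arr in arrivals:
        j = int(rng.integers(0, len(library)))
        w = library.waveforms[j]
        start = int(round(t_arr / dt)) - w.size // 2
        peak_idx = start + library.peak_indices[j]
        s0, s1 = max(0, start), min(m, start + w.size)
        if s1 <= s0:
            continue
        clean[s0:s1] += w[s0 - start : s1 - start]
        if 0 <= peak_idx < m:
            arr_kept.append(float(t_arr))
            peak_times.append(peak_idx * dt)
            ids.append(j)
    tr_noise = noise.traces[int(rng.integers(0, len(noise)))]
    if tr_noise.size < m:
        raise ValueError("noise traces shorter than the trial duration")
    start = int(rng.integers(0, tr_noise.size - m + 1))
    scaled = tr_noise[start : start + m] / snr
    trace = Trace(samples=clean + scaled, sampling_rate=fs)
    truth = TrialTruth(
        arrival_times=np.asarray(arr_kept),
        peak_times=np.asarray(peak_times),
        template_ids=np.asarray(ids, dtype=int),
        trial_snr=snr,
    )
    if return_components:
        return trace, truth, clean, scaled
    return trace, truth


def simulate_trials(spec: SimulationSpec, library: TemplateLibrary,
                    noise: NoiseLibrary,
                    rng: Optional[np.random.Generator] = None
                    ) -> List[Tuple[Trace, TrialTruth]]:
    """Generate ``spec.n_trials`` (trace, truth) pairs at ``spec.snr``."""
    rng = rng or np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_trials):
        arrivals = generate_arrivals(spec, rng)
        out.append(compose_trial(arrivals, library, noise, spec.snr, rng,
                                 trial_duration=spec.trial_duration))
    return out


def train_bank_from_library(library: TemplateLibrary,
                            spont_amplitudes: Optional[Sequence[float]] = None,
                            amplitude_scales: Optional[Sequence[float]] = None
                            ) -> FilterBank:
    """Train a filter bank from the library templates at varied amplitudes.

    Each waveform, padded with a short zero baseline, is treated as a marked
    EPSC spanning its full support.  Experimental banks are trained on
    typical clean evoked EPSCs, whose amplitudes vary severalfold and sit
    mostly below the largest event — the reference the test templates are
    normalized to.  That spread is what gives the c_max statistics a usable
    threshold band (mu + k*sigma) sitting below the convolution responses
    of the events to be detected.  To emulate it, the training copies are
    scaled by ``amplitude_scales`` (default: evenly spaced over 0.3-0.7
    of the unit test-template peak, relative spread ~0.4 as in experimental
    banks, with mu - 2*sigma still above the convolution noise floor).  The templates
    themselves are L1-normalized and thus scale-free; only the pooled
    c_max/amplitude statistics carry the spread.
    """
    pad = 500
    if amplitude_scales is None:
        amplitude_scales = np.linspace(0.3, 0.7, len(library.waveforms))
    models = []
    for w, scale in zip(library.waveforms, amplitude_scales):
        samples = np.concatenate([np.zeros(pad), scale * w, np.zeros(pad)])
        trace = Trace(samples=samples, sampling_rate=library.sampling_rate)
        mark = MarkedEvent(onset_index=pad - 1, offset_index=pad + w.size,
                           peak_index=pad + int(np.argmin(w)))
        models.append(train_template(trace, mark))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return build_bank(models, spont_amplitudes=spont_amplitudes)
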