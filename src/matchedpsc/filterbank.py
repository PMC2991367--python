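"""Training stage: build a bank of approximate matched filters.

Each user-marked EPSC segment is fitted with a low-order polynomial
(default: 8th order) and the fitted waveform, normalized by its L1 norm,
becomes one approximate matched filter (template).  Per-template statistics
— the lead (onset→peak) and trail (peak→offset) durations, the onset-to-peak
amplitude, the self-convolution maximum ``c_max`` and the time shift between
the convolution peak and the event peak — are pooled across the bank.  The
pooled mean/SD of ``c_max`` set the detection and outlier thresholds, and
the pooled lead/trail statistics set the peak- and onset/offset-search
windows in the detection stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
from numpy.polynomial import polynomial as P

from .trace import MarkedEvent, Trace

SCHEMA_VERSION = 1


class DegenerateSegmentError(ValueError):
    """Raised when a marked segment cannot yield a usable template."""


class BaselineMismatchWarning(UserWarning):
    """Onset and offset of a training mark sit at clearly different baselines."""


@dataclass
class TemplateModel:
    """One trained matched filter and the statistics of its source EPSC.

    ``template_samples`` is the fitted waveform at the original sample times,
    scaled to unit L1 norm.  ``shift`` is the signed time offset (ms) between
    the maximum of the template/EPSC convolution and the EPSC peak; it is
    applied in the detection stage to align convolution peaks with event
    peaks.
    """

    coefficients: np.ndarray
    template_samples: np.ndarray
    sampling_rate: float
    lead: Optional[float] = None      # ms, peak - onset
    trail: Optional[float] = None     # ms, offset - peak
    amplitude: Optional[float] = None  # pA, value(onset) - value(peak)
    c_max: Optional[float] = None     # pA
    shift: Optional[float] = None     # ms

    @property
    def duration(self) -> Optional[float]:
        """Event duration in ms (lead + trail)."""
        if self.lead is None or self.trail is None:
            return None
        return self.lead + self.trail

    def to_dict(self) -> dict:
        return {
            "coefficients": np.asarray(self.coefficients).tolist(),
            "template_samples": np.asarray(self.template_samples).tolist(),
            "sampling_rate": self.sampling_rate,
            "lead": self.lead,
            "trail": self.trail,
            "amplitude": self.amplitude,
            "c_max": self.c_max,
            "shift": self.shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateModel":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            template_samples=np.asarray(d["template_samples"], dtype=float),
            sampling_rate=float(d["sampling_rate"]),
            lead=d.get("lead"),
            trail=d.get("trail"),
            amplitude=d.get("amplitude"),
            c_max=d.get("c_max"),
            shift=d.get("shift"),
        )


@dataclass
class FilterBank:
    """A bank of matched filters plus pooled waveform statistics.

    Pooled standard deviations use the sample (n−1) estimator; a single
    template yields SD 0.  ``mean_spont_amplitude`` is the basis of the
    detection-stage amplitude gate (mean spontaneous-EPSC amplitude assessed
    during training); 0 disables the gate unless overridden.
    """

    templates: List[TemplateModel]
    mu_cmax: float
    sigma_cmax: float
    mean_lead: float
    sd_lead: float
    mean_trail: float
    sd_trail: float
    mean_amplitude: float
    mean_spont_amplitude: float = 0.0

    @property
    def n_filters(self) -> int:
        return len(self.templates)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "templates": [t.to_dict() for t in self.templates],
            "mu_cmax": self.mu_cmax,
            "sigma_cmax": self.sigma_cmax,
            "mean_lead": self.mean_lead,
            "sd_lead": self.sd_lead,
            "mean_trail": self.mean_trail,
            "sd_trail": self.sd_trail,
            "mean_amplitude": self.mean_amplitude,
            "mean_spont_amplitude": self.mean_spont_amplitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterBank":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported filter-bank schema version {version}")
        return cls(
            templates=[TemplateModel.from_dict(t) for t in d["templates"]],
            mu_cmax=float(d["mu_cmax"]),
            sigma_cmax=float(d["sigma_cmax"]),
            mean_lead=float(d["mean_lead"]),
            sd_lead=float(d["sd_lead"]),
            mean_trail=float(d["mean_trail"]),
            sd_trail=float(d["sd_trail"]),
            mean_amplitude=float(d["mean_amplitude"]),
            mean_spont_amplitude=float(d.get("mean_spont_amplitude", 0.0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "FilterBank":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def extract_segment(
    trace: Trace,
    mark: MarkedEvent,
    baseline_tolerance: Optional[float] = None,
) -> np.ndarray:
    """Extract a marked EPSC segment, baseline-anchored at its onset value.

    Returns samples on ``[onset_index, offset_index]`` (inclusive) with the
    onset value subtracted, so the segment starts at exactly 0 pA.  A warning
    is emitted when the offset sits at a clearly different baseline level
    than the onset (such marks make poor templates).

    Parameters
    ----------
    baseline_tolerance :
        Maximum tolerated |offset − onset| baseline difference in pA before
        warning.  Default: 25% of the segment's peak-to-peak excursion.
    """
    if mark.onset_index < 0 or mark.offset_index >= trace.n_samples:
        raise IndexError("mark indices out of trace bounds")
    seg = trace.samples[mark.onset_index : mark.offset_index + 1].copy()
    seg -= seg[0]
    ptp = float(np.ptp(seg))
    if baseline_tolerance is None:
        baseline_tolerance = 0.25 * ptp
    if ptp > 0 and abs(seg[-1]) > baseline_tolerance:
        warnings.warn(
            "marked onset and offset are at dissimilar baseline levels "
            f"(mismatch {seg[-1]:.3g} pA); consider a cleaner training EPSC",
            BaselineMismatchWarning,
            stacklevel=2,
        )
    return seg


def fit_template(segment: Sequence[float], order: int = 8,
                 sampling_rate: float = 10_000.0) -> TemplateModel:
    """Fit a polynomial to a marked segment and normalize it to unit L1 norm.

    The time axis is rescaled to [−1, 1] before solving the least-squares
    problem (conditioning); the fitted waveform is evaluated back at the
    original sample times and divided by its L1 norm, so detectability does
    not depend on the training event's amplitude.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    if seg.size < order + 2:
        raise DegenerateSegmentError(
            f"segment of {seg.size} samples is too short for an order-{order} fit"
        )
    if not np.any(seg):
        raise DegenerateSegmentError("all-zero segment has no L1 norm")
    x = np.linspace(-1.0, 1.0, seg.size)
    coef = P.polyfit(x, seg, order)
    fitted = P.polyval(x, coef)
    l1 = float(np.sum(np.abs(fitted)))
    if l1 == 0.0:
        raise DegenerateSegmentError("fitted waveform has zero L1 norm")
    return TemplateModel(
        coefficients=coef,
        template_samples=fitted / l1,
        sampling_rate=sampling_rate,
    )


def _highpass_for_calibration(samples: np.ndarray, sampling_rate: float,
                              cutoff_hz: float = 10.0, order: int = 5
                              ) -> np.ndarray:
    """Zero-phase Butterworth high-pass matching the detection front end."""
    from scipy import signal as _signal

    sos = _signal.butter(order, cutoff_hz, btype="highpass",
                         fs=sampling_rate, output="sos")
    return _signal.sosfiltfilt(sos, samples)


def template_statistics(trace: Trace, mark: MarkedEvent,
                        model: TemplateModel) -> TemplateModel:
    """Fill a fitted template's waveform statistics from its source EPSC.

    lead/trail are the peak−onset and offset−peak durations (ms); amplitude
    is value(onset) − value(peak) in pA and must be positive for an inward
    event; ``c_max`` is the maximum of the full convolution of the
    baseline-anchored raw source segment with the template.  ``shift`` is
    the time offset between the convolution maximum and the event peak,
    calibrated on the high-pass-filtered trace: the detection stage
    convolves filtered data, and filtering advances an asymmetric event's
    peak slightly, so a raw-calibrated shift would misalign by a fraction
    of a millisecond.  Traces too short for stable filtering fall back to
    the raw segment for the shift as well.
    """
    peak = mark.resolve_peak(trace)
    dt = trace.dt_ms
    lead = (peak - mark.onset_index) * dt
    trail = (mark.offset_index - peak) * dt
    amplitude = float(trace.samples[mark.onset_index] - trace.samples[peak])
    if amplitude <= 0:
        raise DegenerateSegmentError(
            "marked event is not an inward deflection (non-positive amplitude); "
            "invert the trace polarity for outward (IPSC) events"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BaselineMismatchWarning)
        seg = extract_segment(trace, mark)
    conv = np.convolve(seg, model.template_samples, mode="full")
    c_max = float(conv.max())
    try:
        filt = _highpass_for_calibration(trace.samples, trace.sampling_rate)
        fseg = filt[mark.onset_index : mark.offset_index + 1]
        fconv = np.convolve(fseg - fseg[0], model.template_samples, mode="full")
        m = int(np.argmax(fconv))
    except ValueError:
        m = int(np.argmax(conv))
    # map the (filtered-domain) convolution peak onto the raw event peak,
    # which is the reference for localization and measurement
    shift = (m - (peak - mark.onset_index)) * dt
    return replace(model, lead=lead, trail=trail, amplitude=amplitude,
                   c_max=c_max, shift=shift)


def train_template(trace: Trace, mark: MarkedEvent, order: int = 8) -> TemplateModel:
    """Convenience: extract, fit and annotate one template from a mark."""
    seg = extract_segment(trace, mark)
    model = fit_template(seg, order=order, sampling_rate=trace.sampling_rate)
    return template_statistics(trace, mark, model)


def _pooled(values: Sequence[float]) -> tuple:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def build_bank(models: Sequence[TemplateModel],
               spont_amplitudes: Optional[Sequence[float]] = None) -> FilterBank:
    """Pool per-template statistics into a :class:`FilterBank`.

    Parameters
    ----------
    models :
        Trained templates (statistics filled).  At least one; fewer than 10
        triggers a warning since the pooled statistics then rest on a thin
        sample.
    spont_amplitudes :
        Amplitudes (pA) of spontaneous EPSCs assessed during training; their
        mean becomes the default detection-stage amplitude cutoff.  When
        absent the stored mean is 0 (gate disabled unless set explicitly).
    """
    models = list(models)
    if not models:
        raise ValueError("cannot build a bank from zero templates")
    if len(models) < 10:
        warnings.warn(
            f"only {len(models)} templates in the bank; at least 10 are "
            "recommended for stable pooled statistics",
            UserWarning,
            stacklevel=2,
        )
    for m in models:
        if m.c_max is None or m.lead is None or m.trail is None:
            raise ValueError("all templates must carry filled statistics")
    mu_cmax, sigma_cmax = _pooled([m.c_max for m in models])
    mean_lead, sd_lead = _pooled([m.lead for m in models])
    mean_trail, sd_trail = _pooled([m.trail for m in models])
    mean_amplitude, _ = _pooled([m.amplitude for m in models])
    spont = float(np.mean(spont_amplitudes)) if spont_amplitudes is not None else 0.0
    return FilterBank(
        templates=models,
        mu_cmax=mu_cmax,
        sigma_cmax=sigma_cmax,
        mean_lead=mean_lead,
        sd_lead=sd_lead,
        mean_trail=mean_trail,
        sd_trail=sd_trail,
        mean_amplitude=mean_amplitude,
        mean_spont_amplitude=spont,
    )
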