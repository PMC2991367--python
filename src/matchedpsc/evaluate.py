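"""Scoring of detections against simulated ground truth; ROC analysis.

A detection is *correct* when its estimated peak time is within a tolerance
(default 1.5 ms) of a true planted peak time, with one-to-one matching;
unmatched truths are omissions and unmatched detections false alarms.
Per-trial correct-detection and false-alarm rates averaged over Monte-Carlo
trials give the probability of correct detection (Pcd) and of false alarm
(Pfa); sweeping the detection-threshold multiplier k (default −2σ…+3σ in
1σ steps) at fixed SNR traces an ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .detect import DetectionConfig, detect
from .filterbank import FilterBank
from .simulate import NoiseLibrary, SimulationSpec, TemplateLibrary, simulate_trials

DEFAULT_TOLERANCE_MS = 1.5
DEFAULT_K_GRID = (-2.0, -1.0, 0.0, 1.0, 2.0, 3.0)


@dataclass
class MatchResult:
    """Per-trial bookkeeping of correct detections, omissions, false alarms."""

    n_true: int
    n_detected: int
    n_correct: int
    errors: List[float] = field(default_factory=list)  # estimated - true, ms
    pairs: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def n_omissions(self) -> int:
        return self.n_true - self.n_correct

    @property
    def n_false_alarms(self) -> int:
        return self.n_detected - self.n_correct


@dataclass
class ROCPoint:
    """One operating point: threshold multiplier k at a fixed SNR."""

    k: float
    pcd: float
    pfa: float
    snr: float


def match_events(truth_times: Sequence[float], detected_times: Sequence[float],
                 tolerance: float = DEFAULT_TOLERANCE_MS) -> MatchResult:
    """Greedy one-to-one nearest matching of detections to truth.

    Candidate pairs within the tolerance are assigned in order of increasing
    |time difference| (ties broken toward the earlier truth event); each
    truth and each detection is used at most once.
    """
    truth = np.asarray(truth_times, dtype=float)
    det = np.asarray(detected_times, dtype=float)
    result = MatchResult(n_true=truth.size, n_detected=det.size, n_correct=0)
    if truth.size == 0 or det.size == 0:
        return result
    pairs = []
    for i, t in enumerate(truth):
        for j, d in enumerate(det):
            delta = abs(d - t)
            if delta <= tolerance:
                pairs.append((delta, i, j))
    pairs.sort()
    used_t: set = set()
    used_d: set = set()
    for delta, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        result.pairs.append((i, j))
        result.errors.append(float(det[j] - truth[i]))
        result.n_correct += 1
    return result


def trial_rates(match: MatchResult, pfa_mode: str = "per_detected"
                ) -> Tuple[Optional[float], float]:
    """Per-trial (Pcd, Pfa).

    Pcd = correct / true (None when the trial has no true events).
    Pfa: fraction of detections that are wrong (``per_detected``, default)
    or false alarms per true event (``per_true``).
    """
    pcd = match.n_correct / match.n_true if match.n_true else None
    if pfa_mode == "per_detected":
        pfa = match.n_false_alarms / match.n_detected if match.n_detected else 0.0
    elif pfa_mode == "per_true":
        pfa = match.n_false_alarms / match.n_true if match.n_true else 0.0
    else:
        raise ValueError(f"unknown pfa_mode {pfa_mode!r}")
    return pcd, pfa


def score_trials(trials, bank: FilterBank, k: float,
                 config: Optional[DetectionConfig] = None,
                 tolerance: float = DEFAULT_TOLERANCE_MS,
                 pfa_mode: str = "per_detected") -> Tuple[ROCPoint, List[MatchResult]]:
    """Detect on a fixed trial set at one threshold multiplier and average.

    Per-trial rates are averaged across trials (trial-wise averaging);
    trials without true events contribute to Pfa only.
    """
    import dataclasses

    base = config or DetectionConfig()
    cfg = dataclasses.replace(base, threshold_multiplier=k)
    matches: List[MatchResult] = []
    pcds, pfas = [], []
    snr = None
    for trace, truth in trials:
        snr = truth.trial_snr
        events = detect(trace, bank, cfg)
        m = match_events(truth.peak_times, [e.t_p for e in events], tolerance)
        matches.append(m)
        pcd, pfa = trial_rates(m, pfa_mode)
        if pcd is not None:
            pcds.append(pcd)
        pfas.append(pfa)
    point = ROCPoint(
        k=k,
        pcd=float(np.mean(pcds)) if pcds else 0.0,
        pfa=float(np.mean(pfas)) if pfas else 0.0,
        snr=float(snr) if snr is not None else float("nan"),
    )
    return point, matches


def roc_curve(spec: SimulationSpec, bank: FilterBank,
              library: TemplateLibrary, noise: NoiseLibrary,
              k_grid: Sequence[float] = DEFAULT_K_GRID,
              config: Optional[DetectionConfig] = None,
              tolerance: float = DEFAULT_TOLERANCE_MS,
              pfa_mode: str = "per_detected",
              rng: Optional[np.random.Generator] = None) -> List[ROCPoint]:
    """ROC curve at ``spec.snr``: one operating point per threshold multiplier.

    The same trial set is reused across the k grid, so the curve reflects
    the threshold sweep alone (and Pcd/Pfa are monotone in k by the
    candidate-run superset property).
    """
    rng = rng or np.random.default_rng(spec.seed)
    trials = simulate_trials(spec, library, noise, rng)
    return [score_trials(trials, bank, k, config, tolerance, pfa_mode)[0]
            for k in k_grid]


def arrival_error_stats(errors: Sequence[float]) -> Tuple[float, float]:
    """Mean and sample SD (ms) of signed arrival-time errors, pooled.

    Errors are (estimated − true) peak times of correctly matched events,
    pooled across trials.
    """
    arr = np.asarray(errors, dtype=float)
    if arr.size == 0:
        raise ValueError("no correct detections to summarize")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd
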