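"""Per-site aggregation of detected events into photostimulation maps.

A circuit-mapping experiment stimulates a grid of sites (default 16 x 16)
while recording from one neuron; detected events from each site's trace are
aggregated into three map layers: mean input amplitude (pA, spontaneous
baseline subtracted), event count, and first-event latency (ms).  Group
statistics across cells (medians of amplitude/rise time/latency, mean event
frequency) summarize cell types the way circuit-mapping studies tabulate
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import DetectedEvent

LAYERS = ("input_amplitude_pA", "event_count", "first_latency_ms")


@dataclass
class SiteMap:
    """One map layer on the stimulation grid; NaN marks missing sites."""

    grid: np.ndarray
    layer: str
    analysis_window: Tuple[float, float]  # ms relative to laser onset

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape

    def to_dict(self) -> dict:
        grid = [[None if np.isnan(v) else float(v) for v in row]
                for row in self.grid]
        return {"layer": self.layer, "analysis_window": list(self.analysis_window),
                "grid": grid}


def _in_window(events: Iterable[DetectedEvent],
               window: Tuple[float, float]) -> List[DetectedEvent]:
    lo, hi = window
    return [e for e in events
            if e.latency is not None and lo <= e.latency < hi]


def site_input_amplitude(
    evoked_summed_inputs: Sequence[float],
    window: Tuple[float, float],
    spont_summed_inputs: Sequence[float] = (),
    spont_window: Optional[Tuple[float, float]] = None,
) -> float:
    """Mean input amplitude of one site, baseline-subtracted (pA).

    The total summed input of events inside the analysis window divided by
    the window length gives a mean current in pA; the same statistic over a
    pre-stimulus (spontaneous) window of the same trace is subtracted, so a
    site whose evoked activity matches its spontaneous level scores 0.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("analysis window must have positive length")
    evoked = float(np.sum(evoked_summed_inputs)) / (hi - lo)
    baseline = 0.0
    if spont_window is not None:
        s_lo, s_hi = spont_window
        if s_hi <= s_lo:
            raise ValueError("spontaneous window must have positive length")
        baseline = float(np.sum(spont_summed_inputs)) / (s_hi - s_lo)
    return evoked - baseline


def build_maps(
    events_by_site: Dict[Tuple[int, int], Sequence[DetectedEvent]],
    shape: Tuple[int, int] = (16, 16),
    window: Tuple[float, float] = (10.0, 150.0),
    baseline_window: Optional[Tuple[float, float]] = None,
) -> Dict[str, SiteMap]:
    """Aggregate per-site events into the three map layers.

    ``window`` and ``baseline_window`` are latency intervals in ms relative
    to the laser onset (the baseline window is negative, pre-stimulus).
    Sites with no in-window events get count 0, amplitude from the baseline
    subtraction alone, and a missing (NaN) first latency.
    """
    rows, cols = shape
    count = np.zeros(shape)
    amplitude = np.zeros(shape)
    latency = np.full(shape, np.nan)
    for site, events in events_by_site.items():
        r, c = site
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"site {site} outside the {rows}x{cols} layout")
        evoked = _in_window(events, window)
        count[r, c] = len(evoked)
        spont: Sequence[DetectedEvent] = ()
        if baseline_window is not None:
            spont = _in_window(events, baseline_window)
        amplitude[r, c] = site_input_amplitude(
            [e.summed_input for e in evoked], window,
            [e.summed_input for e in spont],
            baseline_window,
        )
        if evoked:
            latency[r, c] = min(e.latency for e in evoked)
    return {
        "input_amplitude_pA": SiteMap(amplitude, "input_amplitude_pA", window),
        "event_count": SiteMap(count, "event_count", window),
        "first_latency_ms": SiteMap(latency, "first_latency_ms", window),
    }


def summarize_by_cell(
    cells: Dict[str, pd.DataFrame],
    window_duration_s: float,
    pooled: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Group statistics of evoked events across cells.

    Each cell's table needs columns ``peak_amplitude_pA``, ``rise_time_ms``,
    ``latency_ms`` and ``site`` (site identifier).  Per cell: median peak
    amplitude and rise time, median (across sites) of the first-event
    latency, and mean event frequency — in-window events per site divided by
    the window duration, averaged over sites with events.  The group summary
    is mean ± SE across cells.  With ``pooled=True`` the amplitude/rise/
    latency medians are taken over all events pooled, instead of per cell
    first.

    Returns (per-cell table, group summary with ``mean`` and ``se`` rows).
    """
    if not cells:
        raise ValueError("empty group")
    if window_duration_s <= 0:
        raise ValueError("window duration must be positive")
    rows = []
    for cell_id, df in cells.items():
        if df.empty:
            raise ValueError(f"cell {cell_id!r} has no events")
        first_lat = df.groupby("site")["latency_ms"].min()
        freq = df.groupby("site").size() / window_duration_s
        rows.append({
            "cell": cell_id,
            "median_peak_amplitude_pA": float(df["peak_amplitude_pA"].median()),
            "median_rise_time_ms": float(df["rise_time_ms"].median()),
            "mean_frequency_Hz": float(freq.mean()),
            "median_first_latency_ms": float(first_lat.median()),
        })
    per_cell = pd.DataFrame(rows).set_index("cell")
    if pooled:
        alldf = pd.concat(cells.values(), ignore_index=True)
        first_lat = alldf.groupby("site")["latency_ms"].min()
        pooled_row = {
            "median_peak_amplitude_pA": float(alldf["peak_amplitude_pA"].median()),
            "median_rise_time_ms": float(alldf["rise_time_ms"].median()),
            "mean_frequency_Hz": float(per_cell["mean_frequency_Hz"].mean()),
            "median_first_latency_ms": float(first_lat.median()),
        }
        for col, v in pooled_row.items():
            per_cell.attrs[f"pooled_{col}"] = v
    n = len(per_cell)
    mean = per_cell.mean()
    se = per_cell.std(ddof=1) / np.sqrt(n) if n > 1 else mean * 0.0
    summary = pd.DataFrame({"mean": mean, "se": se}).T
    return per_cell, summary
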