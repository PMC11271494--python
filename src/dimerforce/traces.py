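"""Step detection and dwell-time extraction from bead-height traces.

A trace is a uniformly sampled (time, force, bead-height) record, 200 Hz by
default. The analysis chain turns raw traces into:

* a low-pass smoothed height channel (FFT cutoff at ``f_s / (2 w)`` for a
  w-point window, or a plain moving average),
* step events from a piecewise-constant fit (greedy change-point placement
  with a BIC stop, or a Gaussian-emission HMM for hopping traces),
* dwell-time records from force-jump-cycle hold phases (cycles without a
  qualifying step are kept as right-censored observations),
* (rupture force, step size) pairs from linear force ramps.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "StepEvent",
    "DwellRecord",
    "smooth_trace",
    "detect_steps",
    "extract_dwell_times",
    "rupture_events_from_ramp",
    "dwells_to_frame",
    "frame_to_dwells",
]


@dataclass
class Trace:
    """A (time, force, bead-height) record with uniform sampling."""

    time: np.ndarray
    force: np.ndarray
    height: np.ndarray
    sampling_rate: float = 200.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if not (len(self.time) == len(self.force) == len(self.height)):
            raise ValueError("time, force and height channels must be equal length")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "force_pN": self.force, "height_nm": self.height}
        )


@dataclass(frozen=True)
class StepEvent:
    """A detected step: signed height jump at a time and force."""

    time: float
    force_at_step: float
    step_size: float
    label: str | None = None


@dataclass(frozen=True)
class DwellRecord:
    """A (force, dwell, censored) observation from one hold phase."""

    force: float
    dwell: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.dwell <= 0:
            raise ValueError(f"dwell must be > 0, got {self.dwell}")


def dwells_to_frame(records: Iterable[DwellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"force_pN": r.force, "dwell_s": r.dwell, "censored": r.censored} for r in records],
        columns=["force_pN", "dwell_s", "censored"],
    )


def frame_to_dwells(frame: pd.DataFrame) -> list[DwellRecord]:
    return [
        DwellRecord(force=row.force_pN, dwell=row.dwell_s, censored=bool(row.censored))
        for row in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def smooth_trace(trace: Trace, window: int = 10, method: str = "fft") -> Trace:
    """Low-pass smooth the height channel; length preserved.

    ``method="fft"`` zeroes all Fourier components at or above
    ``sampling_rate / (2 * window)`` Hz (a w-point FFT smoothing);
    ``method="boxcar"`` is a centred moving average of ``window`` points.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(trace):
        raise ValueError(
            f"window ({window}) exceeds trace length ({len(trace)})"
        )
    if window == 1:
        smoothed = trace.height.copy()
    elif method == "fft":
        spec = np.fft.rfft(trace.height)
        freqs = np.fft.rfftfreq(len(trace), d=1.0 / trace.sampling_rate)
        cutoff = trace.sampling_rate / (2.0 * window)
        spec[freqs >= cutoff] = 0.0
        smoothed = np.fft.irfft(spec, n=len(trace))
    elif method == "boxcar":
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(trace.height, pad, mode="edge")
        smoothed = np.convolve(padded, kernel, mode="same")[pad : pad + len(trace)]
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return Trace(
        time=trace.time.copy(),
        force=trace.force.copy(),
        height=smoothed,
        sampling_rate=trace.sampling_rate,
        metadata=dict(trace.metadata),
    )


# ---------------------------------------------------------------------------
# Change-point step detection
# ---------------------------------------------------------------------------


def _best_split(cs: np.ndarray, cs2: np.ndarray, lo: int, hi: int, min_size: int):
    """Best single change point in [lo, hi) by residual-sum reduction.

    Returns (gain, split) where the split index k partitions the segment
    into [lo, k) and [k, hi); gain is the SSE reduction of the split.
    """
    n = hi - lo
    if n < 2 * min_size:
        return 0.0, None
    total_sum = cs[hi] - cs[lo]
    total_sq = cs2[hi] - cs2[lo]
    sse_full = total_sq - total_sum**2 / n
    ks = np.arange(lo + min_size, hi - min_size + 1)
    left_n = ks - lo
    right_n = hi - ks
    left_sum = cs[ks] - cs[lo]
    right_sum = total_sum - left_sum
    sse_split = (
        (cs2[ks] - cs2[lo])
        - left_sum**2 / left_n
        + (total_sq - (cs2[ks] - cs2[lo]))
        - right_sum**2 / right_n
    )
    j = int(np.argmin(sse_split))
    gain = float(sse_full - sse_split[j])
    return gain, int(ks[j])


def _noise_sd(y: np.ndarray) -> float:
    """Robust noise estimate from first differences (median absolute dev)."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / 0.6744897501960817 / np.sqrt(2.0))


def _changepoints(y: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Greedy binary segmentation: accept splits while gain > penalty."""
    cs = np.concatenate(([0.0], np.cumsum(y)))
    cs2 = np.concatenate(([0.0], np.cumsum(y * y)))
    heap: list[tuple[float, int, int, int]] = []
    gain, k = _best_split(cs, cs2, 0, len(y), min_size)
    if k is not None:
        heapq.heappush(heap, (-gain, 0, len(y), k))
    splits: list[int] = []
    while heap:
        neg_gain, lo, hi, k = heapq.heappop(heap)
        if -neg_gain <= penalty:
            break
        splits.append(k)
        for a, b in ((lo, k), (k, hi)):
            g, kk = _best_split(cs, cs2, a, b, min_size)
            if kk is not None and g > penalty:
                heapq.heappush(heap, (-g, a, b, kk))
    return sorted(splits)


def _cluster_bounds(y: np.ndarray, bounds: list[int], min_gap: int) -> list[int]:
    """Collapse change points closer than ``min_gap`` samples into one.

    Noise can split a single sharp edge into two nearby change points; each
    cluster is replaced by its largest-jump boundary.
    """
    if not bounds:
        return bounds
    out: list[int] = []
    cluster = [bounds[0]]
    for k in bounds[1:]:
        if k - cluster[-1] < min_gap:
            cluster.append(k)
        else:
            out.append(_sharpest(y, cluster))
            cluster = [k]
    out.append(_sharpest(y, cluster))
    return out


def _sharpest(y: np.ndarray, cluster: list[int]) -> int:
    if len(cluster) == 1:
        return cluster[0]
    w = max(cluster[-1] - cluster[0], 2)
    jumps = [
        abs(
            y[k : min(k + w, len(y))].mean()
            - y[max(k - w, 0) : k].mean()
        )
        for k in cluster
    ]
    return cluster[int(np.argmax(jumps))]


def _segment_means(y: np.ndarray, bounds: list[int]) -> np.ndarray:
    edges = [0] + bounds + [len(y)]
    return np.array([y[a:b].mean() for a, b in zip(edges, edges[1:])])




def detect_steps(
    trace: Trace,
    min_step: float = 10.0,
    max_states: int | None = None,
    method: str = "changepoint",
    penalty: float | None = None,
    min_size: int = 2,
    min_gap: int = 5,
) -> tuple[list[StepEvent], np.ndarray]:
    """Fit a piecewise-constant level sequence and return the step events.

    ``method="changepoint"`` (default) places change points greedily by
    residual-sum reduction with a BIC-style stopping penalty
    (``2 sigma^2 ln n`` with a robust noise estimate, unless ``penalty`` is
    given), then discards level changes smaller than ``min_step``.
    ``method="hmm"`` fits a ``max_states``-state Gaussian-emission hidden
    Markov model (for hopping traces) and reads steps off the Viterbi path.

    Returns the events sorted by time and the fitted level sequence
    (same length as the trace). A flat trace yields an empty event list.
    """
    y = trace.height
    if len(y) < 2 * min_size:
        return [], y.copy()
    if method == "changepoint":
        if penalty is None:
            sigma = max(_noise_sd(y), 1e-12)
            penalty = 2.0 * sigma**2 * np.log(len(y))
        bounds = _changepoints(y, penalty, min_size)
        bounds = _cluster_bounds(y, bounds, min_gap)
    elif method == "hmm":
        bounds = _hmm_bounds(y, max_states or 2)
        bounds = _cluster_bounds(y, bounds, min_gap)
    else:
        raise ValueError(f"unknown detection method {method!r}")

    means = _segment_means(y, bounds)
    fit = np.empty_like(y)
    edges = [0] + bounds + [len(y)]
    for level, (a, b) in zip(means, zip(edges, edges[1:])):
        fit[a:b] = level
    # Sub-threshold boundaries stay in the piecewise fit (so neighbouring
    # level estimates are uncontaminated) but are not reported as events.
    events = []
    for j, k in enumerate(bounds):
        size = float(means[j + 1] - means[j])
        if abs(size) < min_step:
            continue
        t = 0.5 * (trace.time[k - 1] + trace.time[k])
        events.append(
            StepEvent(
                time=float(t),
                force_at_step=float(trace.force[k]),
                step_size=size,
            )
        )
    return events, fit


def _hmm_bounds(y: np.ndarray, n_states: int) -> list[int]:
    from hmmlearn.hmm import GaussianHMM

    model = GaussianHMM(
        n_components=n_states, covariance_type="diag", n_iter=100, random_state=0
    )
    model.fit(y.reshape(-1, 1))
    path = model.predict(y.reshape(-1, 1))
    return list(np.flatnonzero(np.diff(path) != 0) + 1)


# ---------------------------------------------------------------------------
# Dwell times and ramp events
# ---------------------------------------------------------------------------


def extract_dwell_times(
    traces: Sequence[Trace],
    min_step: float = 10.0,
    **detect_kwargs,
) -> list[DwellRecord]:
    """Dwell-time records from the hold phases of force-jump-cycle traces.

    Each trace must carry ``metadata["hold_phases"]``: a list of
    ``{"start_s", "end_s", "force_pN"}`` dictionaries marking the
    constant-force hold windows. Within each window the first step of at
    least ``min_step`` nm marks the rupture; windows without one yield a
    right-censored record at the hold duration.
    """
    records: list[DwellRecord] = []
    for trace in traces:
        phases = trace.metadata.get("hold_phases")
        if phases is None:
            raise ValueError(
                "trace lacks metadata['hold_phases']; annotate hold windows first"
            )
        for phase in phases:
            start, end = float(phase["start_s"]), float(phase["end_s"])
            mask = (trace.time >= start) & (trace.time < end)
            if not mask.any():
                continue
            sub = Trace(
                time=trace.time[mask],
                force=trace.force[mask],
                height=trace.height[mask],
                sampling_rate=trace.sampling_rate,
            )
            events, _ = detect_steps(sub, min_step=min_step, **detect_kwargs)
            events = [e for e in events if abs(e.step_size) >= min_step]
            force = float(phase.get("force_pN", np.median(sub.force)))
            if events:
                records.append(
                    DwellRecord(force=force, dwell=events[0].time - start, censored=False)
                )
            else:
                records.append(
                    DwellRecord(force=force, dwell=end - start, censored=True)
                )
    return records


def rupture_events_from_ramp(
    trace: Trace,
    loading_rate: float | None = None,
    min_step: float = 10.0,
    **detect_kwargs,
) -> list[StepEvent]:
    """(rupture force, step size) events from a linear force-increase scan.

    The force channel must be monotone over the scan; the force at each
    detected step is read from the force channel at the step sample.
    """
    df = np.diff(trace.force)
    if df.size and not (np.all(df >= -1e-9) or np.all(df <= 1e-9)):
        raise ValueError("force channel is not monotone over the scan region")
    events, _ = detect_steps(trace, min_step=min_step, **detect_kwargs)
    return [e for e in events if abs(e.step_size) >= min_step]
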