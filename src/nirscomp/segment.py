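"""Activation-segment detection via the linear fitting slope (LFS).

Muscle activation shows up in a NIRS channel as a ramp toward a new
hemoglobin plateau over a few seconds; the slope of a short-window linear
fit tracks the concentration change rate and hence the activation degree.
A sliding window (default 8 samples = 500 ms, stride 4 samples = 250 ms
at 16 Hz) yields per-window slopes ``LFS_m^n``.  Runs of consecutive
windows whose slopes share a sign and clear a quiescence threshold are
candidate segments; a run is accepted as active when the mean of its
window slopes agrees with the slope ``LFS_m`` fitted over the whole run
(within a relative tolerance) and that run slope is itself away from
zero.  Rising runs are ``active_up`` (activation), falling runs
``active_down`` (deactivation); everything else is ``inactive``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .exceptions import WindowError
from .improve import ImprovedRecording

KINDS = ("active_up", "active_down", "inactive")


@dataclass
class SegmentConfig:
    """Detector parameters.

    The quiescence threshold ``tol_zero`` is data-driven: 3x the median
    absolute window slope over the trial's first ``rest_duration``
    seconds (assumed rest), floored at ``rel_floor`` times the trial's
    peak absolute window slope so that a noise-free rest period does not
    collapse the threshold to numerical zero.
    """

    window: int = 8      # samples (500 ms at 16 Hz)
    stride: int = 4      # samples (250 ms at 16 Hz)
    tol_rel: float = 0.5          # run mean vs run slope agreement
    tol_zero_factor: float = 3.0  # x median rest-window |slope|
    rest_duration: float = 1.0    # seconds assumed quiescent at trial start
    rel_floor: float = 0.05       # x peak |window slope|


@dataclass
class Segment:
    """Half-open sample interval [start, end) with its fitted slope."""

    start: int
    end: int
    kind: str   # "active_up" | "active_down" | "inactive"
    lfs: float  # slope over the segment, a.u. per second


#: SegmentMap: (channel, series name) -> ordered, non-overlapping segments
#: covering the trial.
SegmentMap = Dict[Tuple[str, str], List[Segment]]


def lfs(values: np.ndarray, times: np.ndarray) -> float:
    """Ordinary least-squares slope of ``values`` against ``times``.

    This is the linear fitting slope sum((t - tbar)(x - xbar)) /
    sum((t - tbar)^2); it is invariant to shifting all times by a
    constant and linear in the values.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.shape != t.shape or x.ndim != 1:
        raise WindowError("values and times must be equal-length 1-D arrays")
    if len(x) < 2:
        raise WindowError("window must contain at least 2 samples")
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0.0:
        raise WindowError("times must not be constant")
    return float(np.dot(tc, x - x.mean()) / denom)


def sliding_lfs(
    series: np.ndarray,
    sampling_rate: float,
    window: int = 8,
    stride: int = 4,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-window slopes of a series.

    Returns ``(slopes, starts)`` where ``starts`` are window start
    indices; the number of windows is ``floor((N - window)/stride) + 1``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < window:
        raise WindowError(f"series of length {n} shorter than one window ({window})")
    if window < 2 or stride < 1:
        raise WindowError("window must be >= 2 and stride >= 1")
    starts = np.arange(0, n - window + 1, stride)
    # OLS slope with fixed, evenly spaced times: closed-form weights
    t = np.arange(window) / sampling_rate
    tc = t - t.mean()
    w = tc / np.dot(tc, tc)
    windows = np.lib.stride_tricks.sliding_window_view(x, window)[starts]
    slopes = windows @ w
    return slopes, starts


def detect_segments(
    series: np.ndarray,
    sampling_rate: float,
    config: Optional[SegmentConfig] = None,
) -> List[Segment]:
    """Partition one series into active/inactive segments.

    The output is an ordered, non-overlapping list of segments covering
    ``[0, len(series))``; an all-quiet series yields a single inactive
    segment.  Detection is invariant to adding a constant offset, and
    negating the series swaps ``active_up`` and ``active_down``.
    """
    cfg = config or SegmentConfig()
    x = np.asarray(series, dtype=float)
    n = len(x)
    slopes, starts = sliding_lfs(x, sampling_rate, cfg.window, cfg.stride)

    rest_limit = cfg.rest_duration * sampling_rate
    rest = np.abs(slopes[starts < rest_limit])
    if rest.size == 0:
        rest = np.abs(slopes)
    tol_zero = max(
        cfg.tol_zero_factor * float(np.median(rest)),
        cfg.rel_floor * float(np.max(np.abs(slopes), initial=0.0)),
    )

    sign = np.zeros(len(slopes), dtype=int)
    sign[slopes > tol_zero] = 1
    sign[slopes < -tol_zero] = -1

    # consecutive same-sign nonzero windows form candidate runs
    active: List[Segment] = []
    i = 0
    while i < len(sign):
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(sign) and sign[j + 1] == sign[i]:
            j += 1
        seg_start = int(starts[i])
        seg_end = int(starts[j]) + cfg.window
        seg_t = np.arange(seg_start, seg_end) / sampling_rate
        run_lfs = lfs(x[seg_start:seg_end], seg_t)
        mean_win = float(np.mean(slopes[i : j + 1]))
        if (
            abs(mean_win - run_lfs) <= cfg.tol_rel * abs(run_lfs)
            and abs(run_lfs) > tol_zero
        ):
            kind = "active_up" if run_lfs > 0 else "active_down"
            active.append(Segment(seg_start, seg_end, kind, run_lfs))
        i = j + 1

    # assemble a non-overlapping cover: clip touching actives, fill gaps
    segments: List[Segment] = []
    cursor = 0
    for seg in active:
        start = max(seg.start, cursor)
        if start >= seg.end:
            continue
        if start > cursor:
            gap_t = np.arange(cursor, start) / sampling_rate
            gap_lfs = lfs(x[cursor:start], gap_t) if start - cursor >= 2 else 0.0
            segments.append(Segment(cursor, start, "inactive", gap_lfs))
        segments.append(Segment(start, seg.end, seg.kind, seg.lfs))
        cursor = seg.end
    if cursor < n:
        gap_t = np.arange(cursor, n) / sampling_rate
        gap_lfs = lfs(x[cursor:n], gap_t) if n - cursor >= 2 else 0.0
        segments.append(Segment(cursor, n, "inactive", gap_lfs))
    return segments


def segment_recording(
    improved: ImprovedRecording, config: Optional[SegmentConfig] = None
) -> SegmentMap:
    """Detect segments on every (channel, series) of an improved recording."""
    cfg = config or SegmentConfig()
    fs = improved.recording.sampling_rate
    out: SegmentMap = {}
    for ch in improved.recording.channels:
        for name in improved.series_names:
            out[(ch, name)] = detect_segments(improved.series(ch, name), fs, cfg)
    return out


def active_spans(segments: List[Segment], series_length: int) -> List[Tuple[int, int]]:
    """Activated spans: from each rising segment's start to the end of the
    next falling segment — the sustained-activation plateau in between is
    part of the activated state.  Unpaired rising or falling segments
    (typically spurious single-run detections) contribute no span.
    """
    spans: List[Tuple[int, int]] = []
    open_start: Optional[int] = None
    for seg in segments:
        if seg.kind == "active_up":
            if open_start is None:
                open_start = seg.start
        elif seg.kind == "active_down" and open_start is not None:
            spans.append((open_start, seg.end))
            open_start = None
    return spans
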