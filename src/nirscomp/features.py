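"""Windowed time-domain features: mean (MEA) and standard deviation (STD).

Each sliding window of each channel's two improved series contributes two
features — the window mean, reflecting the relative hemoglobin
concentration change, and the population standard deviation, reflecting
its stationarity — giving 6 channels x 2 series x 2 features = 24
columns per row for the full configuration (12 when a single component
is selected).  Rows inherit the trial's movement-class label.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import SchemaError, WindowError
from .improve import ImprovedRecording
from .recording import CHANNELS
from .segment import SegmentMap, active_spans

META_COLUMNS = ("trial_id", "window_start", "label")


def mea(values: np.ndarray) -> float:
    """Arithmetic mean of a window."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise WindowError("empty window")
    return float(np.mean(x))


def std(values: np.ndarray) -> float:
    """Population standard deviation (divisor k) of a window."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise WindowError("empty window")
    return float(np.sqrt(np.mean((x - np.mean(x)) ** 2)))


def feature_columns(components: Sequence[str]) -> List[str]:
    """Fixed feature-column order: channel-major, then series, then MEA/STD."""
    return [
        f"{ch}_{series}_{feat}"
        for ch in CHANNELS
        for series in components
        for feat in ("MEA", "STD")
    ]


def extract_features(
    improved: ImprovedRecording,
    window: int = 8,
    stride: int = 4,
    restrict_to_active: bool = False,
    segment_map: Optional[SegmentMap] = None,
    components: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Assemble the labeled feature matrix for one trial.

    One row per sliding-window position fully inside the trial.  With
    ``restrict_to_active`` a segment map is required, and only windows
    whose span lies inside an activated span (rise-to-fall, union over
    channels and series) are kept.  ``components`` selects a subset of
    the improved series (e.g. ``("CMS",)``) for the single-component
    feature sets; default is both series of the improvement method.

    Returns a DataFrame with meta columns ``trial_id, window_start,
    label`` followed by the feature columns in fixed order.
    """
    rec = improved.recording
    missing = [ch for ch in CHANNELS if ch not in rec.hb]
    if missing:
        raise SchemaError(f"recording lacks channels {missing}")
    if components is None:
        components = improved.series_names
    else:
        components = tuple(components)
        unknown = set(components) - set(improved.series_names)
        if unknown:
            raise SchemaError(
                f"components {sorted(unknown)} not produced by method "
                f"{improved.method!r} (has {improved.series_names})"
            )
    n = rec.n_samples
    if n < window:
        raise WindowError(f"trial of {n} samples shorter than one window ({window})")
    starts = np.arange(0, n - window + 1, stride)

    if restrict_to_active:
        if segment_map is None:
            raise SchemaError("restrict_to_active requires a segment_map")
        spans: List[Tuple[int, int]] = []
        for segs in segment_map.values():
            spans.extend(active_spans(segs, n))
        keep = np.zeros(len(starts), dtype=bool)
        for lo, hi in spans:
            keep |= (starts >= lo) & (starts + window <= hi)
        starts = starts[keep]

    cols = feature_columns(components)
    data = np.empty((len(starts), len(cols)))
    j = 0
    for ch in CHANNELS:
        for series in components:
            x = improved.series(ch, series)
            win = np.lib.stride_tricks.sliding_window_view(x, window)[starts]
            mu = win.mean(axis=1)
            sd = np.sqrt(((win - mu[:, None]) ** 2).mean(axis=1))
            data[:, j] = mu
            data[:, j + 1] = sd
            j += 2

    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "label", rec.label)
    df.insert(0, "window_start", starts.astype(int))
    df.insert(0, "trial_id", rec.trial_id)
    return df


def combine_features(frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-trial feature frames, checking column agreement."""
    if not frames:
        raise SchemaError("no feature frames to combine")
    cols = list(frames[0].columns)
    for f in frames[1:]:
        if list(f.columns) != cols:
            raise SchemaError("feature frames have mismatched columns")
    return pd.concat(frames, ignore_index=True)
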