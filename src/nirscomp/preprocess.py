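"""Recording preprocessing: missing-sample padding, low-pass filtering,
EMD baseline-drift removal.

The stage order is pad -> filter -> detrend.  Padding replaces each
dropped sample with the mean of the four preceding values (already-padded
values count as available).  Filtering is a sixth-order Butterworth
low-pass at 0.5 Hz, applied forward-backward (zero phase) as cascaded
second-order sections so activation timing is preserved for the slope
analysis.  Detrending subtracts an EMD-estimated baseline; a monotone or
constant series, which EMD cannot decompose, falls back to removing its
own linear fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .emd import emd
from .exceptions import (
    ConfigurationError,
    FilterLengthError,
    UnpaddablePrefixError,
)
from .recording import NIRSRecording


@dataclass
class PreprocessConfig:
    """Knobs of the cleaning stage.

    ``emd_baseline_rule`` selects what counts as "baseline": the EMD
    residual alone (default) or the residual plus the last (slowest) IMF.
    The latter removes more low-frequency content but, when the
    decomposition yields a single IMF, that IMF is the signal itself, so
    the extra term is only added when at least two IMFs were extracted.
    """

    cutoff: float = 0.5            # Hz
    filter_order: int = 6
    pad_lookback: int = 4          # samples
    emd_max_imfs: int = 8
    emd_baseline_rule: str = "residual_only"  # or "residual_plus_last_imf"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be > 0")
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")
        if self.pad_lookback < 1:
            raise ConfigurationError("pad_lookback must be >= 1")
        if self.emd_baseline_rule not in ("residual_only", "residual_plus_last_imf"):
            raise ConfigurationError(
                f"unknown emd_baseline_rule {self.emd_baseline_rule!r}"
            )


def pad_missing(series: np.ndarray, lookback: int = 4) -> np.ndarray:
    """Replace NaN samples with the mean of the ``lookback`` preceding values.

    Padded values count as available for later gaps, so runs of missing
    samples are filled left to right.  A NaN within the first ``lookback``
    positions cannot be padded and raises :class:`UnpaddablePrefixError`.
    """
    x = np.asarray(series, dtype=float).copy()
    missing = np.nonzero(np.isnan(x))[0]
    if missing.size == 0:
        return x
    if missing[0] < lookback:
        raise UnpaddablePrefixError(
            f"missing sample at index {missing[0]} inside the first {lookback} positions"
        )
    for i in missing:
        x[i] = np.mean(x[i - lookback : i])
    return x


def _burg(x: np.ndarray, order: int) -> np.ndarray:
    """Burg AR coefficients ``a`` with ``x[n] ~ sum_k a[k] * x[n-1-k]``."""
    f = x.copy()
    b = x.copy()
    a = np.zeros(0)
    for m in range(order):
        fm = f[m + 1 :]
        bm = b[m:-1] if m > 0 else b[:-1]
        den = float(np.dot(fm, fm) + np.dot(bm, bm))
        if den == 0.0:
            break
        k = 2.0 * float(np.dot(fm, bm)) / den
        a = np.concatenate([a - k * a[::-1], [k]]) if a.size else np.array([k])
        f_new = fm - k * bm
        b_new = bm - k * fm
        f = np.concatenate([np.zeros(m + 1), f_new])
        b = np.concatenate([np.zeros(m + 1), b_new])
    return a


def _ar_extend(x: np.ndarray, order: int, m: int) -> np.ndarray:
    """Forward AR extrapolation of ``x`` by ``m`` samples (mean-restored)."""
    mu = float(x.mean())
    xc = x - mu
    a = _burg(xc, order)
    if a.size == 0:
        return np.full(m, mu)
    ext = np.concatenate([xc, np.zeros(m)])
    n = len(xc)
    p = len(a)
    for i in range(n, n + m):
        ext[i] = float(np.dot(a, ext[i - 1 : i - 1 - p : -1]))
    return ext[n:] + mu


def lowpass(
    series: np.ndarray,
    sampling_rate: float,
    cutoff: float = 0.5,
    order: int = 6,
    edge: str = "ar",
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; output length equals input length.

    The filter is a cascade of second-order sections run forward and
    backward (no group delay).  ``edge`` selects the boundary handling:

    * ``"ar"`` (default): the series is extended on both sides by Burg
      autoregressive extrapolation (one filter settling length,
      ``4 / cutoff`` seconds) before filtering and the extension is
      discarded afterwards.  Oscillatory content is continued smoothly,
      so stop-band components are attenuated to their steady-state level
      right up to the series ends.  The AR model depends on the data, so
      this mode is linear only away from the edges.
    * ``"pad"``: plain odd-reflection padding (scipy default); exactly
      linear in the input but with the usual low-frequency edge
      transient.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("series must be finite (pad missing samples first)")
    if cutoff >= sampling_rate / 2.0:
        raise ConfigurationError(
            f"cutoff {cutoff} Hz must be below Nyquist {sampling_rate / 2} Hz"
        )
    if edge not in ("ar", "pad"):
        raise ConfigurationError(f"unknown edge mode {edge!r}")
    if len(x) <= 3 * order:
        raise FilterLengthError(
            f"series of length {len(x)} too short for order-{order} zero-phase filtering"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    if edge == "pad":
        return sps.sosfiltfilt(sos, x)
    m = min(len(x) - 1, int(round(4.0 * sampling_rate / cutoff)))
    ar_order = min(12, len(x) // 3)
    right = _ar_extend(x, ar_order, m)
    left = _ar_extend(x[::-1], ar_order, m)[::-1]
    limit = 5.0 * float(np.max(np.abs(x))) + 1e-12
    if np.max(np.abs(right)) > limit or np.max(np.abs(left)) > limit:
        # unstable extrapolation: fall back to plain padding
        return sps.sosfiltfilt(sos, x)
    y = sps.sosfiltfilt(sos, np.concatenate([left, x, right]))
    return y[m : m + len(x)]


def remove_baseline(
    series: np.ndarray,
    sampling_rate: float,
    config: Optional[PreprocessConfig] = None,
) -> np.ndarray:
    """Subtract the EMD-estimated baseline drift from ``series``.

    The baseline is the EMD residual (plus the last IMF under the
    ``residual_plus_last_imf`` rule when >= 2 IMFs exist).  If EMD finds
    nothing oscillatory (monotone/constant input), the series' own linear
    fit is removed instead and a warning is issued.
    """
    config = config or PreprocessConfig()
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("series must be finite")
    imfs, residual = emd(x, max_imfs=config.emd_max_imfs)
    if not imfs:
        warnings.warn(
            "EMD found no oscillatory component; removing the linear fit instead",
            stacklevel=2,
        )
        t = np.arange(len(x), dtype=float)
        coef = np.polynomial.polynomial.polyfit(t, x, 1)
        return x - (coef[0] + coef[1] * t)
    baseline = residual
    if config.emd_baseline_rule == "residual_plus_last_imf" and len(imfs) >= 2:
        baseline = baseline + imfs[-1]
    return x - baseline


def preprocess_recording(
    recording: NIRSRecording, config: Optional[PreprocessConfig] = None
) -> NIRSRecording:
    """Pad, filter and detrend every chromophore series of a recording.

    Metadata and the missing mask (documenting which samples were
    interpolated) are preserved; series length and channel set are
    unchanged.
    """
    config = config or PreprocessConfig()
    out = recording.copy_with()
    for ch in recording.channels:
        for bank in (out.hb, out.hbo2):
            x = pad_missing(bank[ch], lookback=config.pad_lookback)
            x = lowpass(
                x,
                recording.sampling_rate,
                cutoff=config.cutoff,
                order=config.filter_order,
            )
            x = remove_baseline(x, recording.sampling_rate, config)
            bank[ch] = x
    return out
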