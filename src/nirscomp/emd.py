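"""Empirical mode decomposition (EMD) by iterative sifting.

A compact implementation of the classic Huang sifting algorithm used
here for baseline-drift estimation: upper/lower envelopes are natural
cubic splines through the local extrema (with one mirrored extremum per
side to tame end effects), a candidate intrinsic mode function (IMF) is
accepted when the normalised squared change between consecutive siftings
drops below ``sd_thresh``, and decomposition stops when the residual has
fewer than four extrema (a trend) or ``max_imfs`` is reached.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from scipy.interpolate import CubicSpline


def _local_extrema(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (exact flat tops -> midpoint)."""
    d = np.diff(x)
    nz = np.nonzero(d)[0]  # positions with a nonzero slope
    maxima, minima = [], []
    for j in range(1, len(nz)):
        i_prev, i_cur = nz[j - 1], nz[j]
        if d[i_prev] > 0 and d[i_cur] < 0:
            maxima.append((i_prev + 1 + i_cur) // 2)
        elif d[i_prev] < 0 and d[i_cur] > 0:
            minima.append((i_prev + 1 + i_cur) // 2)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _envelope(idx: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic-spline envelope through extrema, mirrored at the ends."""
    ti = idx.astype(float)
    vi = x[idx]
    # mirror the first/last extremum across the series ends
    ts = [2 * 0.0 - ti[0]] if ti[0] > 0 else []
    vs = [vi[0]] if ti[0] > 0 else []
    te = [2 * (n - 1.0) - ti[-1]] if ti[-1] < n - 1 else []
    ve = [vi[-1]] if ti[-1] < n - 1 else []
    tt = np.concatenate([ts, ti, te])
    vv = np.concatenate([vs, vi, ve])
    if len(tt) < 2:
        return np.full(n, vv[0] if len(vv) else 0.0)
    spline = CubicSpline(tt, vv, bc_type="natural")
    return spline(np.arange(n, dtype=float))


def sift(x: np.ndarray, sd_thresh: float = 0.2, max_iter: int = 50) -> np.ndarray:
    """Extract one IMF from ``x``; returns the candidate (may equal ``x``)."""
    h = x.astype(float).copy()
    n = len(h)
    for _ in range(max_iter):
        maxima, minima = _local_extrema(h)
        if len(maxima) < 1 or len(minima) < 1:
            break
        upper = _envelope(maxima, h, n)
        lower = _envelope(minima, h, n)
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = float(np.sum(h * h))
        if denom == 0.0:
            h = h_new
            break
        sd = float(np.sum((h - h_new) ** 2)) / denom
        h = h_new
        if sd < sd_thresh:
            break
    return h


def emd(
    x: np.ndarray, max_imfs: int = 8, sd_thresh: float = 0.2, max_iter: int = 50
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Decompose ``x`` into IMFs and a residual trend.

    Returns
    -------
    imfs : list of ndarray
        Intrinsic mode functions, fastest first.  Empty when the input is
        monotone or constant (nothing oscillatory to extract).
    residual : ndarray
        ``x - sum(imfs)``; the slowly varying trend.
    """
    x = np.asarray(x, dtype=float)
    residual = x.copy()
    imfs: List[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) < 1 or len(minima) < 1:
            break  # residual holds no full oscillation: it is the trend
        imf = sift(residual, sd_thresh=sd_thresh, max_iter=max_iter)
        if float(np.max(np.abs(imf))) < 1e-12 * max(1.0, float(np.max(np.abs(x)))):
            break
        # a genuine IMF oscillates about zero; a trend-like candidate
        # (fewer than two sign changes) means sifting hit the residual
        signs = np.sign(imf[np.abs(imf) > 1e-12 * float(np.max(np.abs(imf)))])
        if np.count_nonzero(np.diff(signs)) < 2:
            break
        imfs.append(imf)
        residual = residual - imf
    return imfs, residual
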