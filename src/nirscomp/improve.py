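"""Signal-improvement transforms for the chromophore pair.

Two decompositions of the (Hb, HbO2) pair are provided:

* **CBSI** (correlation-based signal improvement) assumes Hb and HbO2 are
  perfectly anti-correlated and splits them with a scale factor
  ``alpha = std(HbO2) / std(Hb)`` into a true noise signal
  ``TNS = (HbO2 + alpha * Hb) / 2`` (effects identical in both series)
  and a true functional signal ``TFS = (HbO2 - alpha * Hb) / 2``.

* **DBSI** (differential-based signal improvement) separates the two
  physiological drivers directly: the common-mode signal
  ``CMS = (HbO2 + Hb) / 2`` tracks blood flow (moves both chromophores
  together) and the differential-mode signal ``DMS = (HbO2 - Hb) / 2``
  tracks oxygen consumption (moves them apart).  DBSI is a linear
  bijection; :func:`dbsi_inverse` is its exact inverse and doubles as the
  simulator's forward map.

Standard deviations use the population convention (ddof=0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .exceptions import ConfigurationError, DegenerateChannelError, ShapeError
from .recording import NIRSRecording

#: Names of the (series_a, series_b) pair each method produces.
SERIES_NAMES: Dict[str, Tuple[str, str]] = {
    "raw": ("Hb", "HbO2"),
    "cbsi": ("TNS", "TFS"),
    "dbsi": ("CMS", "DMS"),
}


@dataclass
class ImprovedSignal:
    """Result of one transform on one channel's chromophore pair."""

    method: str  # "raw" | "cbsi" | "dbsi"
    series_a: np.ndarray  # TNS (cbsi) | CMS (dbsi) | Hb (raw)
    series_b: np.ndarray  # TFS (cbsi) | DMS (dbsi) | HbO2 (raw)
    alpha: Optional[float] = None  # CBSI scale factor, None otherwise

    @property
    def names(self) -> Tuple[str, str]:
        return SERIES_NAMES[self.method]

    def series(self, name: str) -> np.ndarray:
        a, b = self.names
        if name == a:
            return self.series_a
        if name == b:
            return self.series_b
        raise KeyError(f"unknown series {name!r} for method {self.method}")


def _check_pair(hb: np.ndarray, hbo2: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    hb = np.asarray(hb, dtype=float)
    hbo2 = np.asarray(hbo2, dtype=float)
    if hb.shape != hbo2.shape or hb.ndim != 1:
        raise ShapeError(f"hb and hbo2 must be equal-length 1-D series, got {hb.shape} vs {hbo2.shape}")
    return hb, hbo2


def cbsi(hb: np.ndarray, hbo2: np.ndarray) -> ImprovedSignal:
    """Correlation-based signal improvement of one chromophore pair."""
    hb, hbo2 = _check_pair(hb, hbo2)
    sd_hb = float(np.std(hb))  # population convention
    if sd_hb == 0.0:
        raise DegenerateChannelError("std(hb) = 0: CBSI alpha undefined")
    alpha = float(np.std(hbo2)) / sd_hb
    tns = 0.5 * (hbo2 + alpha * hb)
    tfs = 0.5 * (hbo2 - alpha * hb)
    return ImprovedSignal(method="cbsi", series_a=tns, series_b=tfs, alpha=alpha)


def dbsi(hb: np.ndarray, hbo2: np.ndarray) -> ImprovedSignal:
    """Differential-based signal improvement of one chromophore pair."""
    hb, hbo2 = _check_pair(hb, hbo2)
    cms = 0.5 * (hbo2 + hb)
    dms = 0.5 * (hbo2 - hb)
    return ImprovedSignal(method="dbsi", series_a=cms, series_b=dms)


def dbsi_inverse(cms: np.ndarray, dms: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`dbsi`: returns ``(hb, hbo2)``."""
    cms, dms = _check_pair(cms, dms)
    return cms - dms, cms + dms


@dataclass
class ImprovedRecording:
    """A recording transformed channel-wise by one improvement method."""

    recording: NIRSRecording
    method: str
    signals: Dict[str, ImprovedSignal]

    @property
    def series_names(self) -> Tuple[str, str]:
        return SERIES_NAMES[self.method]

    def series(self, channel: str, name: str) -> np.ndarray:
        return self.signals[channel].series(name)


def improve_recording(recording: NIRSRecording, method: str = "dbsi") -> ImprovedRecording:
    """Apply one improvement method to every channel of a recording.

    ``method`` is ``"raw"`` (pass-through: Hb/HbO2), ``"cbsi"`` or
    ``"dbsi"``; CBSI's alpha is computed per channel per trial.
    """
    if method not in SERIES_NAMES:
        raise ConfigurationError(f"unknown method {method!r}; choose from {sorted(SERIES_NAMES)}")
    signals: Dict[str, ImprovedSignal] = {}
    for ch in recording.channels:
        hb, hbo2 = recording.hb[ch], recording.hbo2[ch]
        if method == "raw":
            signals[ch] = ImprovedSignal(method="raw", series_a=hb.copy(), series_b=hbo2.copy())
        elif method == "cbsi":
            signals[ch] = cbsi(hb, hbo2)
        else:
            signals[ch] = dbsi(hb, hbo2)
    return ImprovedRecording(recording=recording, method=method, signals=signals)
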