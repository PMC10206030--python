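"""Core container for one multichannel muscle-NIRS trial.

A trial carries six trunk-muscle channels (left/right obliquus externus
abdominis, descending trapezius and erector spinae), each with two
chromophore concentration-change series — deoxyhemoglobin (Hb) and
oxyhemoglobin (HbO2) — sampled at a fixed rate (16 Hz for the target
acquisition system).  Missing samples (wireless drop-outs) are stored as
NaN and flagged in a per-channel boolean mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

from .exceptions import ConfigurationError, ShapeError

#: Canonical channel order: left/right obliquus externus abdominis,
#: descending trapezius, erector spinae.
CHANNELS: Tuple[str, ...] = ("LOEA", "ROEA", "LDT", "RDT", "LES", "RES")

#: Movement classes: no compensation, lean-forward, trunk rotation,
#: shoulder elevation.  The order is the documented class order used for
#: label encoding and deterministic tie-breaking.
CLASSES: Tuple[str, ...] = ("NC", "LF", "TR", "SE")

GROUPS: Tuple[str, ...] = ("healthy", "stroke")

#: Sentinel for dropped samples inside the numeric series.
MISSING = np.nan


@dataclass
class NIRSRecording:
    """One trial: 6 channels x 2 chromophore series plus metadata.

    Parameters
    ----------
    trial_id, subject_id : str
        Identifiers; ``trial_id`` must be unique within a dataset.
    group : str
        ``"healthy"`` or ``"stroke"``.
    label : str
        Movement class, one of :data:`CLASSES`.
    sampling_rate : float
        Samples per second (Hz), strictly positive.
    hb, hbo2 : dict
        Channel name -> 1-D float array of concentration changes (a.u.).
    missing_mask : dict
        Channel name -> boolean array, ``True`` where the sample was
        dropped (the corresponding hb/hbo2 entries are NaN).
    """

    trial_id: str
    subject_id: str
    group: str
    label: str
    sampling_rate: float
    hb: Dict[str, np.ndarray]
    hbo2: Dict[str, np.ndarray]
    missing_mask: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.label not in CLASSES:
            raise ConfigurationError(f"label {self.label!r} not in {CLASSES}")
        if self.group not in GROUPS:
            raise ConfigurationError(f"group {self.group!r} not in {GROUPS}")
        chans = tuple(self.hb)
        if len(set(chans)) != len(chans):
            raise ConfigurationError("duplicate channel names")
        if set(self.hb) != set(self.hbo2):
            raise ShapeError("hb and hbo2 must cover the same channels")
        n = self.n_samples
        for ch in chans:
            self.hb[ch] = np.asarray(self.hb[ch], dtype=float)
            self.hbo2[ch] = np.asarray(self.hbo2[ch], dtype=float)
            if self.hb[ch].shape != (n,) or self.hbo2[ch].shape != (n,):
                raise ShapeError(f"channel {ch}: series lengths differ")
        if not self.missing_mask:
            self.missing_mask = {ch: np.zeros(n, dtype=bool) for ch in chans}
        for ch, mask in self.missing_mask.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (n,):
                raise ShapeError(f"channel {ch}: missing_mask length differs")
            self.missing_mask[ch] = mask

    @property
    def channels(self) -> Tuple[str, ...]:
        """Channel names in canonical order (others appended alphabetically)."""
        known = [c for c in CHANNELS if c in self.hb]
        extra = sorted(set(self.hb) - set(CHANNELS))
        return tuple(known + extra)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.hb.values())))

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, **kwargs) -> "NIRSRecording":
        """Shallow metadata copy with replaced fields (series are copied)."""
        new = replace(
            self,
            hb={c: v.copy() for c, v in self.hb.items()},
            hbo2={c: v.copy() for c, v in self.hbo2.items()},
            missing_mask={c: v.copy() for c, v in self.missing_mask.items()},
        )
        for k, v in kwargs.items():
            setattr(new, k, v)
        return new
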