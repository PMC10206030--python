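"""Synthetic muscle-NIRS trial generator with stage-wise ground truth.

The generator builds each channel's clean signal in common-mode /
differential-mode space — the common-mode signal (CMS) models blood-flow
changes, the differential-mode signal (DMS) models oxygen consumption —
as a logistic ramp-to-plateau response, then maps to the chromophore pair
via the exact inverse of the differential decomposition::

    Hb   = CMS - DMS
    HbO2 = CMS + DMS

Measurement artifacts are layered on after the clean mapping: slow
baseline drift (sinusoid + linear term), a cardiac-band sinusoid,
broadband Gaussian noise, and randomly dropped samples (NaN + mask).
Because the clean CMS/DMS are retained in a :class:`GroundTruth` object,
every downstream stage (detrending, signal improvement, segmentation,
classification) can be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .exceptions import ConfigurationError
from .recording import CHANNELS, CLASSES, NIRSRecording

# (cms_amplitude, dms_amplitude) per class per channel, arbitrary
# concentration-change units.  Executing side is the left: reaching with
# the left hand activates primarily the executing-side obliquus externus
# abdominis (LOEA) in lean-forward and trunk-rotation compensation, and
# the executing-side trapezius (LDT) and erector spinae (LES) in shoulder
# elevation; opposite-side muscles play a weaker auxiliary role.  The
# no-compensation class keeps a light stabiliser engagement of the
# executing-side muscles only.
_DEFAULT_MAP: Dict[str, Dict[str, Tuple[float, float]]] = {
    "NC": {
        "LOEA": (0.15, 0.05), "ROEA": (0.0, 0.0),
        "LDT": (0.15, 0.05), "RDT": (0.0, 0.0),
        "LES": (0.12, 0.04), "RES": (0.0, 0.0),
    },
    "LF": {
        "LOEA": (1.0, 0.35), "ROEA": (0.30, 0.10),
        "LDT": (0.0, 0.0), "RDT": (0.15, 0.05),
        "LES": (0.0, 0.0), "RES": (0.0, 0.0),
    },
    "TR": {
        "LOEA": (0.85, 0.30), "ROEA": (0.20, 0.07),
        "LDT": (0.35, 0.12), "RDT": (0.0, 0.0),
        "LES": (0.0, 0.0), "RES": (0.0, 0.0),
    },
    "SE": {
        "LOEA": (0.0, 0.0), "ROEA": (0.0, 0.0),
        "LDT": (1.0, 0.35), "RDT": (0.20, 0.07),
        "LES": (0.90, 0.30), "RES": (0.25, 0.08),
    },
}


def default_activation_map() -> Dict[str, Dict[str, Tuple[float, float]]]:
    """Fresh copy of the default per-class, per-channel activation map."""
    return {lbl: dict(chs) for lbl, chs in _DEFAULT_MAP.items()}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-trial generator.

    Amplitudes are in arbitrary concentration-change units (the
    acquisition system is uncalibrated); times are seconds; the default
    sampling rate matches the 16 Hz wireless NIRS system the analysis
    targets.
    """

    sampling_rate: float = 16.0
    trial_duration: float = 10.0
    classes: Tuple[str, ...] = CLASSES
    activation_map: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=default_activation_map
    )
    rise_time: float = 2.0          # seconds from rest to plateau
    drift_amplitude: float = 0.3    # a.u., slow sinusoid + linear term
    drift_period: float = 60.0      # seconds, >= trial length
    cardiac_freq: float = 1.2       # Hz
    cardiac_amplitude: float = 0.05  # a.u.
    noise_sd: float = 0.05          # a.u., broadband Gaussian
    missing_rate: float = 0.01      # drop probability per sample
    subject_jitter_sigma: float = 0.1  # lognormal sigma of per-subject amplitude factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.rise_time >= self.trial_duration:
            raise ConfigurationError("rise_time must be shorter than trial_duration")
        if self.trial_duration <= 0:
            raise ConfigurationError("trial_duration must be > 0")
        for lbl, chmap in self.activation_map.items():
            for ch, (a, b) in chmap.items():
                if not (math.isfinite(a) and math.isfinite(b)):
                    raise ConfigurationError(f"non-finite amplitude for {lbl}/{ch}")
        for p in (self.drift_amplitude, self.cardiac_amplitude, self.noise_sd):
            if not math.isfinite(p) or p < 0:
                raise ConfigurationError("artifact amplitudes must be finite and >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))


@dataclass
class GroundTruth:
    """Clean per-channel truth for one simulated trial.

    ``onset``/``offset`` are the sample indices where the activation ramp
    starts rising and finishes falling; ``rise_samples`` is the ramp
    length, so the rising ramp spans ``[onset, onset + rise_samples)`` and
    the falling ramp ``[offset - rise_samples, offset)``.  ``cms``/``dms``
    hold the artifact-free common- and differential-mode series.
    """

    onset: int
    offset: int
    rise_samples: int
    cms: Dict[str, np.ndarray]
    dms: Dict[str, np.ndarray]

    def ramp_up(self) -> Tuple[int, int]:
        return (self.onset, self.onset + self.rise_samples)

    def ramp_down(self) -> Tuple[int, int]:
        return (self.offset - self.rise_samples, self.offset)

    def active_span(self) -> Tuple[int, int]:
        """Full activated span, ramp start to ramp end."""
        return (self.onset, self.offset)


def _activation_template(config: SimulationConfig) -> Tuple[np.ndarray, int, int, int]:
    """Unit ramp-plateau-ramp curve plus (onset, offset, rise) in samples.

    The ramp is logistic with time scale ``rise_time / 8`` so that the
    transition effectively occupies ``rise_time`` seconds (1.8% to 98.2%
    of plateau over +-4 time scales); onset at 20% and offset at 80% of
    the trial give clean rest / plateau / rest segments.
    """
    fs = config.sampling_rate
    t = np.arange(config.n_samples) / fs
    t_on = 0.2 * config.trial_duration
    t_off = 0.8 * config.trial_duration
    w = config.rise_time / 8.0
    up = expit((t - (t_on + config.rise_time / 2.0)) / w)
    down = expit(((t_off - config.rise_time / 2.0) - t) / w)
    s = up * down
    onset = int(round(t_on * fs))
    offset = int(round(t_off * fs))
    rise = int(round(config.rise_time * fs))
    return s, onset, offset, rise


def _drift(rng: np.random.Generator, t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    amp = config.drift_amplitude
    if amp == 0:
        return np.zeros_like(t)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    slope = rng.uniform(-1.0, 1.0) * amp / max(config.trial_duration, 1e-9)
    return amp * np.sin(2.0 * np.pi * t / config.drift_period + phase) + slope * t


def generate_trial(
    config: SimulationConfig,
    label: str,
    subject_id: str = "S01",
    trial_id: str = "T001",
    seed: Optional[int] = None,
    group: str = "healthy",
    amp_factors: Optional[Mapping[str, float]] = None,
) -> Tuple[NIRSRecording, GroundTruth]:
    """Generate one synthetic trial and its ground truth.

    Parameters
    ----------
    label : str
        Movement class; must appear in ``config.activation_map``.
    seed : int, optional
        Per-trial seed (defaults to ``config.seed``); identical seed +
        config + label reproduce the trial bit for bit.
    amp_factors : mapping, optional
        Per-channel multiplicative amplitude factors (subject jitter);
        defaults to 1 everywhere.
    """
    if label not in config.activation_map:
        raise ConfigurationError(
            f"label {label!r} has no entry in activation_map "
            f"(known: {sorted(config.activation_map)})"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    s, onset, offset, rise = _activation_template(config)

    hb: Dict[str, np.ndarray] = {}
    hbo2: Dict[str, np.ndarray] = {}
    mask: Dict[str, np.ndarray] = {}
    cms_true: Dict[str, np.ndarray] = {}
    dms_true: Dict[str, np.ndarray] = {}

    chmap = config.activation_map[label]
    for ch in CHANNELS:
        cms_amp, dms_amp = chmap.get(ch, (0.0, 0.0))
        factor = 1.0 if amp_factors is None else float(amp_factors.get(ch, 1.0))
        cms = cms_amp * factor * s
        dms = dms_amp * factor * s
        cms_true[ch] = cms
        dms_true[ch] = dms
        # exact inverse of the differential decomposition
        ch_hb = cms - dms
        ch_hbo2 = cms + dms

        # artifacts, drawn independently per chromophore series
        for arr in (ch_hb, ch_hbo2):
            arr += _drift(rng, t, config)
            if config.cardiac_amplitude > 0:
                arr += config.cardiac_amplitude * np.sin(
                    2.0 * np.pi * config.cardiac_freq * t + rng.uniform(0.0, 2.0 * np.pi)
                )
            if config.noise_sd > 0:
                arr += rng.normal(0.0, config.noise_sd, size=n)

        m = rng.random(n) < config.missing_rate
        m[:4] = False  # guarantee a paddable prefix for the 4-point rule
        ch_hb[m] = np.nan
        ch_hbo2[m] = np.nan
        hb[ch], hbo2[ch], mask[ch] = ch_hb, ch_hbo2, m

    rec = NIRSRecording(
        trial_id=trial_id,
        subject_id=subject_id,
        group=group,
        label=label,
        sampling_rate=config.sampling_rate,
        hb=hb,
        hbo2=hbo2,
        missing_mask=mask,
    )
    truth = GroundTruth(onset=onset, offset=offset, rise_samples=rise, cms=cms_true, dms=dms_true)
    return rec, truth


def generate_dataset(
    config: SimulationConfig,
    n_subjects: int,
    trials_per_class: int,
    seed: Optional[int] = None,
    nc_trials: Optional[int] = None,
    group: str = "healthy",
) -> List[Tuple[NIRSRecording, GroundTruth]]:
    """Generate a balanced multi-subject dataset.

    Every subject performs ``trials_per_class`` trials of each class in
    ``config.classes``; ``nc_trials`` optionally overrides the count for
    the no-compensation class (the acquisition protocol the simulator
    mirrors used 20 repetitions per compensated motion but only 10
    uncompensated ones).  Subjects differ through per-channel lognormal
    amplitude factors (sigma ``config.subject_jitter_sigma``); the whole
    dataset is deterministic under ``seed``.
    """
    if n_subjects < 1 or trials_per_class < 1:
        raise ConfigurationError("n_subjects and trials_per_class must be >= 1")
    master = np.random.default_rng(config.seed if seed is None else seed)
    out: List[Tuple[NIRSRecording, GroundTruth]] = []
    for si in range(1, n_subjects + 1):
        subject_id = f"S{si:02d}"
        factors = {
            ch: float(np.exp(master.normal(0.0, config.subject_jitter_sigma)))
            for ch in CHANNELS
        }
        for label in config.classes:
            n_trials = trials_per_class
            if label == "NC" and nc_trials is not None:
                n_trials = nc_trials
            for ti in range(1, n_trials + 1):
                trial_seed = int(master.integers(0, 2**31 - 1))
                trial_id = f"{subject_id}_{label}_{ti:03d}"
                out.append(
                    generate_trial(
                        config,
                        label,
                        subject_id=subject_id,
                        trial_id=trial_id,
                        seed=trial_seed,
                        group=group,
                        amp_factors=factors,
                    )
                )
    return out
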