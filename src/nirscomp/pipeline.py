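"""End-to-end orchestration: simulate/load -> preprocess -> improve ->
segment -> features -> cross-validated SVM, per signal type.

The comparison table mirrors the signal-type sweep of the analysis:
``raw`` (Hb/HbO2), ``cbsi`` (TNS/TFS), ``dbsi`` (CMS/DMS) and the four
single-component sets ``tns``, ``tfs``, ``cms``, ``dms``.  Classification
windows are restricted to activated spans (rise-to-fall of the detected
segments, union over channels) by default — features are extracted from
the active segments of each channel and component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .classify import ClassifierConfig, CompensationSVM, EvaluationReport
from .exceptions import ConfigurationError
from .features import combine_features, extract_features
from .improve import improve_recording
from .preprocess import PreprocessConfig, preprocess_recording
from .recording import NIRSRecording
from .segment import SegmentConfig, segment_recording
from .simulate import SimulationConfig, generate_dataset

#: signal type -> (improvement method, component subset or None for both)
SIGNAL_TYPES: Dict[str, Tuple[str, Optional[Tuple[str, ...]]]] = {
    "raw": ("raw", None),
    "cbsi": ("cbsi", None),
    "dbsi": ("dbsi", None),
    "tns": ("cbsi", ("TNS",)),
    "tfs": ("cbsi", ("TFS",)),
    "cms": ("dbsi", ("CMS",)),
    "dms": ("dbsi", ("DMS",)),
}


@dataclass
class FeaturesConfig:
    """Windowing of the feature stage (samples)."""

    window: int = 8
    stride: int = 4
    restrict_to_active: bool = True


@dataclass
class PipelineConfig:
    """Nested configuration for the full pipeline."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    classify: ClassifierConfig = field(default_factory=ClassifierConfig)


_SECTION_TYPES = {
    "simulate": SimulationConfig,
    "preprocess": PreprocessConfig,
    "segment": SegmentConfig,
    "features": FeaturesConfig,
    "classify": ClassifierConfig,
}


def config_from_mapping(mapping: Optional[dict]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a nested dict (e.g. parsed
    YAML); unknown sections or keys are rejected."""
    mapping = mapping or {}
    unknown = set(mapping) - set(_SECTION_TYPES)
    if unknown:
        raise ConfigurationError(f"unknown config section(s) {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        entries = mapping.get(section, {}) or {}
        allowed = set(cls.__dataclass_fields__)
        bad = set(entries) - allowed
        if bad:
            raise ConfigurationError(
                f"unknown key(s) {sorted(bad)} in section {section!r}"
            )
        if section == "simulate" and "activation_map" in entries:
            entries = dict(entries)
            entries["activation_map"] = {
                lbl: {ch: tuple(v) for ch, v in chs.items()}
                for lbl, chs in entries["activation_map"].items()
            }
        if section == "simulate" and "classes" in entries:
            entries = dict(entries)
            entries["classes"] = tuple(entries["classes"])
        kwargs[section] = cls(**entries)
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        return config_from_mapping(yaml.safe_load(fh))


def preprocess_dataset(
    recordings: Sequence[NIRSRecording], config: Optional[PreprocessConfig] = None
) -> List[NIRSRecording]:
    cfg = config or PreprocessConfig()
    return [preprocess_recording(r, cfg) for r in recordings]


def dataset_features(
    recordings: Sequence[NIRSRecording],
    signal_type: str = "dbsi",
    features_config: Optional[FeaturesConfig] = None,
    segment_config: Optional[SegmentConfig] = None,
) -> pd.DataFrame:
    """Feature matrix over preprocessed recordings for one signal type.

    Adds a ``subject_id`` column so subject-level splits remain possible.
    """
    if signal_type not in SIGNAL_TYPES:
        raise ConfigurationError(
            f"unknown signal type {signal_type!r}; choose from {sorted(SIGNAL_TYPES)}"
        )
    method, components = SIGNAL_TYPES[signal_type]
    fcfg = features_config or FeaturesConfig()
    scfg = segment_config or SegmentConfig(window=fcfg.window, stride=fcfg.stride)
    frames = []
    for rec in recordings:
        improved = improve_recording(rec, method)
        seg_map = segment_recording(improved, scfg) if fcfg.restrict_to_active else None
        df = extract_features(
            improved,
            window=fcfg.window,
            stride=fcfg.stride,
            restrict_to_active=fcfg.restrict_to_active,
            segment_map=seg_map,
            components=components,
        )
        df.insert(1, "subject_id", rec.subject_id)
        frames.append(df)
    return combine_features(frames)


def evaluate_features(
    features: pd.DataFrame,
    classifier_config: Optional[ClassifierConfig] = None,
    feature_mode: str = "",
) -> EvaluationReport:
    model = CompensationSVM.from_dataframe(
        features, config=classifier_config, feature_mode=feature_mode
    )
    return model.crossvalidate()


def run_comparison(
    recordings: Sequence[NIRSRecording],
    signal_types: Sequence[str] = ("raw", "cbsi", "dbsi", "tns", "tfs", "cms", "dms"),
    config: Optional[PipelineConfig] = None,
    preprocessed: bool = False,
) -> Dict[str, EvaluationReport]:
    """Cross-validated accuracy per signal type on one dataset."""
    cfg = config or PipelineConfig()
    if not preprocessed:
        recordings = preprocess_dataset(recordings, cfg.preprocess)
    out: Dict[str, EvaluationReport] = {}
    for st in signal_types:
        feats = dataset_features(recordings, st, cfg.features, cfg.segment)
        mode = f"{st} ({'active windows' if cfg.features.restrict_to_active else 'all windows'})"
        out[st] = evaluate_features(feats, cfg.classify, feature_mode=mode)
    return out


def simulate_recordings(
    config: Optional[PipelineConfig] = None,
    n_subjects: int = 6,
    trials_per_class: int = 20,
    seed: Optional[int] = None,
    nc_trials: Optional[int] = None,
    group: str = "healthy",
) -> List[NIRSRecording]:
    cfg = config or PipelineConfig()
    pairs = generate_dataset(
        cfg.simulate,
        n_subjects=n_subjects,
        trials_per_class=trials_per_class,
        seed=seed,
        nc_trials=nc_trials,
        group=group,
    )
    return [rec for rec, _ in pairs]


def comparison_table(reports: Dict[str, EvaluationReport]) -> str:
    """Accuracy-by-signal-type table (plain text)."""
    lines = [f"{'signal':>8} {'accuracy':>10} {'macro F1':>10}"]
    for st, rep in reports.items():
        lines.append(f"{st:>8} {rep.accuracy:>10.4f} {rep.macro_f1:>10.4f}")
    return "\n".join(lines)
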