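"""Pipeline orchestration: offline training, online classification, and the
synthetic experiment.

The two operational modes share one processing chain — Wiener denoise at
the acquisition rate, anti-alias downsample to 1000 Hz, envelope
extraction, per-pattern normalisation — applied identically to training
and live recordings (the whole point: a live pattern must land in the same
feature space as its templates).
"""

from __future__ import annotations

import json
import logging
import re
import shlex
import subprocess
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .classify import ClassificationResult, classify_1nn
from .core import BreathEnvelope, FormatError, RawRecording, VocabularyMismatchError
from .denoise import WienerParams, denoise_recording
from .envelope import downsample, extract_envelope, normalize_envelope
from .evaluate import MetricComparison, compare_metrics, plot_comparison
from .io import read_wav
from .library import (
    DEFAULT_VOCABULARY,
    TemplateLibrary,
    VocabularyEntry,
    build_library,
    load_library,
    save_library,
)
from .synth import generate_subject_dataset

__all__ = [
    "PipelineConfig",
    "process_recording",
    "process_samples",
    "run_offline_training",
    "run_online_classification",
    "run_experiment",
    "load_vocabulary_file",
]

log = logging.getLogger("bpi")

_WAV_NAME = re.compile(r"class(\d+)_rep(\d+)\.wav$")


@dataclass
class PipelineConfig:
    """All tunables of the processing and classification chain."""

    sample_rate_hz: float = 22050.0
    duration_s: float = 10.0
    lead_silence_s: float = 1.0
    intermediate_rate_hz: float = 1000.0
    envelope_rate_hz: float = 100.0
    cutoff_hz: float = 2.0
    wiener_alpha: float = 0.98
    wiener_gain_floor: float = 0.05
    wiener_frame_ms: float = 32.0
    wiener_hop_frac: float = 0.5
    metric: str = "dtw"
    band_width: Optional[int] = None
    rng_seed: int = 0
    n_subjects: int = 23
    n_classes: int = 4
    n_train: int = 10
    n_live: int = 5
    warp_range: tuple = (0.85, 1.2)
    shift_range_s: tuple = (-0.3, 0.3)
    snr_db: float = 10.0

    def __post_init__(self) -> None:
        if not self.envelope_rate_hz < self.intermediate_rate_hz < self.sample_rate_hz:
            raise ValueError("need envelope_rate < intermediate_rate < sample_rate")
        if self.duration_s <= self.lead_silence_s:
            raise ValueError("duration_s must exceed lead_silence_s")

    @property
    def wiener(self) -> WienerParams:
        return WienerParams(
            alpha=self.wiener_alpha,
            noise_from_lead_s=self.lead_silence_s,
            gain_floor=self.wiener_gain_floor,
            frame_len_ms=self.wiener_frame_ms,
            hop_frac=self.wiener_hop_frac,
        )

    @property
    def n_audio_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.duration_s))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        # nested wiener.* keys are accepted as an alias
        wiener = data.pop("wiener", {})
        for key, dest in (
            ("alpha", "wiener_alpha"),
            ("gain_floor", "wiener_gain_floor"),
            ("frame_ms", "wiener_frame_ms"),
            ("lead_silence_s", "lead_silence_s"),
        ):
            if key in wiener:
                data[dest] = wiener[key]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("warp_range", "shift_range_s"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["warp_range"] = list(self.warp_range)
        d["shift_range_s"] = list(self.shift_range_s)
        return d


def process_recording(rec: RawRecording, config: Optional[PipelineConfig] = None) -> BreathEnvelope:
    """Shared processing chain: denoise -> 1000 Hz -> envelope -> normalise."""
    config = config or PipelineConfig()
    den = denoise_recording(rec, config.wiener)
    lo = downsample(den, config.intermediate_rate_hz)
    env = extract_envelope(lo, config.cutoff_hz, config.envelope_rate_hz)
    return normalize_envelope(env)


def process_samples(rec: RawRecording, config: Optional[PipelineConfig] = None) -> np.ndarray:
    """As :func:`process_recording` but returning the bare value vector."""
    return process_recording(rec, config).values


def _conform_length(rec: RawRecording, config: PipelineConfig, name: str = "") -> RawRecording:
    """Zero-pad shorter / truncate longer recordings to the configured
    window so the fixed-length contract (and ED) always holds."""
    n = config.n_audio_samples
    x = rec.samples
    if x.size < n:
        log.warning("%s: padding %d -> %d samples", name, x.size, n)
        x = np.pad(x, (0, n - x.size))
    elif x.size > n:
        log.warning("%s: truncating %d -> %d samples", name, x.size, n)
        x = x[:n]
    else:
        return rec
    return RawRecording(x, rec.sample_rate_hz, rec.silence_lead_s)


def load_vocabulary_file(path: Union[str, Path]) -> List[VocabularyEntry]:
    """Vocabulary JSON: a list of {class_id, label, phrase} objects."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        return [VocabularyEntry(int(v["class_id"]), v["label"], v["phrase"]) for v in data]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed vocabulary entry: {exc}") from exc


def run_offline_training(
    wav_dir: Union[str, Path],
    vocabulary: Union[str, Path, Sequence[VocabularyEntry], None] = None,
    config: Optional[PipelineConfig] = None,
    library_out: Optional[Union[str, Path]] = None,
) -> TemplateLibrary:
    """Offline (training) mode: WAV tree -> persisted template library.

    ``wav_dir`` holds files named ``class<k>_rep<j>.wav``.  Every class
    found must have a vocabulary entry.
    """
    config = config or PipelineConfig()
    if vocabulary is None:
        vocab = DEFAULT_VOCABULARY
    elif isinstance(vocabulary, (str, Path)):
        vocab = load_vocabulary_file(vocabulary)
    else:
        vocab = list(vocabulary)
    wav_dir = Path(wav_dir)
    files = sorted(wav_dir.glob("*.wav"))
    train_sets: Dict[int, List[BreathEnvelope]] = {}
    for f in files:
        m = _WAV_NAME.search(f.name)
        if not m:
            log.warning("skipping unrecognised file name %s", f.name)
            continue
        cid = int(m.group(1))
        rec = read_wav(f, silence_lead_s=config.lead_silence_s,
                       expected_rate_hz=config.sample_rate_hz)
        rec = _conform_length(rec, config, f.name)
        env = process_recording(rec, config)
        env = BreathEnvelope(env.values, env.rate_hz, cid)
        train_sets.setdefault(cid, []).append(env)
        log.info("trained template from %s (class %d)", f.name, cid)
    if not train_sets:
        raise VocabularyMismatchError(f"no class<k>_rep<j>.wav files found in {wav_dir}")
    lib = build_library(train_sets, vocab)
    if library_out is not None:
        save_library(lib, library_out)
        log.info("library with M=%d templates saved to %s", lib.M, library_out)
    return lib


def run_online_classification(
    live_wav: Union[str, Path],
    library_path: Union[str, Path, TemplateLibrary],
    config: Optional[PipelineConfig] = None,
    speech_hook: Optional[str] = None,
) -> ClassificationResult:
    """Online (live) mode: one WAV -> processed -> classified -> phrase.

    ``speech_hook`` is an optional shell command; ``{phrase}`` in it is
    replaced by the emitted phrase (e.g. hand-off to a system TTS).
    """
    config = config or PipelineConfig()
    if isinstance(library_path, TemplateLibrary):
        lib = library_path
    else:
        lib = load_library(library_path)
    rec = read_wav(live_wav, silence_lead_s=config.lead_silence_s,
                   expected_rate_hz=config.sample_rate_hz)
    rec = _conform_length(rec, config, Path(live_wav).name)
    env = process_recording(rec, config)
    result = classify_1nn(env.values, lib, config.metric, config.band_width)
    log.info(
        "classified %s -> class %d (%s), min distance %.4g",
        live_wav, result.predicted_class, result.metric_name,
        float(result.distances[result.nearest_template_index]),
    )
    if speech_hook:
        cmd = [tok.replace("{phrase}", result.phrase) for tok in shlex.split(speech_hook)]
        subprocess.run(cmd, check=False)
    return result


def run_experiment(
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[Union[str, Path]] = None,
    make_plot: bool = False,
) -> MetricComparison:
    """Full synthetic experiment: simulate subjects, train per-subject
    libraries, classify live sets under both metrics, write evaluation CSVs.

    Defaults (23 subjects, 4 classes, 10 train / 5 live repetitions)
    produce 40 training patterns per subject and 92 live sets / 460 live
    classifications per metric overall.
    """
    config = config or PipelineConfig()

    def _datasets():
        for s in range(config.n_subjects):
            yield generate_subject_dataset(
                rng_seed=config.rng_seed + s,
                subject_id=s,
                n_classes=config.n_classes,
                n_train=config.n_train,
                n_live=config.n_live,
                warp_range=config.warp_range,
                shift_range_s=config.shift_range_s,
                snr_db=config.snr_db,
                duration_s=config.duration_s,
                sample_rate_hz=config.sample_rate_hz,
                env_rate_hz=config.envelope_rate_hz,
                silence_lead_s=config.lead_silence_s,
            )

    comparison = compare_metrics(_datasets(), config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for m, cm in comparison.cumulative.items():
            cm.to_frame().to_csv(out_dir / f"confusion_{m}.csv")
            rows = [
                {"subject_id": s.subject_id, "percent_correct": s.percent_correct}
                for s in comparison.subject_scores[m]
            ]
            pd.DataFrame(rows).to_csv(out_dir / f"subjects_{m}.csv", index=False)
        comparison.per_class.to_csv(out_dir / "comparison.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(
                {
                    "mean_accuracy_pct": comparison.mean_accuracy,
                    "pooled_accuracy_pct": comparison.pooled_accuracy,
                    "config": config.to_dict(),
                },
                fh,
                indent=1,
            )
        if make_plot:
            plot_comparison(comparison, out_dir / "comparison.png")
    return comparison
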