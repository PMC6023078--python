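"""Template library: labelled training envelopes plus the phrase vocabulary.

The library is the persistent artifact of the offline (training) mode: M
labelled breath-envelope templates across the user's classes, and the
class -> phrase vocabulary that turns a recognised pattern into speech
output.  Persistence is a human-inspectable ``library.json`` manifest plus
one CSV per template; numeric values round-trip bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np

from .core import BreathEnvelope, FormatError, VocabularyMismatchError
from .io import read_envelope_csv, write_envelope_csv

__all__ = [
    "VocabularyEntry",
    "TemplateLibrary",
    "DEFAULT_VOCABULARY",
    "build_library",
    "phrase_for_class",
    "save_library",
    "load_library",
]


@dataclass(frozen=True)
class VocabularyEntry:
    class_id: int
    label: str
    phrase: str

    def __post_init__(self) -> None:
        if not self.phrase:
            raise ValueError("phrase must be non-empty")
        if not self.label:
            raise ValueError("label must be non-empty")


#: Sample four-class vocabulary; in practice phrases are user-defined.
DEFAULT_VOCABULARY: List[VocabularyEntry] = [
    VocabularyEntry(1, "Breath_Pattern_1", "Hello, good morning"),
    VocabularyEntry(2, "Breath_Pattern_2", "Thank you"),
    VocabularyEntry(3, "Breath_Pattern_3", "My name is …"),
    VocabularyEntry(4, "Breath_Pattern_4", "May I have a train ticket please?"),
]


@dataclass
class TemplateLibrary:
    """M labelled templates sharing one rate/length, plus the vocabulary."""

    templates: List[BreathEnvelope]
    vocabulary: List[VocabularyEntry]
    env_rate_hz: float
    env_len: int

    def __post_init__(self) -> None:
        ids = [v.class_id for v in self.vocabulary]
        if len(set(ids)) != len(ids):
            raise VocabularyMismatchError("duplicate class_id in vocabulary")
        labels = [v.label for v in self.vocabulary]
        if len(set(labels)) != len(labels):
            raise VocabularyMismatchError("duplicate label in vocabulary")
        known = set(ids)
        for k, tpl in enumerate(self.templates):
            if tpl.class_label is None or tpl.class_label not in known:
                raise VocabularyMismatchError(
                    f"template {k} has class {tpl.class_label!r} absent from vocabulary"
                )
            if tpl.n_samples != self.env_len or tpl.rate_hz != self.env_rate_hz:
                raise ValueError(
                    f"template {k}: shape ({tpl.n_samples} @ {tpl.rate_hz} Hz) differs "
                    f"from library layout ({self.env_len} @ {self.env_rate_hz} Hz)"
                )

    @property
    def M(self) -> int:
        return len(self.templates)

    @property
    def class_ids(self) -> List[int]:
        return sorted(v.class_id for v in self.vocabulary)

    def as_matrix(self) -> np.ndarray:
        """Templates stacked row-wise: the M x env_len training matrix."""
        return np.stack([t.values for t in self.templates])

    def labels(self) -> np.ndarray:
        return np.array([int(t.class_label) for t in self.templates])


def build_library(
    train_sets: Mapping[int, Sequence[BreathEnvelope]],
    vocabulary: Sequence[VocabularyEntry],
) -> TemplateLibrary:
    """Assemble a library from per-class envelope lists.

    Every class in ``train_sets`` must appear in ``vocabulary``; all
    envelopes must share rate and length.
    """
    vocabulary = list(vocabulary)
    known = {v.class_id for v in vocabulary}
    missing = sorted(set(train_sets) - known)
    if missing:
        raise VocabularyMismatchError(f"classes {missing} have no vocabulary entry")
    templates: List[BreathEnvelope] = []
    for cid in sorted(train_sets):
        if len(train_sets[cid]) == 0:
            raise VocabularyMismatchError(f"class {cid} has no training envelopes")
        for env in train_sets[cid]:
            templates.append(BreathEnvelope(env.values, env.rate_hz, class_label=cid))
    first = templates[0]
    return TemplateLibrary(
        templates=templates,
        vocabulary=vocabulary,
        env_rate_hz=first.rate_hz,
        env_len=first.n_samples,
    )


def phrase_for_class(lib: TemplateLibrary, class_id: int) -> str:
    """Phrase mapped to a class, verbatim."""
    for entry in lib.vocabulary:
        if entry.class_id == class_id:
            return entry.phrase
    raise KeyError(f"unknown class {class_id}")


def save_library(lib: TemplateLibrary, path: Union[str, Path]) -> Path:
    """Persist a library as ``library.json`` + one CSV per template."""
    root = Path(path)
    (root / "templates").mkdir(parents=True, exist_ok=True)
    manifest = {
        "env_rate_hz": lib.env_rate_hz,
        "env_len": lib.env_len,
        "vocabulary": [
            {"class_id": v.class_id, "label": v.label, "phrase": v.phrase}
            for v in lib.vocabulary
        ],
        "templates": [],
    }
    for k, tpl in enumerate(lib.templates):
        rel = f"templates/class{int(tpl.class_label)}_template{k:03d}.csv"
        write_envelope_csv(root / rel, tpl)
        manifest["templates"].append({"class_id": int(tpl.class_label), "file": rel})
    with open(root / "library.json", "w") as fh:
        json.dump(manifest, fh, indent=1, ensure_ascii=False)
    return root


def load_library(path: Union[str, Path]) -> TemplateLibrary:
    """Load a persisted library; numeric values are reproduced bit-exactly."""
    root = Path(path)
    manifest_path = root / "library.json" if root.is_dir() else root
    root = manifest_path.parent
    if not manifest_path.exists():
        raise FormatError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    for key in ("env_rate_hz", "env_len", "vocabulary", "templates"):
        if key not in manifest:
            raise FormatError(f"{manifest_path}: manifest missing field {key!r}")
    try:
        vocab = [
            VocabularyEntry(int(v["class_id"]), v["label"], v["phrase"])
            for v in manifest["vocabulary"]
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{manifest_path}: malformed vocabulary entry: {exc}") from exc
    templates: List[BreathEnvelope] = []
    for item in manifest["templates"]:
        fpath = root / item["file"]
        if not fpath.exists():
            raise FormatError(f"manifest references missing file: {fpath}")
        env = read_envelope_csv(fpath)
        templates.append(BreathEnvelope(env.values, env.rate_hz, int(item["class_id"])))
    return TemplateLibrary(
        templates=templates,
        vocabulary=vocab,
        env_rate_hz=float(manifest["env_rate_hz"]),
        env_len=int(manifest["env_len"]),
    )
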