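"""Cohort data model and deterministic on-disk round-tripping.

A *session* is one subject's interview, pre-segmented into ``n`` utterances.
Each utterance carries pre-extracted feature vectors for up to three
modalities — acoustic (``A``), visual (``V``) and textual (``T``) — and the
whole session carries a single continuous severity label on a clinical
scale (BDI, 0–63, or PHQ-8, 0–24).  Raw media and feature extraction are
out of scope: this package consumes aligned per-utterance matrices.

On disk a cohort is a JSON manifest plus one comma-delimited matrix file
per (session, modality): ``<session_id>.<modality>.csv``, one row per
utterance, no header, ``%.17g`` floats so float64 values round-trip
exactly.  A keyed-array container (``.npz`` with keys A/V/T) is accepted
as an alternative per-session source when reading.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MODALITY_ORDER = ("A", "V", "T")

SCALE_RANGES = {"BDI": (0.0, 63.0), "PHQ8": (0.0, 24.0)}


class CohortError(Exception):
    """Base class for cohort load/validation failures."""


class CohortLoadError(CohortError):
    """A referenced file is missing or unreadable."""


class CohortValidationError(CohortError):
    """The cohort violates a structural invariant."""


@dataclass(frozen=True)
class FeatureDims:
    """Per-modality feature widths.

    Defaults match the standard extraction stack the data model emulates:
    100-d bag-of-audio-words eGeMAPS acoustics, 2048-d ResNet-50 facial
    embeddings, 768-d BERT sentence embeddings.
    """

    d_A: int = 100
    d_V: int = 2048
    d_T: int = 768

    def __post_init__(self):
        for name in ("d_A", "d_V", "d_T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def of(self, modality: str) -> int:
        return {"A": self.d_A, "V": self.d_V, "T": self.d_T}[modality]


@dataclass
class SessionSample:
    """One subject's aligned utterance-level feature matrices plus label."""

    session_id: str
    features: dict[str, np.ndarray]
    label: float
    scale: str = "PHQ8"

    def __post_init__(self):
        if not self.features:
            raise CohortValidationError(
                f"session {self.session_id!r}: at least one modality required")
        unknown = set(self.features) - set(MODALITY_ORDER)
        if unknown:
            raise CohortValidationError(
                f"session {self.session_id!r}: unknown modalities {sorted(unknown)}")
        self.features = {
            m: np.atleast_2d(np.asarray(x, dtype=np.float64))
            for m, x in self.features.items()
        }
        counts = {m: x.shape[0] for m, x in self.features.items()}
        if len(set(counts.values())) != 1:
            detail = " vs ".join(str(counts[m]) for m in self.modalities)
            raise CohortValidationError(
                f"session {self.session_id!r}: utterance-count mismatch "
                f"across modalities ({detail})")
        if self.n_utterances < 1:
            raise CohortValidationError(
                f"session {self.session_id!r}: empty session")
        if self.scale not in SCALE_RANGES:
            raise CohortValidationError(
                f"session {self.session_id!r}: unknown scale {self.scale!r}")
        lo, hi = SCALE_RANGES[self.scale]
        self.label = float(self.label)
        if not (lo <= self.label <= hi):
            raise CohortValidationError(
                f"session {self.session_id!r}: label {self.label} outside "
                f"{self.scale} range [{lo}, {hi}]")

    @property
    def n_utterances(self) -> int:
        return next(iter(self.features.values())).shape[0]

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITY_ORDER if m in self.features)


@dataclass
class CohortManifest:
    """Index of a cohort on disk: (session_id, label, file paths) entries."""

    entries: list[dict] = field(default_factory=list)
    scale: str = "PHQ8"
    modalities: tuple[str, ...] = MODALITY_ORDER
    split: str = "train"
    seed_note: str | None = None

    def to_json(self) -> str:
        payload = {
            "schema": "mignn-cohort-1",
            "scale": self.scale,
            "modalities": list(self.modalities),
            "split": self.split,
            "seed_note": self.seed_note,
            "entries": self.entries,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "CohortManifest":
        payload = json.loads(text)
        return cls(
            entries=payload["entries"],
            scale=payload["scale"],
            modalities=tuple(payload["modalities"]),
            split=payload.get("split", "train"),
            seed_note=payload.get("seed_note"),
        )


def validate_cohort(samples: list[SessionSample]) -> None:
    """Enforce cohort-level invariants: unique ids, uniform modality set
    and per-modality feature width, single scale."""
    seen: set[str] = set()
    ref_mods: tuple[str, ...] | None = None
    ref_dims: dict[str, int] = {}
    ref_scale: str | None = None
    for s in samples:
        if s.session_id in seen:
            raise CohortValidationError(f"duplicate session_id {s.session_id!r}")
        seen.add(s.session_id)
        if ref_mods is None:
            ref_mods, ref_scale = s.modalities, s.scale
            ref_dims = {m: s.features[m].shape[1] for m in s.modalities}
            continue
        if s.modalities != ref_mods:
            raise CohortValidationError(
                f"session {s.session_id!r}: modality set {s.modalities} differs "
                f"from cohort set {ref_mods}")
        if s.scale != ref_scale:
            raise CohortValidationError(
                f"session {s.session_id!r}: scale {s.scale} differs from "
                f"cohort scale {ref_scale}")
        for m in ref_mods:
            if s.features[m].shape[1] != ref_dims[m]:
                raise CohortValidationError(
                    f"session {s.session_id!r}: modality {m} width "
                    f"{s.features[m].shape[1]} differs from cohort width "
                    f"{ref_dims[m]}")


def _load_matrix(path: Path, session_id: str, modality: str) -> np.ndarray:
    if not path.exists():
        raise CohortLoadError(
            f"session {session_id!r}: missing feature file {path}")
    if path.suffix == ".npz":
        with np.load(path) as bundle:
            if modality not in bundle:
                raise CohortLoadError(
                    f"session {session_id!r}: key {modality!r} absent from {path}")
            return np.atleast_2d(bundle[modality].astype(np.float64))
    return np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=np.float64, ndmin=2))


def read_cohort(manifest_path: str | os.PathLike) -> list[SessionSample]:
    """Load a cohort from its JSON manifest, validating all invariants.

    Samples are returned in manifest order; utterance order is file row
    order (never re-sorted).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CohortLoadError(f"manifest not found: {manifest_path}")
    manifest = CohortManifest.from_json(manifest_path.read_text())
    root = manifest_path.parent
    samples = []
    for entry in manifest.entries:
        sid = entry["session_id"]
        features = {
            m: _load_matrix(root / entry["files"][m], sid, m)
            for m in manifest.modalities
        }
        samples.append(SessionSample(session_id=sid, features=features,
                                     label=entry["label"], scale=manifest.scale))
    validate_cohort(samples)
    return samples


def write_cohort(samples: list[SessionSample], out_dir: str | os.PathLike,
                 split: str = "train", seed_note: str | None = None,
                 manifest_name: str = "manifest.json") -> Path:
    """Write a cohort as manifest + per-session per-modality CSV matrices.

    Deterministic: fixed file naming, ``%.17g`` floats (lossless for
    float64), sorted JSON keys — write→read→write is byte-identical.
    Returns the manifest path.
    """
    validate_cohort(samples)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    modalities = samples[0].modalities if samples else MODALITY_ORDER
    scale = samples[0].scale if samples else "PHQ8"
    entries = []
    for s in samples:
        files = {}
        for m in s.modalities:
            fname = f"{s.session_id}.{m}.csv"
            np.savetxt(out_dir / fname, s.features[m], delimiter=",", fmt="%.17g")
            files[m] = fname
        entries.append({
            "session_id": s.session_id,
            "label": s.label,
            "n_utterances": s.n_utterances,
            "files": files,
        })
    manifest = CohortManifest(entries=entries, scale=scale,
                              modalities=modalities, split=split,
                              seed_note=seed_note)
    path = out_dir / manifest_name
    path.write_text(manifest.to_json())
    return path
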