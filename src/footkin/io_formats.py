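"""On-disk formats: marker/force TSV trials, cohort manifests, configs, tables.

All readers validate and never silently repair: unknown marker labels raise
:class:`~footkin.errors.SchemaError` naming the offenders, segments with too
few markers raise :class:`~footkin.errors.ModelError`, and out-of-vocabulary
static categories raise :class:`~footkin.errors.ValidationError`.  Units are
preserved exactly: millimetres, newtons and degrees in, the same out.

Formats
-------
marker TSV
    ``frame<TAB>label<TAB>x<TAB>y<TAB>z`` — one row per marker per frame,
    100 Hz, 0-based contiguous frame indices; a marker absent from a frame is
    recorded as missing (NaN), never interpolated.
force TSV
    ``sample<TAB>fz`` — vertical ground-reaction force, newtons, 1500 Hz.
cohort manifest CSV
    One row per participant: id, the static assessment fields, and the paths
    of the standing-reference, subtalar-neutral and walking trials.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ModelError, SchemaError, ValidationError
from .model import ANATOMICAL_LABELS, DEFAULT_MODEL

MARKER_RATE_HZ = 100.0
FORCE_RATE_HZ = 1500.0

TRIAL_KINDS = ("walking", "standing_reference", "stn_standing")
FIRST_RAY_CATEGORIES = ("plantarflexed", "normal", "dorsiflexed")
FOREFOOT_CATEGORIES = ("varus", "normal", "valgus")


@dataclass
class StaticAssessment:
    """One foot's Root-protocol static measures.

    Angles are degrees.  ``ncsp_deg``/``rcsp_deg`` are the frontal-plane
    calcaneal angles in neutral / relaxed calcaneal stance position
    (+ = inverted).  The first-ray and forefoot-to-rearfoot alignments are
    clinician category judgements; the Foot Posture Index total is stored
    as given, never computed here.
    """

    ncsp_deg: float
    rcsp_deg: float
    ankle_dorsiflexion_deg: float
    first_mpj_dorsiflexion_deg: float
    first_ray: str
    forefoot: str
    fpi: int

    def __post_init__(self) -> None:
        for name in ("ncsp_deg", "rcsp_deg", "ankle_dorsiflexion_deg",
                     "first_mpj_dorsiflexion_deg"):
            value = float(getattr(self, name))
            if not np.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            setattr(self, name, value)
        if self.first_ray not in FIRST_RAY_CATEGORIES:
            raise ValidationError(
                f"first_ray category {self.first_ray!r} not in {FIRST_RAY_CATEGORIES}"
            )
        if self.forefoot not in FOREFOOT_CATEGORIES:
            raise ValidationError(
                f"forefoot category {self.forefoot!r} not in {FOREFOOT_CATEGORIES}"
            )
        self.fpi = int(self.fpi)


@dataclass
class MarkerTrialBundle:
    """Marker trajectories plus (for walking trials) a vertical force trace.

    ``markers`` maps label -> (n_frames, 3) float array in mm; missing
    samples are NaN.  ``registry`` maps labels to segment names; anatomical
    calibration labels are carried separately and appear only in standing
    reference trials.
    """

    trial_id: str
    kind: str
    markers: dict[str, np.ndarray]
    registry: dict[str, str]
    force: np.ndarray | None = None
    marker_rate_hz: float = MARKER_RATE_HZ
    force_rate_hz: float = FORCE_RATE_HZ
    anatomical_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in TRIAL_KINDS:
            raise ValidationError(f"unknown trial kind {self.kind!r}")
        lengths = {arr.shape[0] for arr in self.markers.values()}
        if len(lengths) > 1:
            raise SchemaError(f"inconsistent marker lengths: {sorted(lengths)}")
        if self.kind == "walking" and self.force is None:
            raise ValidationError(f"walking trial {self.trial_id!r} lacks force data")
        validate_segment_coverage(set(self.markers) - set(self.anatomical_labels),
                                  self.registry)

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    def segment_markers(self, segment: str) -> dict[str, np.ndarray]:
        return {
            label: traj
            for label, traj in self.markers.items()
            if self.registry.get(label) == segment
        }

    def mean_positions(self) -> dict[str, np.ndarray]:
        """Per-marker position averaged over frames (static trials)."""
        return {k: np.nanmean(v, axis=0) for k, v in self.markers.items()}


def validate_segment_coverage(labels: set[str], registry: Mapping[str, str]) -> None:
    """Every registered segment that appears must have >=3 markers (leg 4)."""
    unknown = sorted(lab for lab in labels if lab not in registry)
    if unknown:
        raise SchemaError(f"unknown marker labels: {', '.join(unknown)}")
    per_segment: dict[str, int] = {}
    for lab in labels:
        per_segment[registry[lab]] = per_segment.get(registry[lab], 0) + 1
    for segment, n in per_segment.items():
        need = 4 if segment == "leg" else 3
        if n < need:
            raise ModelError(
                f"segment {segment!r} has {n} markers, needs >= {need}"
            )


# ---------------------------------------------------------------------------
# marker / force TSV
# ---------------------------------------------------------------------------

def write_marker_tsv(path: str | Path, markers: Mapping[str, np.ndarray]) -> None:
    path = Path(path)
    labels = sorted(markers)
    n_frames = next(iter(markers.values())).shape[0]
    with path.open("w", newline="") as fh:
        fh.write("frame\tlabel\tx\ty\tz\n")
        for frame in range(n_frames):
            for label in labels:
                x, y, z = markers[label][frame]
                if np.isnan(x) and np.isnan(y) and np.isnan(z):
                    continue  # missing sample: row omitted
                fh.write(f"{frame}\t{label}\t{x:.9f}\t{y:.9f}\t{z:.9f}\n")


def read_marker_tsv(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    rows: list[tuple[int, str, float, float, float]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["frame", "label", "x", "y", "z"]:
            raise SchemaError(f"{path}: bad marker TSV header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise SchemaError(f"{path}:{lineno}: expected 5 columns")
            rows.append((int(parts[0]), parts[1], float(parts[2]),
                         float(parts[3]), float(parts[4])))
    if not rows:
        raise SchemaError(f"{path}: empty marker file")
    n_frames = max(r[0] for r in rows) + 1
    frames_seen = {r[0] for r in rows}
    if frames_seen != set(range(n_frames)):
        raise SchemaError(f"{path}: frame indices not contiguous from 0")
    labels = sorted({r[1] for r in rows})
    markers = {lab: np.full((n_frames, 3), np.nan) for lab in labels}
    for frame, label, x, y, z in rows:
        markers[label][frame] = (x, y, z)
    return markers


def write_force_tsv(path: str | Path, force: np.ndarray) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("sample\tfz\n")
        for i, fz in enumerate(np.asarray(force, dtype=float)):
            fh.write(f"{i}\t{fz:.9f}\n")


def read_force_tsv(path: str | Path) -> np.ndarray:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample", "fz"]:
            raise SchemaError(f"{path}: bad force TSV header {header}")
        values = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise SchemaError(f"{path}:{lineno}: expected 2 columns")
            if int(parts[0]) != lineno - 2:
                raise SchemaError(f"{path}:{lineno}: sample indices not contiguous")
            values.append(float(parts[1]))
    return np.array(values)


def write_marker_trial(path: str | Path, bundle: MarkerTrialBundle) -> None:
    """Write a bundle as ``<path>`` (markers) and ``<path stem>_force.tsv``."""
    path = Path(path)
    write_marker_tsv(path, bundle.markers)
    if bundle.force is not None:
        write_force_tsv(path.with_name(path.stem + "_force.tsv"), bundle.force)


def read_marker_trial(
    path: str | Path,
    registry: Mapping[str, str] | None = None,
    kind: str = "walking",
    trial_id: str | None = None,
) -> MarkerTrialBundle:
    """Read a marker TSV (and sibling force file for walking trials)."""
    path = Path(path)
    registry = dict(registry) if registry is not None else DEFAULT_MODEL.registry
    markers = read_marker_tsv(path)
    anatomical = tuple(lab for lab in markers if lab in ANATOMICAL_LABELS)
    force = None
    force_path = path.with_name(path.stem + "_force.tsv")
    if force_path.exists():
        force = read_force_tsv(force_path)
    return MarkerTrialBundle(
        trial_id=trial_id or path.stem,
        kind=kind,
        markers=markers,
        registry=registry,
        force=force,
        anatomical_labels=anatomical,
    )


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_FIELDS = [
    "participant_id", "ncsp_deg", "rcsp_deg", "ankle_dorsiflexion_deg",
    "first_mpj_dorsiflexion_deg", "first_ray", "forefoot", "fpi",
    "standing_trial", "stn_trial", "walking_trials",
]


@dataclass
class ManifestEntry:
    participant_id: str
    static: StaticAssessment
    standing_trial: Path
    stn_trial: Path
    walking_trials: list[Path]


def write_cohort_manifest(path: str | Path, entries: Iterable[ManifestEntry]) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_FIELDS)
        writer.writeheader()
        for e in entries:
            s = e.static
            writer.writerow({
                "participant_id": e.participant_id,
                "ncsp_deg": repr(s.ncsp_deg),
                "rcsp_deg": repr(s.rcsp_deg),
                "ankle_dorsiflexion_deg": repr(s.ankle_dorsiflexion_deg),
                "first_mpj_dorsiflexion_deg": repr(s.first_mpj_dorsiflexion_deg),
                "first_ray": s.first_ray,
                "forefoot": s.forefoot,
                "fpi": s.fpi,
                "standing_trial": str(e.standing_trial),
                "stn_trial": str(e.stn_trial),
                "walking_trials": ";".join(str(p) for p in e.walking_trials),
            })


def read_cohort_manifest(path: str | Path) -> list[ManifestEntry]:
    path = Path(path)
    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"{path}: manifest missing columns {sorted(missing)}")
        for row in reader:
            pid = row["participant_id"]
            if pid in seen:
                raise ValidationError(f"duplicate participant id {pid!r}")
            seen.add(pid)
            static = StaticAssessment(
                ncsp_deg=float(row["ncsp_deg"]),
                rcsp_deg=float(row["rcsp_deg"]),
                ankle_dorsiflexion_deg=float(row["ankle_dorsiflexion_deg"]),
                first_mpj_dorsiflexion_deg=float(row["first_mpj_dorsiflexion_deg"]),
                first_ray=row["first_ray"],
                forefoot=row["forefoot"],
                fpi=int(row["fpi"]),
            )
            entries.append(ManifestEntry(
                participant_id=pid,
                static=static,
                standing_trial=Path(row["standing_trial"]),
                stn_trial=Path(row["stn_trial"]),
                walking_trials=[Path(p) for p in row["walking_trials"].split(";") if p],
            ))
    return entries


# ---------------------------------------------------------------------------
# run configuration and result tables
# ---------------------------------------------------------------------------

def read_run_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration into a plain mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: run config must be a mapping")
    return data


def write_json_report(path: str | Path, report: Mapping) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"cannot serialise {type(obj)}")
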