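"""Built-in 6-segment foot model.

Defines the segment chain (leg -> calcaneus -> midfoot -> {medial forefoot ->
hallux, lateral forefoot}), the marker-cluster geometry of each segment's
rigid plate, the anatomical calibration landmarks, and the five inter-segment
joints whose rotations the pipeline reports.

Geometry conventions (laboratory frame, left foot):

* x — mediolateral (subject's right is +x),
* y — anteroposterior, +y is the direction of progression,
* z — vertical, up.

All coordinates are millimetres in the reference (standing) posture with the
ankle-joint centre near the origin.  Cluster triangles are ~40 mm across —
non-degenerate enough for a stable rigid-body fit with optical-capture noise.
The anatomical landmarks are placed symmetrically about the x and z axes so
the leg local coordinate system of the reference posture coincides with the
laboratory axes; the pipeline never relies on this, it only simplifies the
synthetic ground truth.

MODEL_VERSION identifies this geometry; files written by the synthetic
generator record it so processed results can be traced to the geometry that
produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODEL_VERSION = "footkin-6seg-1"

PLANES = ("sagittal", "frontal", "transverse")

SEGMENTS = (
    "leg",
    "calcaneus",
    "midfoot",
    "medial_forefoot",
    "lateral_forefoot",
    "hallux",
)

#: The five inter-segment joints: name -> (proximal segment, distal segment).
JOINTS: dict[str, tuple[str, str]] = {
    "rearfoot": ("leg", "calcaneus"),
    "midfoot_calcaneus": ("calcaneus", "midfoot"),
    "medial_forefoot_midfoot": ("midfoot", "medial_forefoot"),
    "lateral_forefoot_midfoot": ("midfoot", "lateral_forefoot"),
    "hallux_medial_forefoot": ("medial_forefoot", "hallux"),
}

JOINT_NAMES = tuple(JOINTS)

#: Kinematic chain in parent-before-child order:
#: (joint name, parent segment, child segment, joint-centre position mm).
CHAIN: tuple[tuple[str, str, str, tuple[float, float, float]], ...] = (
    ("rearfoot", "leg", "calcaneus", (0.0, 0.0, 70.0)),
    ("midfoot_calcaneus", "calcaneus", "midfoot", (0.0, 55.0, 40.0)),
    ("medial_forefoot_midfoot", "midfoot", "medial_forefoot", (-18.0, 105.0, 32.0)),
    ("lateral_forefoot_midfoot", "midfoot", "lateral_forefoot", (24.0, 95.0, 28.0)),
    ("hallux_medial_forefoot", "medial_forefoot", "hallux", (-25.0, 170.0, 22.0)),
)

#: Rigid-plate cluster marker positions (mm) in the reference posture.
CLUSTERS: dict[str, dict[str, tuple[float, float, float]]] = {
    "leg": {
        "leg_1": (-30.0, 35.0, 285.0),
        "leg_2": (30.0, 35.0, 280.0),
        "leg_3": (-25.0, 30.0, 220.0),
        "leg_4": (25.0, 28.0, 215.0),
    },
    "calcaneus": {
        "cal_1": (-24.0, -52.0, 30.0),
        "cal_2": (24.0, -52.0, 30.0),
        "cal_3": (-15.0, -28.0, 80.0),
        "cal_4": (15.0, -28.0, 80.0),
    },
    "midfoot": {
        "mid_1": (-25.0, 48.0, 60.0),
        "mid_2": (25.0, 48.0, 60.0),
        "mid_3": (-15.0, 84.0, 28.0),
        "mid_4": (15.0, 84.0, 28.0),
    },
    "medial_forefoot": {
        "mff_1": (-46.0, 104.0, 46.0),
        "mff_2": (-4.0, 104.0, 46.0),
        "mff_3": (-46.0, 148.0, 12.0),
        "mff_4": (-4.0, 148.0, 12.0),
    },
    "lateral_forefoot": {
        "lff_1": (8.0, 96.0, 38.0),
        "lff_2": (44.0, 96.0, 38.0),
        "lff_3": (8.0, 132.0, 12.0),
        "lff_4": (44.0, 132.0, 12.0),
    },
    "hallux": {
        "hal_1": (-44.0, 172.0, 38.0),
        "hal_2": (-4.0, 172.0, 38.0),
        "hal_3": (-44.0, 216.0, 2.0),
        "hal_4": (-4.0, 216.0, 2.0),
    },
}

#: Anatomical calibration landmarks (standing reference trial only):
#: medial/lateral malleoli and medial/lateral knee-joint margins.
ANATOMICAL: dict[str, tuple[float, float, float]] = {
    "med_malleolus": (-45.0, 0.0, 80.0),
    "lat_malleolus": (45.0, 0.0, 80.0),
    "med_knee": (-50.0, 0.0, 460.0),
    "lat_knee": (50.0, 0.0, 460.0),
}

ANATOMICAL_LABELS = tuple(ANATOMICAL)


@dataclass(frozen=True)
class SegmentModel:
    """A versioned marker model: cluster geometries, landmarks and chain."""

    version: str = MODEL_VERSION
    segments: tuple[str, ...] = SEGMENTS
    joints: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(JOINTS))
    chain: tuple = CHAIN
    clusters: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {s: dict(m) for s, m in CLUSTERS.items()}
    )
    anatomical: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(ANATOMICAL)
    )

    @property
    def registry(self) -> dict[str, str]:
        """Marker label -> segment name (anatomical labels excluded)."""
        return {
            label: seg for seg, markers in self.clusters.items() for label in markers
        }

    def cluster_array(self, segment: str) -> tuple[list[str], np.ndarray]:
        """Labels and an (n, 3) coordinate array for one segment's cluster."""
        markers = self.clusters[segment]
        labels = sorted(markers)
        return labels, np.array([markers[k] for k in labels], dtype=float)

    def anatomical_array(self) -> tuple[list[str], np.ndarray]:
        labels = sorted(self.anatomical)
        return labels, np.array([self.anatomical[k] for k in labels], dtype=float)


DEFAULT_MODEL = SegmentModel()
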