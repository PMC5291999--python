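"""Marker trajectories to inter-segment Cardan angle curves.

The measurement chain implemented here:

1. A standing reference trial defines the leg local coordinate system (LCS)
   from four anatomical landmarks, records each segment's cluster geometry,
   and sets every foot-segment LCS parallel to the leg LCS — so all five
   inter-segment angles are 0 degrees by construction in that posture.
2. During walking, each segment's pose is tracked by a least-squares rigid
   (Procrustes) fit of its marker cluster against the reference geometry.
3. The rotation of each distal segment relative to its proximal neighbour is
   decomposed with the Cardan x-y-z sequence: sagittal (x, + dorsiflexion),
   frontal (y, + inversion / - eversion for the left foot), transverse (z).
4. Curves are low-pass filtered with a zero-phase Butterworth filter
   (default 6 Hz overall -3 dB) and can be time-normalised to the gait
   cycle or to stance (101 points, 0-100 %).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .errors import ContractError, GeometryError, ModelError, SchemaError, SignalError
from .io_formats import MarkerTrialBundle
from .model import DEFAULT_MODEL, JOINTS, PLANES, SegmentModel

log = logging.getLogger(__name__)

_GIMBAL_GUARD = 1.0 - 1e-12  # |sin(beta)| beyond this -> gimbal fallback


class GimbalWarning(UserWarning):
    """Middle Cardan angle within numerical reach of +/-90 degrees."""


@dataclass
class SegmentFrame:
    """Pose of a segment: rotation (LCS -> lab) and origin in mm."""

    rotation: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-9 or abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise GeometryError("rotation must be orthonormal with det +1")


# ---------------------------------------------------------------------------
# Cardan x-y-z
# ---------------------------------------------------------------------------

def compose_cardan(sagittal_deg: float, frontal_deg: float,
                   transverse_deg: float) -> np.ndarray:
    """Rotation matrix R = Rx(sagittal) @ Ry(frontal) @ Rz(transverse)."""
    a, b, g = np.radians([sagittal_deg, frontal_deg, transverse_deg])
    ca, sa, cb, sb, cg, sg = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(g), np.sin(g)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rx @ ry @ rz


def cardan_xyz(rotation: np.ndarray) -> tuple[float, float, float]:
    """Decompose R into x-y-z Cardan angles (degrees).

    Returns (sagittal, frontal, transverse) such that
    ``R = Rx(sagittal) @ Ry(frontal) @ Rz(transverse)``.  Near a gimbal lock
    (|frontal| -> 90 deg) only the sum/difference of the outer angles is
    defined; the fallback convention sets the transverse angle to 0 and
    emits :class:`GimbalWarning` — never a silent wrong answer.
    """
    r = np.asarray(rotation, dtype=float)
    sb = np.clip(r[0, 2], -1.0, 1.0)
    if abs(sb) >= _GIMBAL_GUARD:
        warnings.warn("gimbal proximity in Cardan x-y-z; transverse set to 0",
                      GimbalWarning, stacklevel=2)
        beta = np.copysign(np.pi / 2, sb)
        alpha = np.arctan2(r[1, 0], r[1, 1])
        gamma = 0.0
    else:
        beta = np.arcsin(sb)
        alpha = np.arctan2(-r[1, 2], r[2, 2])
        gamma = np.arctan2(-r[0, 1], r[0, 0])
    return tuple(np.degrees([alpha, beta, gamma]))


def _cardan_xyz_batch(r: np.ndarray) -> np.ndarray:
    """Vectorised Cardan x-y-z for an (n, 3, 3) stack; degrees, (n, 3)."""
    sb = np.clip(r[:, 0, 2], -1.0, 1.0)
    gimbal = np.abs(sb) >= _GIMBAL_GUARD
    beta = np.arcsin(sb)
    alpha = np.arctan2(-r[:, 1, 2], r[:, 2, 2])
    gamma = np.arctan2(-r[:, 0, 1], r[:, 0, 0])
    if gimbal.any():
        warnings.warn("gimbal proximity in Cardan x-y-z; transverse set to 0",
                      GimbalWarning, stacklevel=2)
        alpha[gimbal] = np.arctan2(r[gimbal, 1, 0], r[gimbal, 1, 1])
        gamma[gimbal] = 0.0
    return np.degrees(np.column_stack([alpha, beta, gamma]))


# ---------------------------------------------------------------------------
# leg LCS from anatomical landmarks
# ---------------------------------------------------------------------------

def build_leg_lcs(anatomical: Mapping[str, np.ndarray],
                  progression: Sequence[float] = (0.0, 1.0, 0.0)) -> SegmentFrame:
    """Leg LCS from the malleoli and knee-joint margins.

    z is the unit vector from the malleolar midpoint to the knee midpoint.
    The frontal plane is the least-squares plane through the four landmarks
    constrained to contain the z direction (a one-parameter rotation, solved
    in closed form as the smallest eigenvector of the 2x2 projected scatter).
    y is the plane's unit normal oriented toward the progression direction;
    x = y cross z completes the right-handed frame.
    """
    required = ("med_malleolus", "lat_malleolus", "med_knee", "lat_knee")
    try:
        pts = np.array([np.asarray(anatomical[k], dtype=float) for k in required])
    except KeyError as exc:
        raise ModelError(f"missing anatomical landmark {exc.args[0]!r}") from None
    mall_mid = 0.5 * (pts[0] + pts[1])
    knee_mid = 0.5 * (pts[2] + pts[3])
    z = knee_mid - mall_mid
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise GeometryError("malleolar and knee midpoints coincide")
    z = z / nz

    # orthonormal basis (u, v) of the plane perpendicular to z
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ z) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - (seed @ z) * z
    u /= np.linalg.norm(u)
    v = np.cross(z, u)

    centred = pts - pts.mean(axis=0)
    proj = centred @ np.column_stack([u, v])      # (4, 2)
    scatter = proj.T @ proj
    eigval, eigvec = np.linalg.eigh(scatter)
    if eigval[-1] < 1e-9:
        raise GeometryError("anatomical landmarks are collinear")
    normal2d = eigvec[:, 0]                        # smallest-eigenvalue direction
    y = normal2d[0] * u + normal2d[1] * v
    if y @ np.asarray(progression, dtype=float) < 0:
        y = -y
    x = np.cross(y, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)                             # re-orthogonalise
    return SegmentFrame(rotation=np.column_stack([x, y, z]), origin=mall_mid)


# ---------------------------------------------------------------------------
# rigid pose fit (Procrustes)
# ---------------------------------------------------------------------------

def _check_cluster(points: np.ndarray) -> None:
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if len(s) < 2 or s[1] <= 1e-8 * max(s[0], 1.0):
        raise GeometryError("marker cluster is collinear or coincident")


def fit_rigid_pose(reference: np.ndarray, frame: np.ndarray,
                   ) -> tuple[SegmentFrame, float]:
    """Least-squares rigid transform mapping ``reference`` onto ``frame``.

    Solves the absolute-orientation problem with the SVD (Kabsch) method:
    minimises sum ||R p_i + t - q_i||^2 over rotations R (det +1, no
    scaling) and translations t.  Returns the transform and the RMS point
    residual in mm.
    """
    p = np.asarray(reference, dtype=float)
    q = np.asarray(frame, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise SchemaError(f"paired point sets must share shape (n, 3); "
                          f"got {p.shape} and {q.shape}")
    if p.shape[0] < 3:
        raise GeometryError("rigid fit needs >= 3 paired points")
    _check_cluster(p)
    rot, t, rms = _fit_rigid_batch(p, q[np.newaxis])
    return SegmentFrame(rotation=rot[0], origin=t[0]), float(rms[0])


def fit_rigid_pose_labeled(reference: Mapping[str, np.ndarray],
                           frame: Mapping[str, np.ndarray],
                           ) -> tuple[SegmentFrame, float]:
    """Label-matched variant of :func:`fit_rigid_pose`."""
    if set(reference) != set(frame):
        missing = set(reference) ^ set(frame)
        raise SchemaError(f"mismatched marker labels: {sorted(missing)}")
    labels = sorted(reference)
    return fit_rigid_pose(np.array([reference[k] for k in labels]),
                          np.array([frame[k] for k in labels]))


def _fit_rigid_batch(reference: np.ndarray, frames: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Kabsch fit of one reference cluster to (m, n, 3) frames."""
    p0 = reference - reference.mean(axis=0)
    qc = frames.mean(axis=1, keepdims=True)
    q0 = frames - qc
    h = np.einsum("ki,mkj->mij", p0, q0)           # (m, 3, 3) covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("mij,mjk->mik",
                                        np.transpose(vt, (0, 2, 1)),
                                        np.transpose(u, (0, 2, 1)))))
    # rotation mapping reference -> frame: R = V diag(1,1,d) U^T
    v = np.transpose(vt, (0, 2, 1))
    v_adj = v.copy()
    v_adj[:, :, 2] *= d[:, np.newaxis]
    rot = np.einsum("mij,mkj->mik", v_adj, u)
    fitted = np.einsum("mij,kj->mki", rot, p0) + qc
    rms = np.sqrt(np.mean(np.sum((fitted - frames) ** 2, axis=2), axis=1))
    t = qc[:, 0, :] - np.einsum("mij,j->mi", rot, reference.mean(axis=0))
    return rot, t, rms


# ---------------------------------------------------------------------------
# zero-phase Butterworth low-pass
# ---------------------------------------------------------------------------

def _design_cutoff(cutoff_hz: float, order: int) -> float:
    """Per-pass cutoff pre-warped so the dual pass is -3 dB at cutoff_hz."""
    return cutoff_hz * (np.sqrt(2.0) - 1.0) ** (-1.0 / order)


def butterworth_lowpass(curve: np.ndarray, cutoff_hz: float = 6.0,
                        rate_hz: float = 100.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    ``order`` is the overall attenuation order: a Butterworth filter of
    order ``order // 2`` is applied forward and backward, and its per-pass
    cutoff is raised so the combined response is -3 dB at ``cutoff_hz``.
    DC gain is exactly 1 and the phase response identically zero.
    """
    if order % 2 or order < 2:
        raise SignalError(f"filter order must be even and >= 2, got {order}")
    if rate_hz <= 2.0 * cutoff_hz:
        raise SignalError(f"rate {rate_hz} Hz must exceed twice the cutoff "
                          f"{cutoff_hz} Hz")
    x = np.asarray(curve, dtype=float)
    per_pass = order // 2
    b, a = _signal.butter(per_pass, _design_cutoff(cutoff_hz, order), fs=rate_hz)
    padlen = 3 * max(len(a), len(b))
    if x.shape[-1] <= padlen:
        raise SignalError(f"curve of length {x.shape[-1]} shorter than the "
                          f"filter warm-up length {padlen + 1}")
    return _signal.filtfilt(b, a, x, axis=-1)


def butterworth_expected_gain(freq_hz: float | np.ndarray, cutoff_hz: float = 6.0,
                              order: int = 4) -> float | np.ndarray:
    """Analytic amplitude gain of the dual-pass filter at ``freq_hz``."""
    fd = _design_cutoff(cutoff_hz, order)
    return 1.0 / (1.0 + (np.asarray(freq_hz, dtype=float) / fd) ** order)


# ---------------------------------------------------------------------------
# angle series container
# ---------------------------------------------------------------------------

@dataclass
class InterSegmentAngleSeries:
    """Three-plane angle curves for the five joints of one trial.

    ``angles`` maps joint name -> (n, 3) degrees with columns
    (sagittal, frontal, transverse).  ``basis`` is ``"time"`` (raw frames at
    ``rate_hz``), ``"cycle"`` (0-100 % of the gait cycle, 101 points) or
    ``"stance"`` (0-100 % of stance, 101 points).
    """

    angles: dict[str, np.ndarray]
    basis: str = "time"
    rate_hz: float | None = 100.0
    trial_id: str = ""
    filter_cutoff_hz: float | None = None
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        lengths = {a.shape for a in self.angles.values()}
        if len({shape[0] for shape in lengths}) > 1:
            raise ContractError("joints have different curve lengths")
        if self.basis not in ("time", "cycle", "stance"):
            raise ContractError(f"unknown basis {self.basis!r}")
        if self.basis != "time" and self.n_samples != 101:
            raise ContractError("normalised series must have 101 samples")

    @property
    def n_samples(self) -> int:
        return next(iter(self.angles.values())).shape[0]

    @property
    def joints(self) -> tuple[str, ...]:
        return tuple(self.angles)

    def curve(self, joint: str, plane: str) -> np.ndarray:
        return self.angles[joint][:, PLANES.index(plane)]

    def times(self) -> np.ndarray:
        if self.basis == "time":
            return self.start_time_s + np.arange(self.n_samples) / self.rate_hz
        return np.linspace(0.0, 100.0, self.n_samples)

    def normalized(self, t0_s: float, t1_s: float, basis: str,
                   n_points: int = 101) -> "InterSegmentAngleSeries":
        """Linearly resample the window [t0_s, t1_s] to ``n_points``."""
        if self.basis != "time":
            raise ContractError("can only normalise a time-based series")
        if not t1_s > t0_s:
            raise ContractError("window end must follow window start")
        t = self.times()
        if t0_s < t[0] - 1e-9 or t1_s > t[-1] + 1e-9:
            raise ContractError(
                f"window [{t0_s:.3f}, {t1_s:.3f}] s outside trial span "
                f"[{t[0]:.3f}, {t[-1]:.3f}] s")
        grid = np.linspace(t0_s, t1_s, n_points)
        resampled = {
            joint: np.column_stack([np.interp(grid, t, arr[:, i])
                                    for i in range(3)])
            for joint, arr in self.angles.items()
        }
        return InterSegmentAngleSeries(
            angles=resampled, basis=basis, rate_hz=None,
            trial_id=self.trial_id, filter_cutoff_hz=self.filter_cutoff_hz)


def mean_across_trials(series_list: Sequence[InterSegmentAngleSeries],
                       ) -> InterSegmentAngleSeries:
    """Pointwise mean of >= 1 angle series on a common normalised base."""
    if not series_list:
        raise ContractError("need at least one series to average")
    first = series_list[0]
    for s in series_list[1:]:
        if s.basis != first.basis or s.basis == "time":
            raise ContractError("all series must share a normalised basis")
        if s.n_samples != first.n_samples or s.joints != first.joints:
            raise ContractError("series have mismatched shape")
    mean_angles = {
        joint: np.mean([s.angles[joint] for s in series_list], axis=0)
        for joint in first.joints
    }
    return InterSegmentAngleSeries(
        angles=mean_angles, basis=first.basis, rate_hz=None,
        trial_id=f"mean_of_{len(series_list)}",
        filter_cutoff_hz=first.filter_cutoff_hz)


# ---------------------------------------------------------------------------
# calibration and tracking
# ---------------------------------------------------------------------------

@dataclass
class SegmentCalibration:
    """Reference geometry captured from the standing trial.

    Stores the leg LCS and, per segment, the cluster's reference marker
    coordinates (frame-averaged, lab space).  Because every foot-segment LCS
    is defined parallel to the leg LCS in this posture, all inter-segment
    angles computed on the standing reference are identically zero.
    """

    leg_lcs: SegmentFrame
    reference_clusters: dict[str, tuple[list[str], np.ndarray]]
    model_version: str = ""

    def segments(self) -> tuple[str, ...]:
        return tuple(self.reference_clusters)


def calibrate_segments(standing: MarkerTrialBundle,
                       model: SegmentModel = DEFAULT_MODEL) -> SegmentCalibration:
    """Build per-segment reference geometry from a standing reference trial."""
    positions = standing.mean_positions()
    missing = [lab for lab in model.anatomical if lab not in positions
               or not np.all(np.isfinite(positions[lab]))]
    if missing:
        raise ModelError(f"standing trial missing anatomical markers: {missing}")
    leg_lcs = build_leg_lcs({lab: positions[lab] for lab in model.anatomical})

    reference: dict[str, tuple[list[str], np.ndarray]] = {}
    for segment in model.segments:
        cluster_labels = sorted(model.clusters[segment])
        pts = []
        for lab in cluster_labels:
            if lab not in positions or not np.all(np.isfinite(positions[lab])):
                raise ModelError(
                    f"standing trial missing cluster marker {lab!r} "
                    f"for segment {segment!r}")
            pts.append(positions[lab])
        arr = np.array(pts)
        _check_cluster(arr)
        reference[segment] = (cluster_labels, arr)
    return SegmentCalibration(leg_lcs=leg_lcs, reference_clusters=reference,
                              model_version=model.version)


def _segment_rotations(trial: MarkerTrialBundle,
                       calibration: SegmentCalibration,
                       ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-frame lab rotations of each segment relative to its reference.

    Returns (rotations, valid) where rotations[seg] has shape (n, 3, 3) and
    ``valid`` flags frames on which every segment had a complete cluster.
    """
    n = trial.n_frames
    valid = np.ones(n, dtype=bool)
    rotations: dict[str, np.ndarray] = {}
    for segment, (labels, ref) in calibration.reference_clusters.items():
        try:
            stacked = np.stack([trial.markers[lab] for lab in labels], axis=1)
        except KeyError as exc:
            raise ModelError(f"trial {trial.trial_id!r} missing marker "
                             f"{exc.args[0]!r} for segment {segment!r}") from None
        seg_valid = np.all(np.isfinite(stacked), axis=(1, 2))
        valid &= seg_valid
        safe = stacked.copy()
        safe[~seg_valid] = ref  # placeholder; flagged invalid, never reported
        rot, _, _ = _fit_rigid_batch(ref, safe)
        rotations[segment] = rot
    if not valid.all():
        log.warning("trial %s: %d/%d frames dropped for missing markers",
                    trial.trial_id, int((~valid).sum()), n)
    return rotations, valid


def compute_joint_angles(trial: MarkerTrialBundle,
                         calibration: SegmentCalibration,
                         cutoff_hz: float | None = 6.0,
                         filter_order: int = 4) -> InterSegmentAngleSeries:
    """Filtered, zero-referenced Cardan angle curves for the five joints.

    Per frame: segment poses by rigid cluster fit, relative rotation of each
    distal segment in its proximal neighbour's LCS, Cardan x-y-z
    decomposition, then zero-phase low-pass filtering (``cutoff_hz=None``
    disables filtering).  Zero reference is inherited from the calibration:
    the standing posture maps to the identity rotation at every joint.
    Frames with an incomplete cluster on any segment are excluded (NaN) and
    logged.
    """
    rotations, valid = _segment_rotations(trial, calibration)
    r0 = calibration.leg_lcs.rotation
    angles: dict[str, np.ndarray] = {}
    for joint, (proximal, distal) in JOINTS.items():
        rel = np.einsum("ji,mjk,kl->mil",
                        r0, np.einsum("mji,mjk->mik",
                                      rotations[proximal], rotations[distal]), r0)
        curves = _cardan_xyz_batch(rel)
        curves[~valid] = np.nan
        angles[joint] = curves

    if cutoff_hz is not None:
        for joint, arr in angles.items():
            angles[joint] = _filter_valid_runs(arr, valid, cutoff_hz,
                                               trial.marker_rate_hz, filter_order)
    return InterSegmentAngleSeries(
        angles=angles, basis="time", rate_hz=trial.marker_rate_hz,
        trial_id=trial.trial_id, filter_cutoff_hz=cutoff_hz)


def _filter_valid_runs(arr: np.ndarray, valid: np.ndarray, cutoff_hz: float,
                       rate_hz: float, order: int) -> np.ndarray:
    """Filter each contiguous run of valid frames; short runs stay NaN."""
    out = np.full_like(arr, np.nan)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        run = idx[s:e + 1]
        try:
            out[run] = butterworth_lowpass(arr[run].T, cutoff_hz, rate_hz, order).T
        except SignalError:
            log.warning("run of %d frames too short to filter; left missing",
                        run.size)
    return out
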