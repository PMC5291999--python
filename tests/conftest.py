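"""Shared fixtures: deterministic standing trials, calibrations and cohorts."""

import numpy as np
import pytest

import footkin as fk
from footkin.synthetic import markers_from_waveforms, static_trial_waveforms


@pytest.fixture(scope="session")
def model():
    return fk.DEFAULT_MODEL


@pytest.fixture(scope="session")
def standing_bundle():
    """Noise-free standing reference trial in the model's reference posture."""
    return markers_from_waveforms(
        static_trial_waveforms(0.0), noise_sd_mm=0.0, seed=0,
        trial_id="standing", kind="standing_reference",
        lead_s=0.0, trail_s=0.0)


@pytest.fixture(scope="session")
def calibration(standing_bundle):
    return fk.calibrate_segments(standing_bundle)


@pytest.fixture(scope="session")
def small_cohort():
    """Three synthetic participants with two marker trials each."""
    return fk.generate_cohort(fk.CohortConfig(n=3, trial_count=2, seed=42))


@pytest.fixture(scope="session")
def small_results(small_cohort):
    return fk.process_synthetic_cohort(small_cohort)


def rigid_pose_quaternion(reference: np.ndarray, frame: np.ndarray):
    """Independent absolute-orientation oracle (Horn's quaternion method).

    Returns (rotation, translation) mapping ``reference`` onto ``frame``;
    implemented from the eigendecomposition of Horn's 4x4 matrix, sharing no
    code with the package's SVD fit.
    """
    p = np.asarray(reference, float)
    q = np.asarray(frame, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    s = pc.T @ qc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    eigval, eigvec = np.linalg.eigh(n)
    w, x, y, z = eigvec[:, np.argmax(eigval)]
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = q.mean(axis=0) - rot @ p.mean(axis=0)
    return rot, t
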