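"""Cardan decomposition, leg LCS, rigid fit, filtering and angle tracking."""

import numpy as np
import pytest
from numpy.testing import assert_allclose
from scipy.spatial.transform import Rotation

import footkin as fk
from footkin.errors import ContractError, GeometryError, ModelError, SignalError
from footkin.kinematics import GimbalWarning, butterworth_expected_gain
from footkin.synthetic import markers_from_waveforms, generate_angle_waveforms

from conftest import rigid_pose_quaternion


# ---------------------------------------------------------------------------
# Cardan x-y-z
# ---------------------------------------------------------------------------

def test_compose_cardan_matches_scipy_rotation():
    rng = np.random.default_rng(1)
    for _ in range(200):
        a, b, g = rng.uniform(-80, 80, 3)
        ours = fk.compose_cardan(a, b, g)
        oracle = Rotation.from_euler("XYZ", [a, b, g], degrees=True).as_matrix()
        assert_allclose(ours, oracle, atol=1e-12)


def test_cardan_known_values():
    assert_allclose(fk.cardan_xyz(np.eye(3)), (0.0, 0.0, 0.0), atol=1e-12)
    assert_allclose(fk.cardan_xyz(fk.compose_cardan(30.0, 0.0, 0.0)),
                    (30.0, 0.0, 0.0), atol=1e-12)
    assert_allclose(fk.cardan_xyz(fk.compose_cardan(0.0, -45.0, 0.0)),
                    (0.0, -45.0, 0.0), atol=1e-12)
    assert_allclose(fk.cardan_xyz(fk.compose_cardan(0.0, 0.0, 12.5)),
                    (0.0, 0.0, 12.5), atol=1e-12)


def test_cardan_round_trip_random():
    rng = np.random.default_rng(2)
    for _ in range(500):
        a = rng.uniform(-179, 179)
        b = rng.uniform(-85, 85)
        g = rng.uniform(-179, 179)
        back = fk.cardan_xyz(fk.compose_cardan(a, b, g))
        assert_allclose(back, (a, b, g), atol=1e-9)


def test_cardan_gimbal_warning_and_consistent_fallback():
    r = fk.compose_cardan(25.0, 90.0, 0.0)
    with pytest.warns(GimbalWarning):
        a, b, g = fk.cardan_xyz(r)
    assert g == 0.0
    assert_allclose(fk.compose_cardan(a, b, g), r, atol=1e-9)


# ---------------------------------------------------------------------------
# leg LCS
# ---------------------------------------------------------------------------

def test_leg_lcs_of_reference_landmarks_is_lab_frame(model):
    frame = fk.build_leg_lcs({k: np.array(v)
                              for k, v in model.anatomical.items()})
    assert_allclose(frame.rotation, np.eye(3), atol=1e-12)
    assert_allclose(frame.origin, [0.0, 0.0, 80.0], atol=1e-12)


def test_leg_lcs_equivariant_under_rotation(model):
    rng = np.random.default_rng(3)
    for _ in range(20):
        q = Rotation.random(random_state=rng).as_matrix()
        shift = rng.normal(0, 100, 3)
        rotated = {k: q @ np.array(v, float) + shift
                   for k, v in model.anatomical.items()}
        # keep +y of the rotated frame pointing along the rotated progression
        frame = fk.build_leg_lcs(rotated, progression=q @ [0.0, 1.0, 0.0])
        assert_allclose(frame.rotation, q, atol=1e-9)
        assert_allclose(frame.origin, q @ [0.0, 0.0, 80.0] + shift, atol=1e-9)


def test_leg_lcs_collinear_landmarks_raise():
    pts = {"med_malleolus": [0.0, 0.0, 0.0], "lat_malleolus": [0.0, 0.0, 10.0],
           "med_knee": [0.0, 0.0, 100.0], "lat_knee": [0.0, 0.0, 110.0]}
    with pytest.raises(GeometryError):
        fk.build_leg_lcs({k: np.array(v) for k, v in pts.items()})


def test_leg_lcs_missing_landmark_raises(model):
    partial = {k: np.array(v) for k, v in model.anatomical.items()}
    partial.pop("med_knee")
    with pytest.raises(ModelError):
        fk.build_leg_lcs(partial)


# ---------------------------------------------------------------------------
# rigid pose fit
# ---------------------------------------------------------------------------

def test_fit_rigid_pose_exact_transform():
    rng = np.random.default_rng(4)
    p = rng.normal(0, 40, (4, 3))
    r_true = Rotation.from_rotvec([0.2, -0.1, 0.4]).as_matrix()
    t_true = np.array([10.0, -5.0, 3.0])
    frame, rms = fk.fit_rigid_pose(p, p @ r_true.T + t_true)
    assert_allclose(frame.rotation, r_true, atol=1e-10)
    assert_allclose(frame.origin, t_true, atol=1e-9)
    assert rms < 1e-9


def test_fit_rigid_pose_matches_quaternion_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.normal(0, 40, (5, 3))
        q = (p @ Rotation.random(random_state=rng).as_matrix().T
             + rng.normal(0, 80, 3) + rng.normal(0, 0.5, p.shape))
        frame, _ = fk.fit_rigid_pose(p, q)
        rot_o, t_o = rigid_pose_quaternion(p, q)
        assert np.abs(frame.rotation - rot_o).max() < 1e-6
        assert np.abs(frame.origin - t_o).max() < 1e-6


def test_fit_rigid_pose_rejects_degenerate_input():
    with pytest.raises(GeometryError):
        fk.fit_rigid_pose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    with pytest.raises(GeometryError):
        fk.fit_rigid_pose(line, line)


def test_fit_rigid_pose_no_reflection():
    # a noisy near-planar cluster must still give det(R) = +1
    rng = np.random.default_rng(6)
    p = np.column_stack([rng.normal(0, 40, (4, 2)), np.zeros(4)])
    p[0, 2] = 0.01
    q = p[:, [1, 0, 2]] * [1, 1, -1] + rng.normal(0, 1.0, p.shape)
    frame, _ = fk.fit_rigid_pose(p, q)
    assert np.linalg.det(frame.rotation) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Butterworth filter
# ---------------------------------------------------------------------------

def test_filter_dc_gain_is_unity():
    out = fk.butterworth_lowpass(np.full(500, 3.7))
    assert_allclose(out, 3.7, atol=1e-9)


def _measured_gain(freq_hz, rate_hz=100.0, duration_s=40.0):
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    x = np.sin(2 * np.pi * freq_hz * t)
    y = fk.butterworth_lowpass(x, rate_hz=rate_hz)
    # project the central section onto the input tone (zero-phase filter)
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    return float(y[mid] @ x[mid] / (x[mid] @ x[mid]))


def test_filter_gains_match_analytic_response():
    for freq in (1.0, 3.0, 6.0, 40.0):
        expected = butterworth_expected_gain(freq)
        assert abs(_measured_gain(freq) - expected) < 0.01
    # the cutoff frequency sits at -3 dB overall (amplitude 1/sqrt(2))
    assert butterworth_expected_gain(6.0) == pytest.approx(2 ** -0.5)
    assert _measured_gain(6.0) == pytest.approx(2 ** -0.5, abs=0.01)


def test_filter_contracts():
    with pytest.raises(SignalError):
        fk.butterworth_lowpass(np.zeros(500), order=3)
    with pytest.raises(SignalError):
        fk.butterworth_lowpass(np.zeros(500), cutoff_hz=60.0, rate_hz=100.0)
    with pytest.raises(SignalError):
        fk.butterworth_lowpass(np.zeros(9))  # at or below the warm-up length


# ---------------------------------------------------------------------------
# series container and averaging
# ---------------------------------------------------------------------------

def _flat_series(value=2.0, n=101, basis="stance"):
    angles = {j: np.full((n, 3), value) for j in fk.JOINT_NAMES}
    return fk.InterSegmentAngleSeries(angles=angles, basis=basis, rate_hz=None)


def test_series_contracts():
    with pytest.raises(ContractError):
        _flat_series(basis="weird")
    with pytest.raises(ContractError):
        _flat_series(n=50)           # normalised series must have 101 samples
    series = _flat_series(basis="stance")
    with pytest.raises(ContractError):
        series.normalized(0.0, 1.0, basis="cycle")


def test_normalized_window_outside_span_raises():
    angles = {j: np.zeros((100, 3)) for j in fk.JOINT_NAMES}
    series = fk.InterSegmentAngleSeries(angles=angles, basis="time", rate_hz=100.0)
    with pytest.raises(ContractError):
        series.normalized(0.5, 2.0, basis="cycle")


def test_mean_across_trials_pointwise():
    mean = fk.mean_across_trials([_flat_series(1.0), _flat_series(3.0)])
    assert_allclose(mean.curve("rearfoot", "sagittal"), 2.0)
    with pytest.raises(ContractError):
        fk.mean_across_trials([])
    with pytest.raises(ContractError):
        fk.mean_across_trials([_flat_series(), _flat_series(basis="cycle")])


# ---------------------------------------------------------------------------
# calibration and tracking
# ---------------------------------------------------------------------------

def test_standing_reference_angles_are_zero(standing_bundle, calibration):
    series = fk.compute_joint_angles(standing_bundle, calibration,
                                     cutoff_hz=None)
    for joint in fk.JOINT_NAMES:
        assert np.abs(series.angles[joint]).max() < 1e-9


def test_zero_noise_tracking_recovers_waveforms(calibration):
    waveforms = generate_angle_waveforms({
        ("rearfoot", "sagittal"): {"offset": -2.0,
                                   "harmonics": [(1, 7.0, 0.45)]},
        ("rearfoot", "frontal"): {"offset": 1.0,
                                  "harmonics": [(1, -4.0, 0.28), (2, 1.0, 0.1)]},
        ("hallux_medial_forefoot", "sagittal"): {"offset": 10.0,
                                                 "harmonics": [(1, 30.0, 0.58)]},
    })
    trial = markers_from_waveforms(waveforms, noise_sd_mm=0.0, seed=1,
                                   kind="walking")
    series = fk.compute_joint_angles(trial, calibration, cutoff_hz=None)
    t = series.times()
    phi = np.mod((t - 0.2) / waveforms.cycle_duration_s, 1.0)
    for (joint, plane), curve in waveforms.curves.items():
        measured = series.curve(joint, plane)
        assert np.abs(measured - curve.evaluate(phi)).max() < 0.01


def test_missing_marker_frames_are_nan(standing_bundle, calibration):
    markers = {k: v.copy() for k, v in standing_bundle.markers.items()}
    markers["cal_1"][3] = np.nan
    trial = fk.MarkerTrialBundle(
        trial_id="gap", kind="standing_reference", markers=markers,
        registry=standing_bundle.registry,
        anatomical_labels=standing_bundle.anatomical_labels)
    series = fk.compute_joint_angles(trial, calibration, cutoff_hz=None)
    assert np.all(np.isnan(series.angles["rearfoot"][3]))
    assert np.all(np.isfinite(np.delete(series.angles["rearfoot"], 3, axis=0)))


def test_calibration_requires_anatomical_markers(standing_bundle):
    markers = {k: v for k, v in standing_bundle.markers.items()
               if k != "med_knee"}
    trial = fk.MarkerTrialBundle(
        trial_id="bad", kind="standing_reference", markers=markers,
        registry=standing_bundle.registry,
        anatomical_labels=tuple(l for l in standing_bundle.anatomical_labels
                                if l != "med_knee"))
    with pytest.raises(ModelError):
        fk.calibrate_segments(trial)
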