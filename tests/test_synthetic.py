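"""Harmonic waveforms, forward kinematics, force traces and cohort draws."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

import footkin as fk
from footkin.errors import ConfigurationError
from footkin.synthetic import (AngleWaveformSet, HarmonicCurve,
                               markers_from_waveforms, static_trial_waveforms,
                               synthetic_force_trace, true_heel_lift_pct,
                               true_stn_crossing)


# ---------------------------------------------------------------------------
# harmonic curves
# ---------------------------------------------------------------------------

def test_harmonic_evaluate_matches_manual_sum():
    curve = HarmonicCurve(offset=1.5, harmonics=((1, 3.0, 0.2), (3, -0.5, 0.7)))
    phi = np.linspace(0, 1, 97)
    manual = (1.5 + 3.0 * np.cos(2 * np.pi * (phi - 0.2))
              - 0.5 * np.cos(6 * np.pi * (phi - 0.7)))
    assert_allclose(curve.evaluate(phi), manual, atol=1e-12)


def test_harmonic_derivative_matches_finite_differences():
    curve = HarmonicCurve(offset=-2.0, harmonics=((2, 4.0, 0.1),))
    phi = np.linspace(0.05, 0.95, 50)
    h = 1e-6
    numeric = (curve.evaluate(phi + h) - curve.evaluate(phi - h)) / (2 * h)
    assert_allclose(curve.derivative(phi), numeric, atol=1e-5)


def test_harmonic_extremum_single_term_analytic():
    curve = HarmonicCurve(offset=2.0, harmonics=((1, 5.0, 0.3),))
    value, phi = curve.extremum_in_window(0.0, 1.0, kind="max")
    assert value == pytest.approx(7.0, abs=1e-6)
    assert phi == pytest.approx(0.3, abs=1e-3)
    value, phi = curve.extremum_in_window(0.0, 1.0, kind="min")
    assert value == pytest.approx(-3.0, abs=1e-6)
    assert phi == pytest.approx(0.8, abs=1e-3)


def test_harmonic_contracts():
    with pytest.raises(ConfigurationError):
        HarmonicCurve(harmonics=((0, 1.0, 0.0),))
    with pytest.raises(ConfigurationError):
        HarmonicCurve(harmonics=tuple((1, 1.0, 0.0) for _ in range(5)))
    with pytest.raises(ConfigurationError):
        AngleWaveformSet(curves={}, stance_fraction=0.9)


def test_jittered_changes_only_dominant_amplitude():
    curve = HarmonicCurve(offset=1.0, harmonics=((1, 5.0, 0.3), (2, 0.5, 0.1)))
    shifted = curve.jittered(0.7)
    assert shifted.offset == 1.0
    assert shifted.harmonics[0] == (1, 5.7, 0.3)
    assert shifted.harmonics[1] == (2, 0.5, 0.1)


def test_generate_angle_waveforms_rejects_unknown_channel():
    with pytest.raises(ConfigurationError):
        fk.generate_angle_waveforms({("shank", "sagittal"): {"offset": 1.0}})


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def test_zero_waveforms_give_reference_marker_positions(model):
    trial = markers_from_waveforms(static_trial_waveforms(0.0),
                                   noise_sd_mm=0.0, seed=0,
                                   kind="walking")
    for segment in model.segments:
        for label, pos in model.clusters[segment].items():
            assert_allclose(trial.markers[label],
                            np.broadcast_to(pos, trial.markers[label].shape),
                            atol=1e-12)


def test_constant_rearfoot_rotation_moves_calcaneus_chain(model):
    """A fixed rearfoot angle rotates every distal segment about its centre."""
    waveforms = fk.generate_angle_waveforms(
        {("rearfoot", "sagittal"): {"offset": 20.0}})
    trial = markers_from_waveforms(waveforms, noise_sd_mm=0.0, seed=0,
                                   kind="walking")
    r = fk.compose_cardan(20.0, 0.0, 0.0)
    centre = np.array([0.0, 0.0, 70.0])     # rearfoot joint centre
    for label, pos in model.clusters["calcaneus"].items():
        expected = r @ (np.asarray(pos) - centre) + centre
        assert_allclose(trial.markers[label][0], expected, atol=1e-9)
    # the hallux inherits the same transform through the chain
    for label, pos in model.clusters["hallux"].items():
        expected = r @ (np.asarray(pos) - centre) + centre
        assert_allclose(trial.markers[label][0], expected, atol=1e-9)
    # the leg does not move
    for label, pos in model.clusters["leg"].items():
        assert_allclose(trial.markers[label][0], pos, atol=1e-12)


def test_markers_deterministic_per_seed():
    waveforms = static_trial_waveforms(3.0)
    a = markers_from_waveforms(waveforms, seed=7, kind="walking")
    b = markers_from_waveforms(waveforms, seed=7, kind="walking")
    c = markers_from_waveforms(waveforms, seed=8, kind="walking")
    assert_allclose(a.markers["cal_1"], b.markers["cal_1"], atol=0)
    assert np.abs(a.markers["cal_1"] - c.markers["cal_1"]).max() > 0


def test_standing_kind_carries_anatomical_markers():
    standing = markers_from_waveforms(static_trial_waveforms(0.0),
                                      noise_sd_mm=0.0, seed=0,
                                      kind="standing_reference",
                                      lead_s=0.0, trail_s=0.0)
    assert set(standing.anatomical_labels) == {
        "med_malleolus", "lat_malleolus", "med_knee", "lat_knee"}
    walking = markers_from_waveforms(static_trial_waveforms(0.0),
                                     noise_sd_mm=0.0, seed=0, kind="walking")
    assert "med_knee" not in walking.markers


# ---------------------------------------------------------------------------
# force trace
# ---------------------------------------------------------------------------

def test_force_trace_supported_exactly_on_stance():
    rate = 1500.0
    force = synthetic_force_trace(int(1.4 * rate), heel_strike_s=0.2,
                                  stance_duration_s=0.62, rate_hz=rate)
    t = np.arange(force.size) / rate
    inside = (t > 0.2 - 1e-9) & (t < 0.82 + 1e-9)
    assert np.all(force[~inside] == 0.0)
    assert np.all(force[inside] >= 0.0)
    # boundary samples may carry float-rounding residue, nothing physical
    assert force[np.abs(t - 0.82) < 1e-9].max(initial=0.0) < 1e-9
    assert force[inside].max() == pytest.approx(800.0, rel=0.01)
    # double hump: local minimum near mid-stance between two maxima
    mid = force[(t > 0.45) & (t < 0.55)].mean()
    first = force[(t > 0.3) & (t < 0.4)].max()
    assert mid < first


# ---------------------------------------------------------------------------
# ground-truth scans
# ---------------------------------------------------------------------------

def test_true_heel_lift_is_after_sagittal_peak():
    waveforms = fk.generate_angle_waveforms(
        {("rearfoot", "sagittal"): {"offset": 0.0,
                                    "harmonics": [(1, 7.0, 0.45)]}})
    hl = true_heel_lift_pct(waveforms)
    # peak dorsiflexion at cycle phase 0.45 = 72.6% of stance
    assert 72.0 < hl < 75.0


def test_true_heel_lift_fallback_when_never_plantarflexing():
    rising = fk.generate_angle_waveforms({})     # all-zero curves: velocity 0
    assert true_heel_lift_pct(rising) == 60.0


def test_true_stn_crossing_analytic_case():
    # frontal curve 5*cos(2 pi phi): crosses 2.5 deg at phi = 1/6
    waveforms = fk.generate_angle_waveforms(
        {("rearfoot", "frontal"): {"harmonics": [(1, 5.0, 0.0)]}})
    passed, timing = true_stn_crossing(waveforms, 2.5, window="stance")
    assert passed
    assert timing == pytest.approx(100.0 / 6.0, abs=0.01)
    passed, timing = true_stn_crossing(waveforms, 9.0, window="stance")
    assert not passed
    assert timing == pytest.approx(0.0, abs=0.01)   # closest at heel strike


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def test_cohort_config_validation():
    with pytest.raises(ConfigurationError):
        fk.CohortConfig(n=1)
    with pytest.raises(ConfigurationError):
        fk.CohortConfig(noise_sd_mm=-1.0)
    with pytest.raises(ConfigurationError):
        fk.CohortConfig(rho={"ncsp_eversion": 1.5})
    with pytest.raises(ConfigurationError):
        fk.CohortConfig(prevalence={"ankle_equinus": 1.2})
    with pytest.raises(ConfigurationError):
        fk.CohortConfig(prevalence={"first_ray_plantarflexed": 0.7,
                                    "first_ray_dorsiflexed": 0.5})
    with pytest.raises(ConfigurationError):
        fk.CohortConfig(group_effects={"not_a_deformity": 1.0})


def test_cohort_deterministic_per_seed():
    a = fk.generate_cohort(fk.CohortConfig(n=3, seed=5), include_markers=False)
    b = fk.generate_cohort(fk.CohortConfig(n=3, seed=5), include_markers=False)
    for pa, pb in zip(a, b):
        assert pa.static == pb.static
        assert pa.true_variables.as_dict() == pb.true_variables.as_dict()


def test_cohort_forced_prevalence():
    cfg = fk.CohortConfig(n=40, seed=9, prevalence={
        "rearfoot_varus": 0.97, "ankle_equinus": 1.0, "hallux_limited": 1.0,
        "first_ray_plantarflexed": 1.0, "first_ray_dorsiflexed": 0.0,
        "forefoot_varus": 0.0, "forefoot_valgus": 1.0})
    cohort = fk.generate_cohort(cfg, include_markers=False)
    assert all(p.static.ankle_dorsiflexion_deg < 10.0 for p in cohort)
    assert all(p.static.first_mpj_dorsiflexion_deg < 65.0 for p in cohort)
    assert all(p.static.first_ray == "plantarflexed" for p in cohort)
    assert all(p.static.forefoot == "valgus" for p in cohort)


def test_cohort_rho_one_gives_perfect_correlation():
    cfg = fk.CohortConfig(n=60, seed=2, rho={"ncsp_eversion": 1.0,
                                             "ankle_dorsiflexion": 0.0,
                                             "hallux_dorsiflexion": 0.0})
    cohort = fk.generate_cohort(cfg, include_markers=False)
    ncsp = np.array([p.static.ncsp_deg for p in cohort])
    ever = np.array([p.true_dynamics["peak_rearfoot_eversion_midstance"]
                     for p in cohort])
    assert np.corrcoef(ncsp, ever)[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_cohort_rho_zero_gives_no_correlation():
    cfg = fk.CohortConfig(n=300, seed=4, rho={"ncsp_eversion": 0.0,
                                              "ankle_dorsiflexion": 0.0,
                                              "hallux_dorsiflexion": 0.0})
    cohort = fk.generate_cohort(cfg, include_markers=False)
    ncsp = np.array([p.static.ncsp_deg for p in cohort])
    ever = np.array([p.true_variables.peak_rearfoot_eversion_midstance
                     for p in cohort])
    assert abs(np.corrcoef(ncsp, ever)[0, 1]) < 3.0 / np.sqrt(300)


def test_cohort_waveform_trough_hits_drawn_target():
    cohort = fk.generate_cohort(fk.CohortConfig(n=10, seed=6),
                                include_markers=False)
    for p in cohort:
        target = p.true_dynamics["peak_rearfoot_eversion_midstance"]
        measured = p.true_variables.peak_rearfoot_eversion_midstance
        # the trough constraint is iterated until the realised mid-stance
        # minimum equals the drawn target
        assert measured == pytest.approx(target, abs=1e-3)


def test_group_effect_shifts_affected_variable():
    base = fk.CohortConfig(n=400, seed=10, rho={"ncsp_eversion": 0.0,
                                                "ankle_dorsiflexion": 0.0,
                                                "hallux_dorsiflexion": 0.0})
    cohort = fk.generate_cohort(base, include_markers=False)
    shifted_cfg = fk.CohortConfig(n=400, seed=10, rho=base.rho,
                                  group_effects={"ankle_equinus": -3.0})
    shifted = fk.generate_cohort(shifted_cfg, include_markers=False)
    for p0, p1 in zip(cohort, shifted):
        delta = (p1.true_dynamics["peak_rearfoot_dorsiflexion_midstance"]
                 - p0.true_dynamics["peak_rearfoot_dorsiflexion_midstance"])
        expected = -3.0 if p0.static.ankle_dorsiflexion_deg < 10.0 else 0.0
        assert delta == pytest.approx(expected, abs=1e-9)


def test_write_cohort_round_trip(tmp_path):
    cohort = fk.generate_cohort(fk.CohortConfig(n=2, trial_count=1, seed=3))
    manifest = fk.synthetic.write_cohort(cohort, tmp_path)
    entries = fk.read_cohort_manifest(manifest)
    assert [e.participant_id for e in entries] == ["P001", "P002"]
    assert entries[0].static.ncsp_deg == cohort[0].static.ncsp_deg
    trial = fk.read_marker_trial(entries[0].walking_trials[0], kind="walking")
    original = cohort[0].trials[0]
    assert trial.force is not None
    assert_allclose(trial.markers["cal_1"], original.markers["cal_1"],
                    atol=1e-6)
    assert_allclose(trial.force, original.force, atol=1e-6)


def test_write_cohort_without_markers_raises(tmp_path):
    cohort = fk.generate_cohort(fk.CohortConfig(n=2, seed=3),
                                include_markers=False)
    with pytest.raises(ConfigurationError):
        fk.synthetic.write_cohort(cohort, tmp_path)
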