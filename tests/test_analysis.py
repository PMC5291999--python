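"""End-to-end processing pipeline, the analysis model and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import footkin as fk
from footkin.analysis import COMPARISON_GRID, CORRELATION_GRID, truth_frame
from footkin.cli import main as cli_main
from footkin.errors import ContractError


# ---------------------------------------------------------------------------
# processing pipeline
# ---------------------------------------------------------------------------

def test_clean_cohort_recovers_truth_closely():
    """No marker noise, no waveform jitter: measured variables hit the truth."""
    cfg = fk.CohortConfig(n=2, trial_count=2, seed=11,
                          noise_sd_mm=0.0, amplitude_jitter_deg=0.0)
    cohort = fk.generate_cohort(cfg)
    results = fk.process_synthetic_cohort(cohort)
    for p, r in zip(cohort, results):
        truth = p.true_variables.as_dict()
        measured = r.variables.as_dict()
        for name in truth:
            assert measured[name] == pytest.approx(truth[name], abs=0.1), name
        assert r.stn_angle_deg == pytest.approx(p.stn_angle_deg, abs=0.05)
        assert r.stn.passed == p.true_stn_passed_stance
        assert r.stn.timing_pct == pytest.approx(p.true_stn_timing_pct, abs=1.5)


def test_noisy_cohort_stays_jitter_bounded(small_cohort, small_results):
    """0.5 mm noise and <1 deg amplitude jitter keep errors within ~2.5 deg.

    The range variable combines errors of two extrema, so the bound is looser
    than the per-peak one.
    """
    for p, r in zip(small_cohort, small_results):
        truth = p.true_variables.as_dict()
        measured = r.variables.as_dict()
        for name in truth:
            assert abs(measured[name] - truth[name]) < 2.5, name
        assert r.n_trials == 2
        assert r.profile.count == fk.classify_deformities(p.static).count


def test_manifest_pipeline_equals_in_memory_pipeline(tmp_path, small_cohort,
                                                     small_results):
    manifest = fk.write_cohort(small_cohort, tmp_path)
    from_disk = fk.process_cohort_from_manifest(manifest)
    for mem, disk in zip(small_results, from_disk):
        assert mem.participant_id == disk.participant_id
        for name, value in mem.variables.as_dict().items():
            assert disk.variables.as_dict()[name] == pytest.approx(value,
                                                                   abs=1e-5)
        assert disk.stn.passed == mem.stn.passed


def test_truth_frame_matches_statics():
    cohort = fk.generate_cohort(fk.CohortConfig(n=5, seed=1),
                                include_markers=False)
    df, profiles, stn = truth_frame(cohort)
    assert len(df) == len(profiles) == len(stn) == 5
    for p, prof in zip(cohort, profiles):
        assert prof.rearfoot_varus == (p.static.ncsp_deg > 0.0)
        assert prof.ankle_equinus == (p.static.ankle_dorsiflexion_deg < 10.0)
    assert list(df["ncsp_deg"]) == [p.static.ncsp_deg for p in cohort]


# ---------------------------------------------------------------------------
# analysis model
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted():
    cohort = fk.generate_cohort(fk.CohortConfig(n=80, seed=21),
                                include_markers=False)
    df, profiles, stn = truth_frame(cohort)
    return fk.CohortAnalysis(df, profiles, stn).fit()


def test_fit_covers_the_full_grid(fitted):
    expected_cells = [(name, var) for name, _, vars_ in COMPARISON_GRID
                      for var in vars_]
    assert [(c.family, c.variable) for c in fitted.comparisons] == expected_cells
    assert [c.pair for c in fitted.correlations] == list(CORRELATION_GRID)
    assert fitted.n == 80


def test_result_lookup_and_errors(fitted):
    c = fitted.comparison("ankle_equinus", "peak_rearfoot_dorsiflexion_midstance")
    assert c.family == "ankle_equinus"
    with pytest.raises(KeyError):
        fitted.comparison("ankle_equinus", "not_a_variable")
    r = fitted.correlation("ncsp_deg", "peak_rearfoot_eversion_midstance")
    assert r.n == 80
    with pytest.raises(KeyError):
        fitted.correlation("ncsp_deg", "not_a_variable")


def test_rearfoot_varus_cell_is_skipped_at_high_prevalence(fitted):
    c = fitted.comparison("rearfoot_varus", "peak_rearfoot_eversion_midstance")
    assert c.skipped
    assert "comparator" in c.note


def test_summary_and_report_round_trip(fitted, tmp_path):
    text = fitted.summary()
    assert "Cohort analysis of 80 feet" in text
    assert "Subtalar neutral" in text
    assert "Correlations" in text
    fitted.save(tmp_path)
    report = json.loads((tmp_path / "stats_report.json").read_text())
    assert report["n"] == 80
    assert len(report["comparisons"]) == len(fitted.comparisons)
    assert (tmp_path / "comparisons.csv").exists()
    assert (tmp_path / "correlations.csv").exists()
    frame = pd.read_csv(tmp_path / "deformity_counts.csv")
    assert frame["n_feet"].sum() == 80


def test_analysis_contracts():
    cohort = fk.generate_cohort(fk.CohortConfig(n=3, seed=2),
                                include_markers=False)
    df, profiles, _ = truth_frame(cohort)
    with pytest.raises(ContractError):
        fk.CohortAnalysis(df, profiles[:2])
    with pytest.raises(ContractError):
        fk.CohortAnalysis(df.iloc[:1], profiles[:1])


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

def test_cli_run_all_writes_reports(tmp_path):
    config = tmp_path / "run.yaml"
    # correlations need n >= 3, so this is the smallest end-to-end run
    config.write_text("cohort:\n  n: 3\n  trial_count: 1\n  seed: 5\n")
    runner = CliRunner()
    result = runner.invoke(cli_main, ["run-all", "--config", str(config),
                                      "--out", str(tmp_path / "out")])
    assert result.exit_code == 0, result.output
    assert (tmp_path / "out/cohort/manifest.csv").exists()
    report = json.loads(
        (tmp_path / "out/analysis/stats_report.json").read_text())
    assert report["n"] == 3
    assert "Cohort analysis of 3 feet" in result.output


def test_cli_process_writes_variables(tmp_path):
    cohort = fk.generate_cohort(fk.CohortConfig(n=2, trial_count=1, seed=6))
    manifest = fk.write_cohort(cohort, tmp_path / "cohort")
    runner = CliRunner()
    result = runner.invoke(cli_main, ["process", "--manifest", str(manifest),
                                      "--out", str(tmp_path / "proc")])
    assert result.exit_code == 0, result.output
    frame = pd.read_csv(tmp_path / "proc/variables.csv")
    assert len(frame) == 2
    assert "peak_rearfoot_eversion_midstance" in frame.columns
    stn = json.loads((tmp_path / "proc/stn_results.json").read_text())
    assert set(stn) == {"P001", "P002"}


def test_cli_rejects_unknown_config_keys(tmp_path):
    config = tmp_path / "run.yaml"
    config.write_text("cohort:\n  cohort_size: 2\n")
    runner = CliRunner()
    result = runner.invoke(cli_main, ["simulate", "--config", str(config),
                                      "--out", str(tmp_path / "out")])
    assert result.exit_code != 0
    assert "unknown CohortConfig keys" in result.output
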