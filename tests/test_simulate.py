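"""Simulator contracts: waveform structure, peak distribution, determinism."""

import numpy as np
import pytest

from grfest import (SENSOR_LOCATIONS, SimulationConfig, SubjectParams,
                    export_raw_fixture, label_phases, simulate_study,
                    simulate_trial)
from grfest.phase import phase_names

SUBJ = SubjectParams("S01", 54.7)


@pytest.mark.parametrize("landing_type", ["unilateral", "bilateral"])
def test_flight_grf_is_exactly_zero(landing_type):
    cfg = SimulationConfig(seed=1)
    trial = simulate_trial(cfg, landing_type, SUBJ, seed=3)
    flight = trial.phase == "flight"
    assert flight.any()
    assert np.all(trial.grf_bw_sensor[flight] == 0.0)
    assert np.all(trial.grf_bw >= 0.0)


def test_degenerate_peak_distribution_hits_mean_exactly():
    cfg = SimulationConfig(peak_sd_unilateral=0.0)
    for seed in range(5):
        trial = simulate_trial(cfg, "unilateral", SUBJ, seed=seed)
        assert trial.grf_bw.max() == pytest.approx(2.35, abs=1e-9)
        assert trial.grf_bw_sensor.max() == pytest.approx(2.35, abs=1e-9)


def test_peak_sample_mean_matches_configured_normal():
    # Monte-Carlo against the configured Normal(2.35, 0.38), truncated at 1.2
    # (truncation mass there is negligible, < 1e-3)
    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(99)
    peaks = [simulate_trial(cfg, "unilateral", SUBJ, rng).peak_bw
             for _ in range(1000)]
    se = 0.38 / np.sqrt(len(peaks))
    assert abs(np.mean(peaks) - 2.35) < 3 * se


def test_exactly_one_contiguous_flight_interval():
    cfg = SimulationConfig(seed=2)
    trial = simulate_trial(cfg, "bilateral", SUBJ, seed=8)
    flight = (trial.phase == "flight").astype(int)
    starts = np.sum(np.diff(flight) == 1)
    assert starts == 1 and flight[0] == 0 and flight[-1] == 0


def test_sacrum_coupling_and_flight_freefall_noiseless(noiseless_trial):
    t = noiseless_trial
    sac_z = t.sensor_accel["sacrum"][:, 2]
    ground = t.phase == "ground"
    np.testing.assert_allclose(sac_z[ground] + 1.0, t.grf_bw_sensor[ground],
                               atol=1e-12)
    np.testing.assert_allclose(sac_z[~ground], -1.0, atol=1e-12)
    # limb accelerations stay nonzero while airborne
    for loc in ("thigh_l", "shin_r"):
        assert np.all(np.abs(t.sensor_accel[loc][~ground][:, 2]) > 0.1)


def test_threshold_rule_reproduces_phase_series(noiseless_trial):
    labels = label_phases(noiseless_trial.grf_bw_sensor)
    assert (phase_names(labels) == noiseless_trial.phase).all()


def test_study_counts_and_determinism():
    cfg = SimulationConfig(n_subjects=4, jumps_per_type=3, seed=42)
    study_a = simulate_study(cfg)
    study_b = simulate_study(cfg)
    assert len(study_a) == 4
    for ds in study_a:
        assert len(ds.trials) == 6  # 3 jumps x 2 landing types
        assert {t.landing_type for t in ds.trials} == {"unilateral", "bilateral"}
    for da, db in zip(study_a, study_b):
        assert da.mass == db.mass
        for ta, tb in zip(da.trials, db.trials):
            np.testing.assert_array_equal(ta.grf_bw, tb.grf_bw)
            np.testing.assert_array_equal(ta.sensor_accel["shin_l"],
                                          tb.sensor_accel["shin_l"])


def test_subject_mass_distribution():
    cfg = SimulationConfig(n_subjects=2000, jumps_per_type=1,
                           landing_types=("unilateral",),
                           noise_sd_per_sensor=0.0, seed=77)
    masses = [ds.mass for ds in simulate_study(cfg)]
    se = 3.3 / np.sqrt(len(masses))
    assert abs(np.mean(masses) - 54.7) < 3 * se


@pytest.mark.parametrize("bad", [
    dict(n_subjects=0),
    dict(sample_rate_sensor=0),
    dict(peak_mean_unilateral=0.9),
    dict(flight_duration=(0.5, 0.3)),
    dict(noise_sd_per_sensor=-0.1),
    dict(landing_types=("hop",)),
])
def test_config_validation(bad):
    with pytest.raises(ValueError):
        SimulationConfig(**bad)


def test_landing_type_outside_config_rejected():
    cfg = SimulationConfig(landing_types=("unilateral",))
    with pytest.raises(ValueError, match="landing type"):
        simulate_trial(cfg, "bilateral", SUBJ, seed=0)


def test_fixture_force_csv_in_newtons(tmp_path):
    trial = simulate_trial(SimulationConfig(), "unilateral", SUBJ, seed=4)
    export_raw_fixture(trial, tmp_path)
    files = {p.name for p in tmp_path.iterdir()}
    assert files == {f"{loc}.csv" for loc in SENSOR_LOCATIONS} | {"forceplate.csv"}
    lines = (tmp_path / "forceplate.csv").read_text().splitlines()
    # first plate sample is quiet stance at 1 BW for a 54.7 kg subject
    force0 = float(lines[1].split(",")[1])
    assert force0 == pytest.approx(54.7 * 9.81, rel=1e-6)
    assert force0 == pytest.approx(536.6, abs=0.5)
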