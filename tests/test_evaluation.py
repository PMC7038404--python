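"""Metrics, fold plans, subset enumeration, the sweep, and Bland-Altman."""

import copy
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from grfest import (bland_altman, enumerate_subsets, make_folds, pearson_r,
                    peak_agreement, rmse_bw, run_combination_search,
                    run_refinement, SimulationConfig, simulate_study)
from grfest.pipeline import fit_bundle


# ----------------------------------------------------------------- metrics

def test_metric_closed_forms():
    truth = np.array([0.0, 0.5, 1.0, 2.0])
    assert rmse_bw(truth, truth) == 0.0
    assert pearson_r(truth, truth) == pytest.approx(1.0)
    assert rmse_bw(truth + 0.1, truth) == pytest.approx(0.1)
    assert pearson_r(truth + 0.1, truth) == pytest.approx(1.0)
    assert pearson_r(-truth, truth) == pytest.approx(-1.0)


@given(st.floats(0.01, 100.0),
       st.lists(st.floats(-5, 5), min_size=2, max_size=20),
       st.lists(st.floats(-5, 5), min_size=2, max_size=20))
def test_rmse_scale_covariance(a, p, t):
    n = min(len(p), len(t))
    p, t = np.asarray(p[:n]), np.asarray(t[:n])
    assert rmse_bw(a * p, a * t) == pytest.approx(a * rmse_bw(p, t), rel=1e-9)


def test_pearson_rejects_zero_variance():
    with pytest.raises(ValueError):
        pearson_r(np.ones(5), np.arange(5.0))


# ------------------------------------------------------------------- folds

@pytest.mark.parametrize("n,scheme,expected", [
    (14, "leave_two_out", 91),
    (23, "leave_one_out", 23),
    (5, "leave_two_out", 10),
    (5, "leave_one_out", 5),
])
def test_fold_counts(n, scheme, expected):
    ids = [f"S{i:02d}" for i in range(n)]
    plan = make_folds(ids, scheme)
    assert len(plan) == expected
    k = 2 if scheme == "leave_two_out" else 1
    assert expected == math.comb(n, k)
    seen = set()
    for train, test in plan.folds:
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(ids)
        seen.add(test)
    assert len(seen) == expected  # each test subset exactly once


def test_fold_order_deterministic():
    a = make_folds(["c", "a", "b"], "leave_one_out")
    assert [t for _, t in a.folds] == [("a",), ("b",), ("c",)]


@pytest.mark.parametrize("m,expected", [(6, 63), (1, 1), (3, 7)])
def test_subset_counts(m, expected):
    locs = [f"loc{i}" for i in range(m)]
    subsets = enumerate_subsets(locs)
    assert len(subsets) == expected == 2 ** m - 1
    assert len(set(subsets)) == expected
    sizes = [len(s) for s in subsets]
    assert sizes == sorted(sizes)  # ordered by size then lexicographic


# ------------------------------------------------------------------- sweep

def test_dry_run_counts_planned_fits():
    rep = run_combination_search(n_subjects=14, dry_run=True)
    assert rep.n_fits == 63 * 91 * 2 == 11466
    rep1 = run_combination_search(n_subjects=3, dry_run=True,
                                  locations=("a", "b"),
                                  landing_types=("unilateral",))
    assert rep1.n_fits == 3 * 3 * 1


@pytest.fixture(scope="module")
def mini_study():
    cfg = SimulationConfig(n_subjects=3, jumps_per_type=2,
                           landing_types=("unilateral",), seed=17)
    return simulate_study(cfg)


def test_small_search_counts_and_ranks(mini_study):
    rep = run_combination_search(mini_study, landing_types=("unilateral",),
                                 locations=("sacrum", "thoracic"), seed=0)
    assert rep.n_fits == 3 * 3  # 3 subsets x C(3,2) folds x 1 landing type
    assert not rep.failures
    assert [r.rank for r in rep.results] == list(range(1, len(rep.results) + 1))
    rmses = [r.combined_rmse for r in rep.results]
    assert rmses == sorted(rmses)


def test_noise_sensor_ranks_below_sacrum(mini_study):
    noisy = copy.deepcopy(mini_study)
    rng = np.random.default_rng(5)
    for ds in noisy:
        for t in ds.trials:
            t.sensor_accel["thoracic"] = rng.normal(
                0, 1.0, t.sensor_accel["thoracic"].shape)
    rep = run_combination_search(
        noisy, landing_types=("unilateral",), seed=0,
        subsets=[("sacrum",), ("thoracic",)])
    by_subset = {r.subset: r.rank for r in rep.results}
    assert by_subset[("sacrum",)] < by_subset[("thoracic",)]


def test_refinement_leave_one_out(mini_study):
    rep = run_refinement(mini_study, "sacrum",
                         landing_types=("unilateral",), seed=0)
    assert rep.n_fits == 3  # 3 subjects, leave-one-out, single subset
    assert rep.results[0].subset == ("sacrum",)


def test_peak_agreement_runs(mini_study):
    bundle = fit_bundle(mini_study[:2], "unilateral", ("sacrum",), seed=1)
    out = peak_agreement({"unilateral": bundle}, mini_study[2:])
    ba = out["unilateral"]
    assert ba.n_pairs == 2
    assert ba.limits_of_agreement[0] <= ba.mean_difference \
        <= ba.limits_of_agreement[1]


# ------------------------------------------------------------ Bland-Altman

def test_bland_altman_identical_pairs():
    ba = bland_altman([2.0, 2.5, 3.0], [2.0, 2.5, 3.0])
    assert ba.mean_difference == 0.0
    assert ba.limits_of_agreement == (0.0, 0.0)


def test_bland_altman_constant_offset():
    model = np.array([2.0, 2.5, 3.0, 2.2])
    ba = bland_altman(model, model + 0.11)
    assert ba.mean_difference == pytest.approx(0.11)
    assert ba.sd_difference == pytest.approx(0.0, abs=1e-12)


def test_bland_altman_hand_computed_pairs():
    plate = np.array([2.4, 2.1, 3.0, 2.8, 2.6])
    model = np.array([2.2, 2.3, 2.7, 2.9, 2.4])
    diff = plate - model
    ba = bland_altman(model, plate)
    assert ba.mean_difference == pytest.approx(diff.mean())
    sd = diff.std(ddof=1)
    assert ba.limits_of_agreement == pytest.approx(
        (diff.mean() - 1.96 * sd, diff.mean() + 1.96 * sd))
    assert ba.n_pairs == 5


@given(st.lists(st.floats(1.2, 4.0), min_size=2, max_size=15),
       st.lists(st.floats(1.2, 4.0), min_size=2, max_size=15))
def test_bland_altman_limit_ordering(model, plate):
    n = min(len(model), len(plate))
    ba = bland_altman(model[:n], plate[:n])
    lo, hi = ba.limits_of_agreement
    assert lo <= ba.mean_difference <= hi
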