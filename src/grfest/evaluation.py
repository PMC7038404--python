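"""Evaluation machinery: agreement metrics (RMSE in BW, Pearson r,
Bland–Altman), subject-level cross-validation fold plans, and the exhaustive
sensor-combination search that ranks every non-empty subset of the six
sensor placements by held-out combined-model accuracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .phase import (FLIGHT, GROUND, ClassifierSpec, build_point_sets,
                    evaluate_classifier, trial_phase_codes)
from .pipeline import estimate_profile, fit_bundle, peak_grf, trial_grf_100
from .simulate import SENSOR_LOCATIONS


# ---------------------------------------------------------------- metrics

def rmse_bw(predicted, truth) -> float:
    """Root-mean-square error of a predicted GRF curve, in BW."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sqrt(np.mean((predicted - truth) ** 2)))


def pearson_r(predicted, truth) -> float:
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape or predicted.size < 2:
        raise ValueError("need equal-length series of >= 2 samples")
    if np.std(truth) == 0 or np.std(predicted) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(stats.pearsonr(predicted, truth).statistic)


@dataclass
class BlandAltmanSummary:
    """Agreement between paired peak measurements: mean difference and
    1.96-SD limits of agreement, with differences taken plate - model."""

    mean_difference: float
    sd_difference: float
    limits_of_agreement: tuple[float, float]
    n_pairs: int


def bland_altman(model_peaks, plate_peaks) -> BlandAltmanSummary:
    model_peaks = np.asarray(model_peaks, dtype=float)
    plate_peaks = np.asarray(plate_peaks, dtype=float)
    if model_peaks.shape != plate_peaks.shape:
        raise ValueError("peak arrays must be paired (equal length)")
    n = model_peaks.size
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = plate_peaks - model_peaks
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanSummary(mean_difference=mean, sd_difference=sd,
                              limits_of_agreement=(mean - 1.96 * sd,
                                                   mean + 1.96 * sd),
                              n_pairs=int(n))


# ---------------------------------------------------------------- folds

@dataclass
class FoldPlan:
    scheme: str
    subject_ids: tuple
    folds: list[tuple[tuple, tuple]]  # (train_ids, test_ids)

    def __len__(self) -> int:
        return len(self.folds)


def make_folds(subject_ids, scheme: str) -> FoldPlan:
    """Subject-level cross-validation folds.

    ``leave_two_out`` enumerates all C(n, 2) held-out pairs;
    ``leave_one_out`` all n singletons.  Order is lexicographic in the sorted
    subject ids, so fold plans are deterministic.
    """
    ids = tuple(sorted(subject_ids))
    if scheme == "leave_two_out":
        k = 2
    elif scheme == "leave_one_out":
        k = 1
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if len(ids) <= k:
        raise ValueError(f"need more than {k} subjects for {scheme}")
    folds = []
    for test in itertools.combinations(ids, k):
        train = tuple(s for s in ids if s not in test)
        folds.append((train, test))
    return FoldPlan(scheme=scheme, subject_ids=ids, folds=folds)


def enumerate_subsets(locations=SENSOR_LOCATIONS) -> list[tuple[str, ...]]:
    """All 2^m - 1 non-empty sensor subsets, ordered by size then
    lexicographically within a size."""
    locations = tuple(locations)
    subsets: list[tuple[str, ...]] = []
    for r in range(1, len(locations) + 1):
        subsets.extend(sorted(itertools.combinations(sorted(locations), r)))
    return subsets


# ---------------------------------------------------------------- search

@dataclass
class SearchResult:
    subset: tuple[str, ...]
    landing_type: str
    flight_rmse: float
    ground_rmse: float
    combined_rmse: float
    correlation: float
    svm_percent_correct: float
    n_folds: int
    rank: int = 0


@dataclass
class SearchReport:
    results: list[SearchResult]
    n_fits: int
    failures: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])


def _evaluate_fold(bundle, test_datasets, landing_type, aggregate="averaged"):
    """Per-trial combined/phase-wise RMSE and r on held-out subjects."""
    rows = []
    for ds in test_datasets:
        for trial in ds.trials_of(landing_type):
            truth = trial_grf_100(trial)
            est, phase_pred = estimate_profile(bundle, trial)
            codes = trial_phase_codes(trial)
            row = {"combined_rmse": rmse_bw(est, truth),
                   "correlation": pearson_r(est, truth)}
            for name, code in (("flight", FLIGHT), ("ground", GROUND)):
                m = codes == code
                row[f"{name}_rmse"] = (
                    rmse_bw(est[m], truth[m]) if m.sum() >= 2 else np.nan)
            rows.append(row)
    df = pd.DataFrame(rows)
    if aggregate == "averaged":
        return df.mean()
    pooled = {c: float(np.sqrt(np.mean(df[c] ** 2))) if c.endswith("rmse")
              else float(df[c].mean()) for c in df.columns}
    return pd.Series(pooled)


def run_combination_search(datasets=None, landing_types=("unilateral", "bilateral"),
                           scheme: str = "leave_two_out",
                           subsets=None, locations=SENSOR_LOCATIONS,
                           top_k: int = 10, seed: int = 0,
                           dry_run: bool = False,
                           aggregate: str = "averaged",
                           fit_kwargs: dict | None = None,
                           classifier_spec: ClassifierSpec | None = None,
                           n_subjects: int | None = None) -> SearchReport:
    """The exhaustive sensor-subset sweep.

    For every non-empty sensor subset, every cross-validation fold, and every
    landing type, a combined model is trained on the fold's training subjects
    and evaluated on the held-out subjects; subsets are then ranked by mean
    combined RMSE (ties: higher mean correlation, then fewer sensors) and the
    top ``top_k`` retained.

    ``dry_run=True`` enumerates every (subset, fold, landing-type) cell and
    counts the model fits the sweep would perform without training anything —
    six sensors, 14 subjects and both landing types plan 63 x 91 x 2 = 11,466
    fits.
    """
    if subsets is None:
        subsets = enumerate_subsets(locations)
    if datasets is not None:
        subject_ids = [ds.subject_id for ds in datasets]
    elif n_subjects is not None:
        subject_ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
    else:
        raise ValueError("provide datasets or n_subjects")
    plan = make_folds(subject_ids, scheme)
    fit_kwargs = dict(fit_kwargs or {})

    n_fits = 0
    failures: list[dict] = []
    if dry_run:
        for subset in subsets:
            for _train, _test in plan.folds:
                for _lt in landing_types:
                    n_fits += 1
        return SearchReport(results=[], n_fits=n_fits)

    if len(subject_ids) < 3:
        raise ValueError("need at least 3 subjects to train and hold out")
    by_id = {ds.subject_id: ds for ds in datasets}
    results: list[SearchResult] = []
    for subset in subsets:
        base = classifier_spec or ClassifierSpec()
        cspec = replace(base, sensor_subset=tuple(subset), seed=seed)
        for lt in landing_types:
            per_fold: list[pd.Series] = []
            svm_pcts: list[float] = []
            for train_ids, test_ids in plan.folds:
                train = [by_id[s] for s in train_ids]
                test = [by_id[s] for s in test_ids]
                try:
                    Xtr, ytr, Xte, yte = build_point_sets(train, test, cspec)
                    bundle = fit_bundle(train, lt, subset, seed=seed,
                                        svm_points=(Xtr, ytr), **fit_kwargs)
                    n_fits += 1
                    cm = evaluate_classifier(bundle.estimator.classifier_,
                                             Xte, yte)
                    svm_pcts.append(cm.percent_overall)
                    per_fold.append(_evaluate_fold(bundle, test, lt, aggregate))
                except Exception as exc:  # record and continue the sweep
                    failures.append({"subset": subset, "fold": test_ids,
                                     "landing_type": lt, "error": repr(exc)})
            if not per_fold:
                continue
            agg = pd.concat(per_fold, axis=1).mean(axis=1)
            results.append(SearchResult(
                subset=tuple(subset), landing_type=lt,
                flight_rmse=float(agg["flight_rmse"]),
                ground_rmse=float(agg["ground_rmse"]),
                combined_rmse=float(agg["combined_rmse"]),
                correlation=float(agg["correlation"]),
                svm_percent_correct=float(np.mean(svm_pcts)),
                n_folds=len(per_fold)))

    results.sort(key=lambda r: (r.landing_type, r.combined_rmse,
                                -r.correlation, len(r.subset)))
    kept: list[SearchResult] = []
    for lt in sorted({r.landing_type for r in results}):
        group = [r for r in results if r.landing_type == lt]
        for i, r in enumerate(group):
            r.rank = i + 1
        kept.extend(group[:top_k])
    return SearchReport(results=kept, n_fits=n_fits, failures=failures)


def run_refinement(datasets, sensor: str = "sacrum",
                   landing_types=("unilateral", "bilateral"),
                   seed: int = 0, **kwargs) -> SearchReport:
    """Single-sensor leave-one-out refinement over a larger cohort."""
    return run_combination_search(datasets, landing_types=landing_types,
                                  scheme="leave_one_out",
                                  subsets=[(sensor,)], seed=seed, **kwargs)


def peak_agreement(bundles: dict, datasets, use_true_phase: bool = False
                   ) -> dict[str, BlandAltmanSummary]:
    """Bland-Altman agreement of model vs plate peak GRF per landing type.

    ``bundles`` maps landing type -> fitted ModelBundle.  With
    ``use_true_phase`` the ground-phase restriction uses plate-derived labels
    instead of the classifier's (a validation-only mode; deployment has no
    plate).
    """
    out = {}
    for lt, bundle in bundles.items():
        model_peaks, plate_peaks = [], []
        for ds in datasets:
            for trial in ds.trials_of(lt):
                truth = trial_grf_100(trial)
                est, phase_pred = estimate_profile(bundle, trial)
                codes = trial_phase_codes(trial)
                if use_true_phase:
                    phase_pred = codes
                model_peaks.append(peak_grf(est, phase_pred))
                plate_peaks.append(peak_grf(truth, codes))
        out[lt] = bland_altman(model_peaks, plate_peaks)
    return out
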