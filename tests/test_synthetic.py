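"""Tests of the set-point cohort generator and the recovery harness."""

import dataclasses

import numpy as np
import pytest

from thyrocap import (
    GroupSpec,
    HormonePair,
    SyntheticSpec,
    cohort_table,
    compute_gt,
    default_spec,
    generate,
    recovery_experiment,
    summarize_strata,
)
from thyrocap.synthetic import GeneratorConfigError, _EUTHYROID_DEFAULT


def test_default_spec_is_the_study_conditions():
    spec = default_spec()
    by_name = {g.name: g for g in spec.groups}
    assert by_name["euthyroid"].n == 313
    assert by_name["SH"].n == 183
    assert by_name["SH"].tsh_range == (4.5, 15.0)
    assert by_name["SH"].ft4_range == (10.43, 24.5)
    assert spec.noise_cv_tsh == spec.noise_cv_ft4 == 0.05


def test_determinism_under_seed():
    a, truth_a = generate(default_spec(seed=5))
    b, truth_b = generate(default_spec(seed=5))
    assert a == b
    assert truth_a.equals(truth_b)
    c, _ = generate(default_spec(seed=6))
    assert a != c


def test_zero_noise_roundtrips_true_capacity():
    spec = dataclasses.replace(default_spec(seed=2), noise_cv_tsh=0.0, noise_cv_ft4=0.0)
    subjects, truth = generate(spec)
    by_id = truth.set_index("id")
    for s in subjects:
        gt = compute_gt(HormonePair(s.tsh, s.ft4)).gt
        true_gt = by_id.loc[s.id, "gt_true_pmol_s"]
        assert gt == pytest.approx(true_gt, rel=1e-12)


def test_generated_subjects_respect_group_ranges():
    subjects, truth = generate(default_spec(seed=11))
    by_id = {s.id: s for s in subjects}
    for _, row in truth.iterrows():
        s = by_id[row["id"]]
        assert s.tsh > 0 and s.ft4 > 0 and s.age >= 0 and s.sex in ("M", "F")
        if row["group"] == "SH":
            assert 4.5 < s.tsh <= 15.0
            assert 10.43 <= s.ft4 <= 24.5  # the admissible SH FT4 window
        else:
            assert 0.6 < s.tsh <= 4.5


def test_group_moments_converge_without_range_rejection():
    # with an unbounded TSH window and a capacity distribution far from
    # the feasibility floor, accepted draws are the raw distributions
    g = GroupSpec(name="eu", n=10000, gt_median=3.0, gt_log_sigma=0.15,
                  ft4_mean=16.3, ft4_sd=2.19, tsh_range=(1e-9, 1e9))
    _, truth = generate(SyntheticSpec(groups=(g,), seed=7))
    ft4 = truth["ft4_true"].to_numpy()
    log_gt = np.log(truth["gt_true_pmol_s"].to_numpy())
    n = len(truth)
    assert abs(ft4.mean() - 16.3) < 2 * 2.19 / np.sqrt(n)
    assert abs(ft4.std(ddof=1) - 2.19) < 2 * 2.19 / np.sqrt(2 * n)
    assert abs(log_gt.mean() - np.log(3.0)) < 2 * 0.15 / np.sqrt(n)
    assert abs(log_gt.std(ddof=1) - 0.15) < 2 * 0.15 / np.sqrt(2 * n)


def test_measured_capacity_median_tracks_generator_median():
    # Monte-Carlo oracle: euthyroid group generated around a true median
    # of 2.5 pmol/s keeps its measured-GT median within 0.15 at 5% noise
    eu = dataclasses.replace(_EUTHYROID_DEFAULT, gt_median=2.5)
    medians = []
    for i in range(200):
        subjects, _ = generate(SyntheticSpec(groups=(eu,), seed=1000 + i))
        table = cohort_table(subjects)
        medians.append(float(table["gt_actual_pmol_s"].median()))
    assert abs(np.mean(medians) - 2.5) < 0.15


def test_infeasible_configuration_reports_feasible_region():
    bad = dataclasses.replace(_EUTHYROID_DEFAULT, gt_median=0.5, gt_log_sigma=0.05)
    with pytest.raises(GeneratorConfigError, match="GT >"):
        generate(SyntheticSpec(groups=(bad,), seed=0))


def test_antibody_positivity_rate_matches_probability():
    spec = dataclasses.replace(
        default_spec(seed=3),
        groups=(dataclasses.replace(_EUTHYROID_DEFAULT, n=5000, ab_positive_prob=0.2),),
    )
    subjects, _ = generate(spec)
    positive = sum((s.tg_ab > 34) or (s.tpo_ab > 34) for s in subjects)
    assert positive / len(subjects) == pytest.approx(0.2, abs=0.02)


def test_recovery_zero_noise_has_zero_error():
    spec = dataclasses.replace(default_spec(seed=4), noise_cv_tsh=0.0, noise_cv_ft4=0.0)
    res = recovery_experiment(spec, 10)
    # zero up to float roundoff through the algebraic inversion
    assert all(abs(b) < 1e-12 for b in res.bias)
    assert all(r < 1e-12 for r in res.rmse)


def test_recovery_rmse_nondecreasing_in_tsh_noise():
    rmses = []
    for cv in (0.0, 0.04, 0.10):
        spec = dataclasses.replace(default_spec(seed=42), noise_cv_tsh=cv,
                                   noise_cv_ft4=0.0)
        res = recovery_experiment(spec, 30)
        rmses.append(float(np.mean(res.rmse[:5])))  # Q1..Q4 + mild (severe is tiny)
    assert rmses[0] < 1e-12  # noiseless TSH: roundoff only
    assert rmses[0] <= rmses[1] <= rmses[2]


def test_stratum_mean_capacity_decreases_with_common_ft4_distribution():
    # with identical FT4 distributions across groups, capacity is monotone
    # decreasing in TSH, so stratum mean GT must fall from Q1 to severe SH
    eu = dataclasses.replace(_EUTHYROID_DEFAULT, gt_ft4_log_corr=0.0)
    sh = GroupSpec(name="SH", n=183, gt_median=1.75, gt_log_sigma=0.15,
                   ft4_mean=eu.ft4_mean, ft4_sd=eu.ft4_sd, tsh_range=(4.5, 15.0),
                   gt_ft4_log_corr=0.0)
    for seed in (0, 1, 2):
        subjects, _ = generate(SyntheticSpec(groups=(eu, sh), seed=seed))
        summaries = [s for s in summarize_strata(cohort_table(subjects)) if s.n > 0]
        means = [s.gt_actual_mean for s in summaries]
        assert all(a >= b for a, b in zip(means, means[1:]))


def test_sh_subjects_sit_above_predicted_curve():
    subjects, _ = generate(default_spec(seed=9))
    table = cohort_table(subjects)
    sh = table[table["classification"] != "euthyroid"]
    assert (sh["tsh_miu_l"] > sh["tsh_predicted"]).all()
    assert (sh["gt_actual_pmol_s"] < sh["gt_predicted_pmol_s"]).all()
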