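"""Tests of classification, quartile binning, stratum aggregation and statistics."""

import numpy as np
import pytest

from thyrocap import (
    Subject,
    antibody_positive,
    bmi_sds,
    classify,
    cohort_table,
    compare,
    quartile_bins,
    summarize_strata,
)
from thyrocap.spina import DomainError


def subject(tsh=3.0, ft4=16.0, **kw):
    defaults = dict(id="s", age=8.0, sex="F")
    defaults.update(kw)
    return Subject(tsh=tsh, ft4=ft4, **defaults)


@pytest.mark.parametrize(
    "tsh,expected",
    [
        (4.5, "euthyroid"),    # boundary: SH requires strictly > 4.5
        (4.51, "mild_SH"),     # smallest SH value in the study
        (10.0, "mild_SH"),
        (10.23, "severe_SH"),  # smallest severe value in the study
        (0.6, "euthyroid"),
    ],
)
def test_classify_tsh_boundaries(tsh, expected):
    assert classify(subject(tsh=tsh)) == expected
    assert classify(tsh) == expected


@pytest.mark.parametrize(
    "tg,tpo,expected",
    [
        (35.0, 1.0, True),     # one assay over threshold suffices
        (34.0, 34.0, False),   # strict inequality at 34 IU/mL
        (None, 100.0, True),   # and/or semantics with a missing assay
        (10.0, None, False),
        (None, None, None),    # indeterminate: excluded from denominators
    ],
)
def test_antibody_positive_semantics(tg, tpo, expected):
    assert antibody_positive(subject(tg_ab=tg, tpo_ab=tpo)) is expected


def test_quartile_bins_equally_spaced_values():
    bins = quartile_bins(np.linspace(1.0, 4.0, 8))
    labels = [bins.assign(v) for v in np.linspace(1.0, 4.0, 8)]
    assert labels == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


def test_quartile_bins_uniform_sample_boundaries():
    # closed-form quantiles of Uniform(0.6, 4.47): 1.5675 / 2.535 / 3.5025
    rng = np.random.default_rng(42)
    values = rng.uniform(0.6, 4.47, 10000)
    bins = quartile_bins(values)
    assert bins.q25 == pytest.approx(1.5675, abs=0.05)
    assert bins.q50 == pytest.approx(2.535, abs=0.05)
    assert bins.q75 == pytest.approx(3.5025, abs=0.05)


def test_quartile_bins_require_four_distinct_values():
    with pytest.raises(ValueError):
        quartile_bins([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        quartile_bins([2.0, 2.0, 2.0, 2.0, 2.0])


def test_quartile_ties_go_to_lower_bin():
    values = [1, 1, 2, 2, 3, 3, 4, 4]
    bins = quartile_bins(values)
    assert bins.assign(bins.q25) == "Q1"
    assert bins.assign(bins.q50) == "Q2"
    assert bins.assign(bins.q75) == "Q3"


def test_cohort_partition_covers_every_subject_once():
    rng = np.random.default_rng(3)
    subjects = [
        subject(id=f"s{i}", tsh=t, ft4=f)
        for i, (t, f) in enumerate(zip(rng.uniform(0.6, 14, 200), rng.uniform(11, 24, 200)))
    ]
    table = cohort_table(subjects)
    assert len(table) == 200
    assert set(table["stratum"]) <= {"Q1", "Q2", "Q3", "Q4", "mild_SH", "severe_SH"}
    eu = table[table["classification"] == "euthyroid"]
    assert set(eu["stratum"]) <= {"Q1", "Q2", "Q3", "Q4"}
    sizes = eu["stratum"].value_counts()
    assert abs(sizes.max() - sizes.min()) <= 1  # near-equal quartiles, no ties here
    # stratum TSH ranges are non-overlapping and ordered
    summaries = [s for s in summarize_strata(table) if s.n > 0]
    for a, b in zip(summaries, summaries[1:]):
        assert a.tsh_max <= b.tsh_min


def test_single_subject_stratum_aggregates():
    subjects = [subject(id=f"e{i}", tsh=t) for i, t in enumerate([1.0, 2.0, 3.0, 4.0])]
    subjects.append(subject(id="m", tsh=6.7, ft4=15.7))
    table = cohort_table(subjects)
    mild = next(s for s in summarize_strata(table) if s.label == "mild_SH")
    assert mild.n == 1
    assert mild.gt_actual_median == mild.gt_actual_mean
    assert mild.gt_actual_median == pytest.approx(1.6809754499999996, rel=1e-12)
    assert mild.tsh_min == mild.tsh_max == 6.7


def test_positivity_percentage_rounding():
    subjects = [subject(id=f"e{i}", tsh=t) for i, t in enumerate([1.0, 2.0, 3.0, 4.0])]
    subjects += [
        subject(id=f"m{i}", tsh=6.0, tg_ab=100.0 if i < 20 else 5.0, tpo_ab=5.0)
        for i in range(171)
    ]
    table = cohort_table(subjects)
    mild = next(s for s in summarize_strata(table, pct_decimals=0) if s.label == "mild_SH")
    assert (mild.ab_positive, mild.ab_evaluable) == (20, 171)
    assert mild.ab_positive_pct == 12  # 20/171 at the integer convention


def test_indeterminate_antibodies_excluded_from_denominator():
    subjects = [subject(id=f"e{i}", tsh=t, tg_ab=None, tpo_ab=None)
                for i, t in enumerate([1.0, 2.0, 3.0, 4.0])]
    subjects += [subject(id="m1", tsh=6.0, tg_ab=50.0, tpo_ab=None),
                 subject(id="m2", tsh=6.1, tg_ab=1.0, tpo_ab=1.0),
                 subject(id="m3", tsh=6.2, tg_ab=None, tpo_ab=None)]
    table = cohort_table(subjects)
    mild = next(s for s in summarize_strata(table) if s.label == "mild_SH")
    assert mild.n == 3
    assert mild.ab_evaluable == 2  # the doubly missing subject is indeterminate
    assert mild.ab_positive == 1
    assert mild.ab_positive_pct == 50.0


def test_empty_stratum_row():
    subjects = [subject(id=f"e{i}", tsh=t) for i, t in enumerate([1.0, 2.0, 3.0, 4.0])]
    severe = next(s for s in summarize_strata(cohort_table(subjects))
                  if s.label == "severe_SH")
    assert severe.n == 0 and severe.gt_actual_median is None


def test_t_test_null_case_and_power():
    same = list(np.arange(10.0))
    res = compare([same, same], "t_test")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0, abs=1e-12)
    rng = np.random.default_rng(0)
    res = compare([rng.normal(0, 1, 50), rng.normal(5, 1, 50)], "t_test")
    assert res.p_value < 1e-10


def test_chi_squared_antibody_contingency():
    # SH 22/183 positive vs euthyroid 20/313: significantly different
    res = compare([(22, 161), (20, 293)], "chi_squared", ["SH", "euthyroid"])
    assert res.p_value < 0.05


def test_anova_tukey_adjusted_pairwise_matches_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
    rng = np.random.default_rng(1)
    groups = [rng.normal(mu, 1.0, 30) for mu in (0.0, 0.5, 2.0)]
    res = compare(groups, "anova_tukey", ["a", "b", "c"])
    assert res.p_value < 1e-6
    assert len(res.posthoc) == 3
    assert all(p.adjusted for p in res.posthoc)
    data = np.concatenate(groups)
    labels = np.repeat(["a", "b", "c"], 30)
    sm = statsmodels.pairwise_tukeyhsd(data, labels)
    for ours, theirs in zip(res.posthoc, sm.pvalues):
        assert ours.p_value == pytest.approx(theirs, abs=1e-6)


def test_compare_rejects_degenerate_groups():
    with pytest.raises(ValueError):
        compare([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]], "anova_tukey")


@pytest.mark.parametrize(
    "bmi,mean,sd,expected",
    [(17.0, 17.0, 1.5, 0.0), (20.0, 17.0, 1.5, 2.0), (14.0, 17.0, 1.5, -2.0)],
)
def test_bmi_sds_linear_and_antisymmetric(bmi, mean, sd, expected):
    assert bmi_sds(bmi, mean, sd) == pytest.approx(expected)


def test_bmi_sds_rejects_nonpositive_sd():
    with pytest.raises(DomainError):
        bmi_sds(20.0, 17.0, 0.0)


def test_subject_invariants():
    with pytest.raises(DomainError):
        subject(tsh=-1.0)
    with pytest.raises(DomainError):
        subject(age=-1.0)
    with pytest.raises(DomainError):
        Subject(id="x", age=5.0, sex="?", tsh=2.0, ft4=15.0)
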