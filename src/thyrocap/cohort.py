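"""Cohort stratification and group comparison for thyroid-function analysis.

Subjects are classified by serum TSH into euthyroid (TSH <= 4.5 mIU/L),
mild subclinical hypothyroidism (4.5 < TSH <= 10) and severe SH
(TSH > 10).  The euthyroid subset is further divided into quartiles of
its TSH distribution (Q1..Q4), giving six ordered strata.  Per stratum
the pipeline aggregates actual secretory capacity (from the measured
TSH/FT4 pair), predicted capacity (from the population curve at the
subject's FT4), and thyroid-autoantibody positivity (TG-Ab and/or
TPO-Ab > 34 IU/mL).  Group comparisons use Welch's t-test, one-way
ANOVA with Tukey's HSD (adjusted p-values), and Pearson's chi-squared
test, at a 0.05 significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .population import DEFAULT_CURVE, PopulationCurve, predict_tsh_array
from .spina import DEFAULT_CONSTANTS, DomainError, SpinaConstants, gt_from_tsh_ft4

__all__ = [
    "SH_TSH_THRESHOLD",
    "SEVERE_TSH_THRESHOLD",
    "ANTIBODY_THRESHOLD",
    "STRATUM_ORDER",
    "Subject",
    "QuartileBins",
    "StratumSummary",
    "ComparisonResult",
    "classify",
    "antibody_positive",
    "quartile_bins",
    "bmi_sds",
    "cohort_table",
    "summarize_strata",
    "compare",
]

#: TSH above this (mIU/L) defines subclinical hypothyroidism.
SH_TSH_THRESHOLD = 4.5
#: TSH above this (mIU/L) defines the severe form of SH.
SEVERE_TSH_THRESHOLD = 10.0
#: TG-Ab / TPO-Ab above this (IU/mL) counts as antibody-positive.
ANTIBODY_THRESHOLD = 34.0

STRATUM_ORDER = ("Q1", "Q2", "Q3", "Q4", "mild_SH", "severe_SH")


@dataclass(frozen=True)
class Subject:
    """One clinical record: demographics plus the TSH/FT4 pair and antibodies.

    ``tsh`` in mIU/L, ``ft4`` in pmol/L, antibodies in IU/mL; missing
    optional assays are ``None``.
    """

    id: str
    age: float
    sex: str  # "M" or "F"
    tsh: float
    ft4: float
    bmi: Optional[float] = None
    bmi_sds: Optional[float] = None
    tg_ab: Optional[float] = None
    tpo_ab: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.tsh > 0:
            raise DomainError(f"subject {self.id}: tsh must be > 0, got {self.tsh!r}")
        if not self.ft4 > 0:
            raise DomainError(f"subject {self.id}: ft4 must be > 0, got {self.ft4!r}")
        if self.age < 0:
            raise DomainError(f"subject {self.id}: age must be >= 0, got {self.age!r}")
        if self.sex not in ("M", "F"):
            raise DomainError(f"subject {self.id}: sex must be 'M' or 'F', got {self.sex!r}")


def classify(
    subject: "Subject | float",
    sh_threshold: float = SH_TSH_THRESHOLD,
    severe_threshold: float = SEVERE_TSH_THRESHOLD,
) -> str:
    """Classify a subject (or bare TSH value, mIU/L) by TSH.

    Returns ``"euthyroid"`` (TSH <= 4.5), ``"mild_SH"`` (4.5 < TSH <= 10)
    or ``"severe_SH"`` (TSH > 10).  Boundaries follow the clinical
    definitions: SH requires TSH strictly above 4.5.
    """
    tsh = subject.tsh if isinstance(subject, Subject) else float(subject)
    if tsh <= sh_threshold:
        return "euthyroid"
    if tsh <= severe_threshold:
        return "mild_SH"
    return "severe_SH"


def antibody_positive(
    subject: Subject, threshold: float = ANTIBODY_THRESHOLD
) -> Optional[bool]:
    """Thyroid-antibody status: TG-Ab and/or TPO-Ab strictly above threshold.

    A missing assay is evaluated on the available one ("and/or"
    semantics); with both assays missing the status is indeterminate and
    ``None`` is returned, excluding the subject from positivity
    denominators.
    """
    if subject.tg_ab is None and subject.tpo_ab is None:
        return None
    for value in (subject.tg_ab, subject.tpo_ab):
        if value is not None and value > threshold:
            return True
    return False


@dataclass(frozen=True)
class QuartileBins:
    """Quartile bins of a euthyroid TSH distribution.

    Boundaries are the 25th/50th/75th percentiles (linear interpolation
    between order statistics); a value tied with a boundary is assigned
    to the lower bin.
    """

    q25: float
    q50: float
    q75: float

    def assign(self, tsh: float) -> str:
        if tsh <= self.q25:
            return "Q1"
        if tsh <= self.q50:
            return "Q2"
        if tsh <= self.q75:
            return "Q3"
        return "Q4"

    def assign_array(self, tsh) -> np.ndarray:
        tsh = np.asarray(tsh, dtype=float)
        labels = np.full(tsh.shape, "Q4", dtype=object)
        labels[tsh <= self.q75] = "Q3"
        labels[tsh <= self.q50] = "Q2"
        labels[tsh <= self.q25] = "Q1"
        return labels


def quartile_bins(euthyroid_tsh: Sequence[float]) -> QuartileBins:
    """Quartile boundaries of the euthyroid TSH values.

    Raises
    ------
    ValueError
        With fewer than 4 subjects or fewer than 4 distinct values.
    """
    values = np.asarray(list(euthyroid_tsh), dtype=float)
    if values.size < 4 or np.unique(values).size < 4:
        raise ValueError(
            f"quartile binning needs >= 4 distinct TSH values, got {values.size} "
            f"({np.unique(values).size} distinct)"
        )
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return QuartileBins(q25=float(q25), q50=float(q50), q75=float(q75))


def bmi_sds(bmi: float, ref_mean: float, ref_sd: float) -> float:
    """BMI standard-deviation score: ``(bmi - ref_mean) / ref_sd``.

    ``ref_mean``/``ref_sd`` are the age-, race- and sex-specific
    reference BMI mean and SD (kg/m^2), supplied by the caller from a
    national growth reference.
    """
    if not ref_sd > 0:
        raise DomainError(f"ref_sd must be > 0, got {ref_sd!r}")
    return (bmi - ref_mean) / ref_sd


def cohort_table(
    subjects: Sequence[Subject],
    constants: SpinaConstants = DEFAULT_CONSTANTS,
    curve: PopulationCurve = DEFAULT_CURVE,
    sh_threshold: float = SH_TSH_THRESHOLD,
    severe_threshold: float = SEVERE_TSH_THRESHOLD,
    antibody_threshold: float = ANTIBODY_THRESHOLD,
) -> pd.DataFrame:
    """Per-subject analysis table.

    Adds to each record the actual secretory capacity
    (``gt_actual_pmol_s``, from the measured TSH/FT4), the
    population-predicted TSH and capacity at the subject's FT4
    (``tsh_predicted``, ``gt_predicted_pmol_s``), the TSH classification
    and the stratum label (euthyroid TSH quartile or mild/severe SH).
    Quartiles are computed on the euthyroid subset of this cohort.
    """
    if len(subjects) == 0:
        raise ValueError("empty cohort")
    df = pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "bmi": [s.bmi for s in subjects],
            "bmi_sds": [s.bmi_sds for s in subjects],
            "tsh_miu_l": [s.tsh for s in subjects],
            "ft4_pmol_l": [s.ft4 for s in subjects],
            "tg_ab_iu_ml": [s.tg_ab for s in subjects],
            "tpo_ab_iu_ml": [s.tpo_ab for s in subjects],
        }
    )
    df["gt_actual_pmol_s"] = gt_from_tsh_ft4(
        df["tsh_miu_l"].to_numpy(), df["ft4_pmol_l"].to_numpy(), constants
    )
    df["tsh_predicted"] = predict_tsh_array(df["ft4_pmol_l"].to_numpy(), curve)
    df["gt_predicted_pmol_s"] = gt_from_tsh_ft4(
        df["tsh_predicted"].to_numpy(), df["ft4_pmol_l"].to_numpy(), constants
    )
    df["classification"] = [
        classify(s, sh_threshold, severe_threshold) for s in subjects
    ]
    ab = [antibody_positive(s, antibody_threshold) for s in subjects]
    df["ab_positive"] = pd.array(ab, dtype="boolean")

    stratum = df["classification"].copy()
    eu_mask = stratum == "euthyroid"
    if eu_mask.sum() >= 4:
        bins = quartile_bins(df.loc[eu_mask, "tsh_miu_l"])
        stratum.loc[eu_mask] = bins.assign_array(df.loc[eu_mask, "tsh_miu_l"])
    df["stratum"] = stratum
    return df


@dataclass(frozen=True)
class StratumSummary:
    """One row of the stratum table: TSH range, capacity aggregates, positivity.

    ``ab_positive_pct`` is computed over the antibody-evaluable subjects
    (``ab_evaluable``); this equals ``n`` whenever every subject has at
    least one antibody assay.  Aggregates are ``None`` for an empty
    stratum.
    """

    label: str
    n: int
    tsh_min: Optional[float] = None
    tsh_max: Optional[float] = None
    gt_actual_median: Optional[float] = None
    gt_actual_mean: Optional[float] = None
    gt_predicted_median: Optional[float] = None
    gt_predicted_mean: Optional[float] = None
    ab_positive: int = 0
    ab_evaluable: int = 0
    ab_positive_pct: Optional[float] = None


def summarize_strata(
    table: pd.DataFrame, pct_decimals: int = 1
) -> list[StratumSummary]:
    """Aggregate a :func:`cohort_table` result into the six ordered strata.

    Rows are emitted in the order Q1..Q4, mild_SH, severe_SH; an absent
    stratum yields a row with ``n=0`` and absent aggregates.
    """
    out: list[StratumSummary] = []
    for label in STRATUM_ORDER:
        sub = table[table["stratum"] == label]
        n = int(len(sub))
        if n == 0:
            out.append(StratumSummary(label=label, n=0))
            continue
        ab = sub["ab_positive"]
        evaluable = int(ab.notna().sum())
        positive = int((ab == True).sum())  # noqa: E712 - pandas boolean array
        pct = (
            round(100.0 * positive / evaluable, pct_decimals) if evaluable else None
        )
        out.append(
            StratumSummary(
                label=label,
                n=n,
                tsh_min=float(sub["tsh_miu_l"].min()),
                tsh_max=float(sub["tsh_miu_l"].max()),
                gt_actual_median=float(sub["gt_actual_pmol_s"].median()),
                gt_actual_mean=float(sub["gt_actual_pmol_s"].mean()),
                gt_predicted_median=float(sub["gt_predicted_pmol_s"].median()),
                gt_predicted_mean=float(sub["gt_predicted_pmol_s"].mean()),
                ab_positive=positive,
                ab_evaluable=evaluable,
                ab_positive_pct=pct,
            )
        )
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one statistical comparison.

    ``adjusted`` marks multiplicity-adjusted p-values (Tukey HSD
    pairwise rows, attached under ``posthoc`` of the ANOVA result).
    """

    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    adjusted: bool = False
    posthoc: tuple["ComparisonResult", ...] = field(default_factory=tuple)


def compare(
    groups: Sequence[Sequence[float]],
    test: str,
    labels: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """Compare groups with the named test.

    Parameters
    ----------
    groups
        For ``"t_test"`` (Welch, two-sided): exactly two samples of
        values.  For ``"anova_tukey"``: two or more samples with at
        least two members each; the result carries Tukey HSD pairwise
        comparisons with adjusted p-values in ``posthoc``.  For
        ``"chi_squared"``: one ``(positive, negative)`` count pair per
        group, compared with Pearson's chi-squared on the contingency
        table.
    """
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    labels = tuple(str(l) for l in labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")

    if test == "t_test":
        if len(groups) != 2:
            raise ValueError("t_test compares exactly 2 groups")
        a, b = (np.asarray(g, dtype=float) for g in groups)
        _check_nondegenerate([a, b])
        res = stats.ttest_ind(a, b, equal_var=False)
        return ComparisonResult(
            test="t_test", groups=labels, statistic=float(res.statistic),
            p_value=float(res.pvalue),
        )

    if test == "anova_tukey":
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if any(a.size < 2 for a in arrays):
            raise ValueError("anova_tukey needs >= 2 members per group")
        _check_nondegenerate(arrays)
        f_stat, f_p = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
        posthoc = []
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                posthoc.append(
                    ComparisonResult(
                        test="tukey_hsd",
                        groups=(labels[i], labels[j]),
                        statistic=float(tukey.statistic[i, j]),
                        p_value=float(tukey.pvalue[i, j]),
                        adjusted=True,
                    )
                )
        return ComparisonResult(
            test="anova_tukey", groups=labels, statistic=float(f_stat),
            p_value=float(f_p), posthoc=tuple(posthoc),
        )

    if test == "chi_squared":
        table = np.asarray(groups, dtype=float)
        if table.ndim != 2 or table.shape[1] != 2:
            raise ValueError("chi_squared expects one (positive, negative) pair per group")
        res = stats.chi2_contingency(table, correction=False)
        return ComparisonResult(
            test="chi_squared", groups=labels, statistic=float(res.statistic),
            p_value=float(res.pvalue),
        )

    raise ValueError(f"unknown test {test!r}")


def _check_nondegenerate(arrays: Sequence[np.ndarray]) -> None:
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("all groups are constant and identical; comparison undefined")
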