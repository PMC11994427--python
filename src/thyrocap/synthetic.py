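"""Seeded synthetic pediatric thyroid cohorts built on individual set-points.

The clinical cohorts this analysis targets are not publicly deposited,
so validation runs on synthetic cohorts generated from the same
physiology the analysis assumes.  Each simulated subject owns a latent
set-point: a true secretory capacity GT drawn from a group-level
lognormal (TSH in healthy populations is right-skewed) and a true FT4
drawn from a group-level normal, optionally correlated with GT on the
log scale (higher-capacity glands tend to run higher FT4).  The true
TSH is then the unique value consistent with that capacity and FT4
under the secretory-capacity formula (its algebraic inversion), after
which multiplicative lognormal assay noise is applied to both TSH and
FT4.  Draws are rejected and redrawn until the measured values fall in
the group's admissible ranges, so group boundaries carry no probability
atoms.

Default group parameters reproduce the study conditions of a pediatric
cohort of 313 euthyroid children (TSH 0.6-4.5 mIU/L) and 183 children
with subclinical hypothyroidism (TSH 4.5-15 mIU/L, FT4 10.43-24.5
pmol/L); see the per-group defaults below and docs/methods.md for the
calibration rationale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .cohort import Subject, cohort_table, STRATUM_ORDER
from .spina import DEFAULT_CONSTANTS, SpinaConstants, min_feasible_gt, tsh_from_gt_ft4

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "default_spec",
    "strata_spec",
    "TABLE_STRATA_MEDIANS",
    "generate",
    "RecoveryResult",
    "recovery_experiment",
    "GeneratorConfigError",
]


class GeneratorConfigError(ValueError):
    """The generative parameters define an (almost) empty acceptance region."""


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one cohort group (or one stratum).

    ``gt_median``/``gt_log_sigma`` parameterise the lognormal of true
    capacity (pmol/s); ``gt_ft4_log_corr`` is the log-scale correlation
    between true GT and true FT4.  ``tsh_range`` is the half-open
    interval (lo, hi] the measured TSH must fall in; ``ft4_range``
    optionally constrains FT4 the same way (inclusive bounds).
    """

    name: str
    n: int
    gt_median: float
    gt_log_sigma: float
    ft4_mean: float
    ft4_sd: float
    tsh_range: tuple[float, float]
    ft4_range: Optional[tuple[float, float]] = None
    gt_ft4_log_corr: float = 0.0
    ab_positive_prob: float = 0.0
    age_range: tuple[float, float] = (1.0, 17.0)
    male_fraction: float = 0.5
    bmi_sds_mean: float = 1.0
    bmi_sds_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group {self.name}: n must be > 0")
        if not (self.gt_median > 0 and self.gt_log_sigma >= 0):
            raise ValueError(f"group {self.name}: invalid GT distribution")
        if not self.ft4_sd > 0:
            raise ValueError(f"group {self.name}: ft4_sd must be > 0")
        if not self.tsh_range[0] < self.tsh_range[1]:
            raise ValueError(f"group {self.name}: tsh_range must be increasing")
        if not -1.0 <= self.gt_ft4_log_corr <= 1.0:
            raise ValueError(f"group {self.name}: correlation must be in [-1, 1]")
        if not 0.0 <= self.ab_positive_prob <= 1.0:
            raise ValueError(f"group {self.name}: ab_positive_prob must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """A full cohort recipe: groups plus shared assay noise and the seed.

    ``noise_cv_tsh``/``noise_cv_ft4`` are relative (coefficient of
    variation) assay errors applied as unit-mean multiplicative
    lognormal noise.
    """

    groups: tuple[GroupSpec, ...]
    noise_cv_tsh: float = 0.05
    noise_cv_ft4: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("need at least one group")
        if self.noise_cv_tsh < 0 or self.noise_cv_ft4 < 0:
            raise ValueError("noise CVs must be >= 0")


# Calibrated once so that accepted-cohort TSH moments sit at the study's
# group statistics (euthyroid 3.01 +/- 0.95, SH 6.7 +/- 2.05 mIU/L); see
# docs/methods.md.
_EUTHYROID_DEFAULT = GroupSpec(
    name="euthyroid",
    n=313,
    gt_median=2.0,
    gt_log_sigma=0.20,
    ft4_mean=16.3,
    ft4_sd=2.19,
    tsh_range=(0.6, 4.5),
    gt_ft4_log_corr=0.0,
    ab_positive_prob=20 / 313,
    age_range=(1.3, 16.7),
    male_fraction=145 / 313,
    bmi_sds_mean=1.03,
    bmi_sds_sd=1.59,
)
_SH_DEFAULT = GroupSpec(
    name="SH",
    n=183,
    gt_median=1.75,
    gt_log_sigma=0.15,
    ft4_mean=15.7,
    ft4_sd=2.32,
    tsh_range=(4.5, 15.0),
    ft4_range=(10.43, 24.5),
    gt_ft4_log_corr=0.7,
    ab_positive_prob=22 / 183,
    age_range=(1.0, 14.9),
    male_fraction=84 / 183,
    bmi_sds_mean=1.11,
    bmi_sds_sd=1.46,
)


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The study conditions: 313 euthyroid + 183 SH children."""
    return SyntheticSpec(groups=(_EUTHYROID_DEFAULT, _SH_DEFAULT), seed=seed)


#: Published per-stratum secretory-capacity medians (pmol/s), Q1..Q4 then
#: mild and severe SH, usable as generator inputs for recovery studies.
TABLE_STRATA_MEDIANS = (3.21, 2.53, 2.20, 1.70, 1.77, 1.29)

_STRATA_TSH_RANGES = (
    (0.6, 2.25),
    (2.26, 3.14),
    (3.15, 3.82),
    (3.85, 4.47),
    (4.5, 9.93),
    (10.23, 14.0),
)
_STRATA_N = (80, 77, 78, 78, 171, 12)
_STRATA_AB = (3 / 80, 3 / 77, 8 / 78, 6 / 78, 20 / 171, 2 / 12)


def strata_spec(
    seed: int = 0,
    gt_medians: Sequence[float] = TABLE_STRATA_MEDIANS,
    gt_log_sigma: float = 0.2,
) -> SyntheticSpec:
    """A six-stratum recipe with per-stratum true GT medians.

    Stratum sizes, TSH ranges and antibody-positivity rates mirror the
    published stratum table; ``gt_medians`` defaults to the published
    capacity medians, making this the input for parameter-recovery
    experiments.
    """
    if len(gt_medians) != 6:
        raise ValueError("need one GT median per stratum (6)")
    groups = []
    for label, med, rng_, n, ab in zip(
        STRATUM_ORDER, gt_medians, _STRATA_TSH_RANGES, _STRATA_N, _STRATA_AB
    ):
        sh = label.endswith("SH")
        groups.append(
            GroupSpec(
                name=label,
                n=n,
                gt_median=float(med),
                gt_log_sigma=gt_log_sigma,
                ft4_mean=15.7 if sh else 16.3,
                ft4_sd=2.32 if sh else 2.19,
                tsh_range=rng_,
                ft4_range=(10.43, 24.5) if sh else None,
                ab_positive_prob=ab,
            )
        )
    return SyntheticSpec(groups=tuple(groups), seed=seed)


def _noise_sigma(cv: float) -> float:
    # lognormal sigma giving a coefficient of variation of cv
    return float(np.sqrt(np.log1p(cv * cv)))


def _sample_group(
    group: GroupSpec,
    cv_tsh: float,
    cv_ft4: float,
    rng: np.random.Generator,
    constants: SpinaConstants,
) -> dict[str, np.ndarray]:
    """Vectorised rejection sampling of one group's accepted subjects."""
    n = group.n
    got: dict[str, list[np.ndarray]] = {k: [] for k in
        ("gt_true", "ft4_true", "tsh_true", "tsh", "ft4")}
    accepted = 0
    drawn = 0
    s_t, s_f = _noise_sigma(cv_tsh), _noise_sigma(cv_ft4)
    rho = group.gt_ft4_log_corr
    while accepted < n:
        m = max(4 * (n - accepted), 2000)
        drawn += m
        z1 = rng.standard_normal(m)
        z2 = rng.standard_normal(m)
        ft4_true = group.ft4_mean + group.ft4_sd * z1
        gt_true = group.gt_median * np.exp(
            group.gt_log_sigma * (rho * z1 + np.sqrt(1.0 - rho * rho) * z2)
        )
        ok = ft4_true > 0
        if group.ft4_range is not None:
            lo, hi = group.ft4_range
            ok &= (ft4_true >= lo) & (ft4_true <= hi)
        ok &= gt_true > min_feasible_gt(np.where(ok, ft4_true, 1.0), constants)
        tsh_true = np.where(
            ok, tsh_from_gt_ft4(gt_true, np.where(ok, ft4_true, 1.0), constants), np.nan
        )
        # unit-mean multiplicative assay noise
        tsh_meas = tsh_true * np.exp(rng.normal(-0.5 * s_t * s_t, s_t, m)) if s_t else tsh_true
        ft4_meas = ft4_true * np.exp(rng.normal(-0.5 * s_f * s_f, s_f, m)) if s_f else ft4_true
        lo, hi = group.tsh_range
        ok &= (tsh_meas > lo) & (tsh_meas <= hi) & (ft4_meas > 0)
        if group.ft4_range is not None:
            flo, fhi = group.ft4_range
            ok &= (ft4_meas >= flo) & (ft4_meas <= fhi)
        idx = np.flatnonzero(ok)[: n - accepted]
        for key, arr in (
            ("gt_true", gt_true), ("ft4_true", ft4_true), ("tsh_true", tsh_true),
            ("tsh", tsh_meas), ("ft4", ft4_meas),
        ):
            got[key].append(arr[idx])
        accepted += idx.size
        if drawn >= max(100 * n, 10_000) and accepted < 0.01 * drawn:
            gmin = float(min_feasible_gt(group.ft4_mean, constants))
            raise GeneratorConfigError(
                f"group {group.name}: acceptance rate {accepted}/{drawn} below 1%. "
                f"At FT4 = {group.ft4_mean:g} pmol/L the model requires true GT > "
                f"{gmin:.4g} pmol/s, and the measured TSH must land in "
                f"({group.tsh_range[0]:g}, {group.tsh_range[1]:g}] mIU/L; the "
                f"configured GT lognormal (median {group.gt_median:g}, log-sigma "
                f"{group.gt_log_sigma:g}) puts almost no mass in that region."
            )
    return {k: np.concatenate(v)[:n] for k, v in got.items()}


def generate(
    spec: SyntheticSpec,
    constants: SpinaConstants = DEFAULT_CONSTANTS,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Subject], pd.DataFrame]:
    """Generate one cohort.

    Returns the list of :class:`~thyrocap.cohort.Subject` records (what
    an analyst would see) and the hidden truth table with columns
    ``id, group, gt_true_pmol_s, tsh_true, ft4_true`` (what the
    generator knew).  Deterministic for a fixed ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    truth_rows: list[pd.DataFrame] = []
    for group in spec.groups:
        draws = _sample_group(group, spec.noise_cv_tsh, spec.noise_cv_ft4, rng, constants)
        n = group.n
        ids = [f"{group.name}-{i + 1:04d}" for i in range(n)]
        ages = rng.uniform(group.age_range[0], group.age_range[1], n)
        sexes = np.where(rng.random(n) < group.male_fraction, "M", "F")
        bmi_sds = rng.normal(group.bmi_sds_mean, group.bmi_sds_sd, n)
        tg, tpo = _antibody_values(group.ab_positive_prob, n, rng)
        for i in range(n):
            subjects.append(
                Subject(
                    id=ids[i],
                    age=float(round(ages[i], 2)),
                    sex=str(sexes[i]),
                    tsh=float(draws["tsh"][i]),
                    ft4=float(draws["ft4"][i]),
                    bmi_sds=float(round(bmi_sds[i], 2)),
                    tg_ab=float(round(tg[i], 1)),
                    tpo_ab=float(round(tpo[i], 1)),
                )
            )
        truth_rows.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "group": group.name,
                    "gt_true_pmol_s": draws["gt_true"],
                    "tsh_true": draws["tsh_true"],
                    "ft4_true": draws["ft4_true"],
                }
            )
        )
    return subjects, pd.concat(truth_rows, ignore_index=True)


def _antibody_values(p_positive: float, n: int, rng: np.random.Generator):
    """TG-Ab/TPO-Ab values: positives get at least one assay above the
    34 IU/mL threshold (TPO-only half the time, TG-only a quarter, both a
    quarter); negatives sit uniformly in the low assay range."""
    threshold = _cohort.ANTIBODY_THRESHOLD
    tg = rng.uniform(1.0, 0.85 * threshold, n)
    tpo = rng.uniform(1.0, 0.85 * threshold, n)
    positive = rng.random(n) < p_positive
    pattern = rng.random(n)
    high = lambda k: threshold + rng.lognormal(3.0, 1.0, k)  # noqa: E731
    tpo_hi = positive & (pattern < 0.75)
    tg_hi = positive & (pattern >= 0.5)
    tpo[tpo_hi] = high(int(tpo_hi.sum()))
    tg[tg_hi] = high(int(tg_hi.sum()))
    return tg, tpo


@dataclass(frozen=True)
class RecoveryResult:
    """Per-stratum recovery of true capacity medians through the pipeline.

    ``bias`` and ``rmse`` are relative (fractions of the per-replicate
    truth, the median true GT of the subjects the pipeline assigned to
    that stratum); ``ordering_recovery_rate`` is the fraction of
    replicates in which the stratum medians of estimated GT satisfied
    Q1 > Q2 >= Q3 >= Q4 > mild SH > severe SH.
    """

    n_replicates: int
    strata: tuple[str, ...]
    truth_median: tuple[float, ...]      # mean over replicates, pmol/s
    estimate_median: tuple[float, ...]   # mean over replicates, pmol/s
    bias: tuple[float, ...]              # relative
    rmse: tuple[float, ...]              # relative
    ordering_recovery_rate: float
    sh_below_predicted_rate: float       # fraction of SH subjects with actual < predicted GT


def _ordering_recovered(medians: dict[str, float]) -> bool:
    if any(label not in medians for label in STRATUM_ORDER):
        return False
    m = [medians[label] for label in STRATUM_ORDER]
    return m[0] > m[1] >= m[2] >= m[3] > m[4] > m[5]


def recovery_experiment(
    spec: SyntheticSpec,
    n_replicates: int,
    constants: SpinaConstants = DEFAULT_CONSTANTS,
) -> RecoveryResult:
    """Generate ``n_replicates`` cohorts and push each through the full
    stratification pipeline, scoring estimated against true capacity.

    Replicate seeds are spawned deterministically from ``spec.seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    child_seeds = np.random.SeedSequence(spec.seed).spawn(n_replicates)
    rel_err: dict[str, list[float]] = {label: [] for label in STRATUM_ORDER}
    truth_meds: dict[str, list[float]] = {label: [] for label in STRATUM_ORDER}
    est_meds: dict[str, list[float]] = {label: [] for label in STRATUM_ORDER}
    ordering_hits = 0
    sh_below = 0
    sh_total = 0
    for ss in child_seeds:
        subjects, truth = generate(spec, constants, rng=np.random.default_rng(ss))
        table = cohort_table(subjects, constants)
        merged = table.merge(truth[["id", "gt_true_pmol_s"]], on="id")
        medians: dict[str, float] = {}
        for label in STRATUM_ORDER:
            sub = merged[merged["stratum"] == label]
            if len(sub) == 0:
                continue
            est = float(sub["gt_actual_pmol_s"].median())
            tru = float(sub["gt_true_pmol_s"].median())
            medians[label] = est
            est_meds[label].append(est)
            truth_meds[label].append(tru)
            rel_err[label].append((est - tru) / tru)
        if _ordering_recovered(medians):
            ordering_hits += 1
        sh_mask = table["classification"] != "euthyroid"
        sh_total += int(sh_mask.sum())
        sh_below += int(
            (table.loc[sh_mask, "gt_actual_pmol_s"]
             < table.loc[sh_mask, "gt_predicted_pmol_s"]).sum()
        )
    strata = tuple(STRATUM_ORDER)
    return RecoveryResult(
        n_replicates=n_replicates,
        strata=strata,
        truth_median=tuple(float(np.mean(truth_meds[s])) if truth_meds[s] else float("nan") for s in strata),
        estimate_median=tuple(float(np.mean(est_meds[s])) if est_meds[s] else float("nan") for s in strata),
        bias=tuple(float(np.mean(rel_err[s])) if rel_err[s] else float("nan") for s in strata),
        rmse=tuple(float(np.sqrt(np.mean(np.square(rel_err[s])))) if rel_err[s] else float("nan") for s in strata),
        ordering_recovery_rate=ordering_hits / n_replicates,
        sh_below_predicted_rate=sh_below / sh_total if sh_total else float("nan"),
    )
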