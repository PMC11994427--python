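"""Cohort file I/O and report rendering.

The cohort exchange format is a UTF-8, comma-separated file with '.'
decimal separator and header

    id,age,sex,bmi,bmi_sds,tsh_miu_l,ft4_pmol_l,tg_ab_iu_ml,tpo_ab_iu_ml

Missing optional values are empty fields.  Reading is defensive: rows
violating the physical invariants (non-positive TSH or FT4) or with
unparseable numerics are excluded, each with a logged reason and line
number, so that reported group sizes stay auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ComparisonResult, StratumSummary, Subject
from .config import RunConfig
from .spina import DomainError

__all__ = [
    "COHORT_COLUMNS",
    "ReadReport",
    "read_cohort",
    "write_cohort",
    "write_truth",
    "render_report",
]

logger = logging.getLogger("thyrocap")

COHORT_COLUMNS = (
    "id", "age", "sex", "bmi", "bmi_sds",
    "tsh_miu_l", "ft4_pmol_l", "tg_ab_iu_ml", "tpo_ab_iu_ml",
)


@dataclass(frozen=True)
class ReadReport:
    """Result of reading a cohort file: subjects kept plus an exclusion audit."""

    subjects: list[Subject]
    n_rows: int
    exclusions: list[tuple[int, str]]  # (1-based data line number, reason)


class SchemaError(ValueError):
    """The cohort file header does not match the expected schema."""


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_cohort(path: str | Path) -> ReadReport:
    """Read a cohort CSV into typed subjects.

    Raises
    ------
    SchemaError
        If a required column is missing.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str}, float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {sorted(missing)}")
    subjects: list[Subject] = []
    exclusions: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            subjects.append(
                Subject(
                    id=str(row.id),
                    age=float(row.age),
                    sex=str(row.sex),
                    tsh=float(row.tsh_miu_l),
                    ft4=float(row.ft4_pmol_l),
                    bmi=_opt(row.bmi),
                    bmi_sds=_opt(row.bmi_sds),
                    tg_ab=_opt(row.tg_ab_iu_ml),
                    tpo_ab=_opt(row.tpo_ab_iu_ml),
                )
            )
        except (DomainError, TypeError, ValueError) as exc:
            exclusions.append((i, str(exc)))
            logger.warning("excluded data line %d: %s", i, exc)
    if exclusions:
        logger.info(
            "read %d rows, kept %d, excluded %d", len(df), len(subjects), len(exclusions)
        )
    return ReadReport(subjects=subjects, n_rows=len(df), exclusions=exclusions)


def write_cohort(subjects: Sequence[Subject], path: str | Path) -> None:
    """Write subjects in the cohort CSV schema (inverse of :func:`read_cohort`)."""
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
    df.to_csv(path, index=False)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write a generator truth table (id, group, gt_true_pmol_s, tsh_true, ft4_true)."""
    truth.to_csv(path, index=False)


def _sig(value: Optional[float], figs: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if value == 0:
        return "0"
    digits = figs - 1 - int(math.floor(math.log10(abs(value))))
    return f"{round(value, digits):g}"


def _pct_sig2(pct: Optional[float]) -> str:
    """Two-significant-figure percentage, the stratum-table convention
    (3.7, 10, 12 ...)."""
    return _sig(pct, 2)


def render_report(
    table: pd.DataFrame,
    summaries: Sequence[StratumSummary],
    comparisons: Sequence[ComparisonResult],
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
) -> dict[str, Path]:
    """Write the analysis reports into ``out_dir``.

    Emits

    - ``subjects_augmented.csv`` -- the per-subject table at full precision;
    - ``group_table.csv`` / ``group_table.txt`` -- SH vs euthyroid group
      comparison (demographics, TSH, FT4, antibody positivity);
    - ``stratum_table.csv`` -- exactly the columns ``stratum, tsh_min,
      tsh_max, gt_median, gt_mean, ab_positive`` with capacities at the
      configured significant figures;
    - ``stratum_table_full.csv`` -- all stratum aggregates (including
      predicted capacity) at full precision;
    - ``stratum_table.txt`` -- the aligned human-readable stratum table;
    - ``comparisons.csv`` -- one row per statistical comparison.

    Rendering is deterministic: identical inputs give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["subjects"] = out / "subjects_augmented.csv"
    table.to_csv(paths["subjects"], index=False)

    paths["group_table_csv"] = out / "group_table.csv"
    paths["group_table_txt"] = out / "group_table.txt"
    group_df = _group_table(table, config)
    group_df.to_csv(paths["group_table_csv"], index=False)
    paths["group_table_txt"].write_text(group_df.to_string(index=False) + "\n", encoding="utf-8")

    sf = config.gt_sig_figs
    rows = []
    for s in summaries:
        if s.n == 0:
            continue
        ab = (
            f"{_pct_sig2(s.ab_positive_pct)}% ({s.ab_positive}/{s.ab_evaluable})"
            if s.ab_evaluable
            else ""
        )
        rows.append(
            {
                "stratum": s.label,
                "tsh_min": "" if s.tsh_min is None else f"{s.tsh_min:g}",
                "tsh_max": "" if s.tsh_max is None else f"{s.tsh_max:g}",
                "gt_median": _sig(s.gt_actual_median, sf),
                "gt_mean": _sig(s.gt_actual_mean, sf),
                "ab_positive": ab,
            }
        )
    stratum_df = pd.DataFrame(rows)
    paths["stratum_table_csv"] = out / "stratum_table.csv"
    stratum_df.to_csv(paths["stratum_table_csv"], index=False)
    paths["stratum_table_txt"] = out / "stratum_table.txt"
    paths["stratum_table_txt"].write_text(
        stratum_df.to_string(index=False) + "\n", encoding="utf-8"
    )

    paths["stratum_table_full_csv"] = out / "stratum_table_full.csv"
    pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
        paths["stratum_table_full_csv"], index=False
    )

    comp_rows = []
    for c in comparisons:
        for r in (c, *c.posthoc):
            comp_rows.append(
                {
                    "test": r.test,
                    "groups": " vs ".join(r.groups),
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "adjusted": r.adjusted,
                }
            )
    paths["comparisons_csv"] = out / "comparisons.csv"
    pd.DataFrame(
        comp_rows, columns=["test", "groups", "statistic", "p_value", "adjusted"]
    ).to_csv(paths["comparisons_csv"], index=False)
    return paths


def _group_table(table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """SH vs euthyroid group summary in the style of a demographics table."""
    d = config.pct_decimals
    rows = []
    for name, mask in (
        ("SH", table["classification"] != "euthyroid"),
        ("euthyroid", table["classification"] == "euthyroid"),
    ):
        sub = table[mask]
        n = len(sub)
        ab = sub["ab_positive"]
        evaluable = int(ab.notna().sum())
        pos = int((ab == True).sum())  # noqa: E712
        pct = round(100.0 * pos / evaluable, d) if evaluable else float("nan")
        rows.append(
            {
                "group": name,
                "n": n,
                "age_mean": round(float(sub["age"].mean()), 2) if n else "",
                "age_sd": round(float(sub["age"].std(ddof=1)), 2) if n > 1 else "",
                "male": int((sub["sex"] == "M").sum()),
                "female": int((sub["sex"] == "F").sum()),
                "bmi_sds_mean": round(float(sub["bmi_sds"].mean()), 2)
                if sub["bmi_sds"].notna().any() else "",
                "tsh_mean": round(float(sub["tsh_miu_l"].mean()), 2) if n else "",
                "tsh_sd": round(float(sub["tsh_miu_l"].std(ddof=1)), 2) if n > 1 else "",
                "ft4_mean": round(float(sub["ft4_pmol_l"].mean()), 2) if n else "",
                "ft4_sd": round(float(sub["ft4_pmol_l"].std(ddof=1)), 2) if n > 1 else "",
                "ab_positive": f"{pos} ({pct:g}%)" if evaluable else "",
            }
        )
    return pd.DataFrame(rows)
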