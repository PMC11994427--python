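"""Population-average TSH-FT4 curve and the predicted secretory capacity.

Large population studies describe ln TSH as a pair of overlapping
negative sigmoid functions of FT4, one fitted below and one above
12 pmol/L.  Each branch is a 4-parameter logistic

    ln TSH = offset + span / (1 + exp(-(center - FT4) / width))

with the published parameters

    low branch  (FT4 <  12 pmol/L): offset 1.4,  span 3.5, center  7.0, width 1.0
    high branch (FT4 >= 12 pmol/L): offset -3.7, span 5.3, center 20.6, width 3.0

The two branches do not meet at 12 pmol/L (the low branch approaches
ln TSH ~ 1.423, the high branch starts at ~ 1.315); the discontinuity is
a property of the published model and is deliberately not smoothed.

Back-transforming gives the population "predicted TSH" at a subject's
FT4, and feeding that predicted TSH into the secretory-capacity formula
gives the "predicted GT" -- the capacity of a population-average
individual at that FT4.  Predicted quantities are functions of FT4 only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spina import DEFAULT_CONSTANTS, DomainError, GtValue, SpinaConstants, gt_from_tsh_ft4

__all__ = [
    "LogisticBranch",
    "PopulationCurve",
    "DEFAULT_CURVE",
    "PredictedTsh",
    "predict_ln_tsh",
    "predict_tsh_array",
    "predict_gt",
]


@dataclass(frozen=True)
class LogisticBranch:
    """One negative-sigmoid branch of the ln TSH vs FT4 relationship.

    ``ln_tsh(ft4) = offset + span / (1 + exp(-(center - ft4)/width))``;
    strictly decreasing in FT4, bounded in (offset, offset + span).
    """

    offset: float
    span: float
    center: float  # FT4 at the logistic midpoint, pmol/L
    width: float   # pmol/L per log-unit of steepness

    def ln_tsh(self, ft4):
        ft4 = np.asarray(ft4, dtype=float)
        return self.offset + self.span / (1.0 + np.exp(-(self.center - ft4) / self.width))


@dataclass(frozen=True)
class PopulationCurve:
    """The published branch pair with its FT4 boundary (pmol/L).

    FT4 exactly at the boundary is assigned to the high branch: the
    publication defines the branches on FT4 < 12 and FT4 > 12 only, and
    pediatric euthyroid/SH FT4 lies almost entirely above 12 pmol/L.
    """

    low: LogisticBranch = LogisticBranch(offset=1.4, span=3.5, center=7.0, width=1.0)
    high: LogisticBranch = LogisticBranch(offset=-3.7, span=5.3, center=20.6, width=3.0)
    boundary: float = 12.0

    def branch_for(self, ft4: float) -> str:
        return "low_ft4" if ft4 < self.boundary else "high_ft4"


DEFAULT_CURVE = PopulationCurve()


@dataclass(frozen=True)
class PredictedTsh:
    """Population-predicted TSH at a given FT4.

    ``tsh = exp(ln_tsh)``; ``branch`` records which sigmoid produced it.
    """

    ft4: float
    ln_tsh: float
    tsh: float
    branch: str


def predict_ln_tsh(ft4: float, curve: PopulationCurve = DEFAULT_CURVE) -> PredictedTsh:
    """Predicted ln TSH (and back-transformed TSH, mIU/L) at ``ft4`` pmol/L.

    Raises
    ------
    DomainError
        If ``ft4`` is non-positive.
    """
    if not ft4 > 0:
        raise DomainError(f"ft4 must be > 0 pmol/L, got {ft4!r}")
    branch_name = curve.branch_for(ft4)
    branch = curve.low if branch_name == "low_ft4" else curve.high
    ln = float(branch.ln_tsh(ft4))
    return PredictedTsh(ft4=float(ft4), ln_tsh=ln, tsh=float(np.exp(ln)), branch=branch_name)


def predict_tsh_array(ft4, curve: PopulationCurve = DEFAULT_CURVE):
    """Vectorised predicted TSH (mIU/L) for an array of FT4 values (pmol/L)."""
    ft4 = np.asarray(ft4, dtype=float)
    ln = np.where(ft4 < curve.boundary, curve.low.ln_tsh(ft4), curve.high.ln_tsh(ft4))
    return np.exp(ln)


def predict_gt(
    ft4: float,
    constants: SpinaConstants = DEFAULT_CONSTANTS,
    curve: PopulationCurve = DEFAULT_CURVE,
) -> GtValue:
    """Predicted secretory capacity (pmol/s) of a population-average
    individual at ``ft4``: the capacity formula evaluated at the
    population-predicted TSH.  Depends on FT4 only, never on the
    subject's measured TSH."""
    predicted = predict_ln_tsh(ft4, curve)
    gt = float(gt_from_tsh_ft4(predicted.tsh, ft4, constants))
    return GtValue.from_gt(gt)
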