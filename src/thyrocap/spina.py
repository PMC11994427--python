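"""Thyroid secretory capacity (SPINA-GT) from paired TSH/FT4 measurements.

SPINA-GT estimates the maximum stimulated secretion rate of the thyroid
gland, in pmol/s, from a single equilibrium pair of serum TSH (mIU/L) and
free T4 (pmol/L) together with physiological constants for hormone
dilution, clearance, central damping and plasma protein binding:

    GT = beta_T * (D_T + TSH) * (1 + K41*[TBG] + K42*[TBPA]) * [FT4]
         -----------------------------------------------------------
                              alpha_T * TSH

with FT4 in mol/L inside the formula.  The binding term
``1 + K41*[TBG] + K42*[TBPA]`` converts free to total T4 at equilibrium
with thyroxine-binding globulin (TBG) and transthyretin (TBPA).

Units are handled at the API boundary: TSH in mIU/L (identical to
uIU/mL), FT4 in pmol/L, GT in pmol/s.  The adult reference range for GT
is 1.4-8.7 pmol/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DomainError",
    "InfeasibleGtError",
    "GT_REFERENCE_RANGE",
    "SpinaConstants",
    "DEFAULT_CONSTANTS",
    "HormonePair",
    "GtValue",
    "compute_gt",
    "invert_gt",
    "gt_from_tsh_ft4",
    "tsh_from_gt_ft4",
    "min_feasible_gt",
]

#: Reference range of SPINA-GT in pmol/s (inclusive bounds).
GT_REFERENCE_RANGE = (1.4, 8.7)

# FT4 enters the formula in mol/L; GT is reported in pmol/s.
_PMOL_PER_MOL = 1e12


class DomainError(ValueError):
    """An input lies outside the physical domain of a formula."""


class InfeasibleGtError(ValueError):
    """A (GT, FT4) pair below the TSH -> infinity asymptote of the model."""

    def __init__(self, gt: float, ft4: float, gt_min: float):
        self.gt = gt
        self.ft4 = ft4
        self.gt_min = gt_min
        super().__init__(
            f"gt={gt:g} pmol/s is infeasible at ft4={ft4:g} pmol/L: "
            f"the model requires gt > {gt_min:.6g} pmol/s (the capacity "
            "needed to sustain this FT4 at unboundedly large TSH)"
        )


@dataclass(frozen=True)
class SpinaConstants:
    """Physiological constants of the secretory-capacity formula.

    Attributes
    ----------
    alpha_t : float
        Dilution factor for thyroxine, 1/L.
    beta_t : float
        Clearance exponent for T4, 1/s.
    d_t : float
        Damping constant (EC50) of TSH at the thyroid, mIU/L.
    k41 : float
        Dissociation constant of T4 at thyroxine-binding globulin, L/mol.
    k42 : float
        Dissociation constant of T4 at transthyretin, L/mol.
    tbg : float
        Standard TBG concentration, mol/L.
    tbpa : float
        Standard transthyretin concentration, mol/L.
    """

    alpha_t: float = 0.1
    beta_t: float = 1.1e-6
    d_t: float = 2.75
    k41: float = 2e10
    k42: float = 2e8
    tbg: float = 300e-9
    tbpa: float = 4.5e-6

    def __post_init__(self) -> None:
        for name in ("alpha_t", "beta_t", "d_t", "k41", "k42", "tbg", "tbpa"):
            value = getattr(self, name)
            if not value > 0:
                raise DomainError(f"SpinaConstants.{name} must be > 0, got {value!r}")

    @property
    def binding_factor(self) -> float:
        """Free-to-total T4 conversion factor ``1 + K41*TBG + K42*TBPA``.

        6901 with the default constants.
        """
        return 1.0 + self.k41 * self.tbg + self.k42 * self.tbpa


DEFAULT_CONSTANTS = SpinaConstants()


@dataclass(frozen=True)
class HormonePair:
    """One subject's paired serum measurement: TSH in mIU/L, FT4 in pmol/L."""

    tsh: float
    ft4: float

    def __post_init__(self) -> None:
        if not self.tsh > 0:
            raise DomainError(f"tsh must be > 0 mIU/L, got {self.tsh!r}")
        if not self.ft4 > 0:
            raise DomainError(f"ft4 must be > 0 pmol/L, got {self.ft4!r}")


@dataclass(frozen=True)
class GtValue:
    """A secretory-capacity estimate in pmol/s with its reference-range flag."""

    gt: float
    in_reference_range: bool

    @classmethod
    def from_gt(cls, gt: float) -> "GtValue":
        lo, hi = GT_REFERENCE_RANGE
        return cls(gt=gt, in_reference_range=lo <= gt <= hi)


def gt_from_tsh_ft4(tsh, ft4, constants: SpinaConstants = DEFAULT_CONSTANTS):
    """Vectorised secretory capacity: arrays of TSH (mIU/L), FT4 (pmol/L) -> GT (pmol/s).

    No domain checking; scalar users should call :func:`compute_gt`.
    """
    ft4_mol = np.asarray(ft4, dtype=float) / _PMOL_PER_MOL
    tsh = np.asarray(tsh, dtype=float)
    gt_mol = (
        constants.beta_t
        * (constants.d_t + tsh)
        * constants.binding_factor
        * ft4_mol
        / (constants.alpha_t * tsh)
    )
    return gt_mol * _PMOL_PER_MOL


def min_feasible_gt(ft4, constants: SpinaConstants = DEFAULT_CONSTANTS):
    """Infimum of feasible GT (pmol/s) at a given FT4: the TSH -> infinity asymptote."""
    ft4_mol = np.asarray(ft4, dtype=float) / _PMOL_PER_MOL
    return (
        constants.beta_t * constants.binding_factor * ft4_mol / constants.alpha_t
    ) * _PMOL_PER_MOL


def tsh_from_gt_ft4(gt, ft4, constants: SpinaConstants = DEFAULT_CONSTANTS):
    """Vectorised algebraic inverse: TSH (mIU/L) sustaining capacity ``gt`` at ``ft4``.

    Where ``gt`` is at or below the asymptote the result is inf/negative;
    callers must mask.  Scalar users should call :func:`invert_gt`.
    """
    ft4_mol = np.asarray(ft4, dtype=float) / _PMOL_PER_MOL
    gt_mol = np.asarray(gt, dtype=float) / _PMOL_PER_MOL
    bc = constants.beta_t * constants.binding_factor * ft4_mol
    with np.errstate(divide="ignore", invalid="ignore"):
        return constants.d_t * bc / (constants.alpha_t * gt_mol - bc)


def compute_gt(
    pair: HormonePair, constants: SpinaConstants = DEFAULT_CONSTANTS
) -> GtValue:
    """Secretory capacity of the thyroid from one TSH/FT4 pair.

    GT is strictly decreasing in TSH at fixed FT4 (through the factor
    ``1 + D_T/TSH``) and linear in FT4 at fixed TSH.

    Raises
    ------
    DomainError
        If TSH or FT4 is non-positive (enforced by :class:`HormonePair`).
    """
    gt = float(gt_from_tsh_ft4(pair.tsh, pair.ft4, constants))
    return GtValue.from_gt(gt)


def invert_gt(
    gt: float, ft4: float, constants: SpinaConstants = DEFAULT_CONSTANTS
) -> float:
    """The TSH (mIU/L) at which a gland of capacity ``gt`` sustains ``ft4``.

    Exact algebraic inverse of :func:`compute_gt` in its TSH argument;
    ``invert_gt(compute_gt(HormonePair(t, f)).gt, f) == t`` up to rounding.

    Raises
    ------
    DomainError
        If ``gt`` or ``ft4`` is non-positive.
    InfeasibleGtError
        If ``gt`` does not exceed the minimum capacity able to sustain
        ``ft4`` (the TSH -> infinity asymptote); the message states that
        minimum.
    """
    if not ft4 > 0:
        raise DomainError(f"ft4 must be > 0 pmol/L, got {ft4!r}")
    if not gt > 0:
        raise DomainError(f"gt must be > 0 pmol/s, got {gt!r}")
    gt_min = float(min_feasible_gt(ft4, constants))
    if gt <= gt_min:
        raise InfeasibleGtError(gt, ft4, gt_min)
    tsh = float(tsh_from_gt_ft4(gt, ft4, constants))
    if not math.isfinite(tsh) or tsh <= 0:  # pragma: no cover - guarded above
        raise InfeasibleGtError(gt, ft4, gt_min)
    return tsh
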