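"""Screening cost model for classifier-based triage.

When an imaging classifier triages a population before the expensive
confirmatory amyloid test (CSF or PET), the resources needed to recruit a
fixed number of amyloid-positive subjects depend on the classifier's
precision P and recall R and on the population prevalence rho:

    savings_cost  = 1 - (1 / (2 * C_avg)) * (rho * C_PET / P + C_MRI / R)
    savings_tests = 1 - rho / P

The first is the fractional reduction of total economic cost (C_MRI and
C_PET are the unit costs of the screening MRI and of the confirmatory
test; C_avg the average per-participant cost of standard screening); the
second is the fraction of confirmatory tests spared.  Both can be
negative: a poor classifier costs more than no triage at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SavingsParams",
    "SavingsResult",
    "savings_cost",
    "savings_tests",
    "pr_savings_surface",
    "SavingsSurface",
]


@dataclass(frozen=True)
class SavingsParams:
    """Prevalence and unit costs of the triage scenario.

    Defaults: confirmatory test 3000 cost units, screening MRI 700, and
    the average screening cost the arithmetic mean of the two (1850).
    The CSF and PET confirmatory tests are treated as one cost parameter.
    """

    rho: float = 0.20
    c_mri: float = 700.0
    c_pet: float = 3000.0
    c_avg: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.c_avg is None:
            object.__setattr__(self, "c_avg", 0.5 * (self.c_mri + self.c_pet))
        if not 0 < self.rho < 1:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        for name in ("c_mri", "c_pet", "c_avg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class SavingsResult:
    savings_cost: float
    savings_tests: float

    def __post_init__(self) -> None:
        if self.savings_cost > 1 or self.savings_tests > 1:
            raise ValueError("savings fractions cannot exceed 1")


def savings_cost(P: float, R: float, params: SavingsParams = SavingsParams()) -> float:
    """Fractional reduction of total screening cost at operating point (P, R)."""
    if not 0 < P <= 1:
        raise ValueError(f"precision must be in (0, 1], got {P}")
    if not 0 < R <= 1:
        raise ValueError(f"recall must be in (0, 1], got {R}")
    return 1.0 - (params.rho * params.c_pet / P + params.c_mri / R) / (2.0 * params.c_avg)


def savings_tests(P: float, rho: float) -> float:
    """Fraction of confirmatory CSF/PET tests spared at precision P."""
    if not 0 < P <= 1:
        raise ValueError(f"precision must be in (0, 1], got {P}")
    if not 0 < rho < 1:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    return 1.0 - rho / P


@dataclass
class SavingsSurface:
    """Savings evaluated on a (recall, precision) lattice."""

    recall: np.ndarray           # 1-D grid, ascending, in (0, 1]
    precision: np.ndarray        # 1-D grid, ascending, in (0, 1]
    values: np.ndarray           # (n_recall, n_precision) savings_cost lattice
    negative_region: np.ndarray  # bool lattice where savings < 0
    contours: dict[float, list[np.ndarray]]  # iso-level -> list of (R, P) polylines


def pr_savings_surface(
    params: SavingsParams = SavingsParams(),
    grid_resolution: int = 101,
    iso_levels: Sequence[float] = (0.0, 0.2, 0.4, 0.6),
) -> SavingsSurface:
    """Evaluate the cost-savings surface over precision-recall space.

    The grid is open at 0 (P = 0 or R = 0 means infinite cost) and closed
    at 1.  Iso-savings contours are extracted with a marching-squares
    routine and returned as (R, P) polylines; levels outside the surface
    range get an empty polyline list.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    from skimage import measure

    axis = np.linspace(0.0, 1.0, grid_resolution + 1)[1:]  # open at 0
    R, P = np.meshgrid(axis, axis, indexing="ij")
    values = 1.0 - (params.rho * params.c_pet / P + params.c_mri / R) / (2.0 * params.c_avg)
    contours: dict[float, list[np.ndarray]] = {}
    step = axis[1] - axis[0]
    for level in iso_levels:
        lines = measure.find_contours(values, level=level)
        polylines = []
        for line in lines:
            # convert from fractional grid indices to (R, P) coordinates
            polylines.append(np.column_stack([axis[0] + line[:, 0] * step, axis[0] + line[:, 1] * step]))
        contours[float(level)] = polylines
    return SavingsSurface(
        recall=axis,
        precision=axis,
        values=values,
        negative_region=values < 0,
        contours=contours,
    )
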