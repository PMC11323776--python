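"""Core domain types for the HOLC-grade / census-tract analysis pipeline.

All geometry is planar: coordinates are assumed to be in a consistent
equal-area projection with a single length unit, and no reprojection is
ever attempted. Areas are in the squared coordinate unit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

from shapely.geometry.base import BaseGeometry

#: HOLC security-map grades in order of desirability, "A" (best) first.
#: "E" is a heterogeneous extra category carried through linkage so that it
#: can be excluded explicitly downstream, never silently reassigned.
GRADES = ("A", "B", "C", "D", "E")

#: Grades that enter the statistical analyses.
ANALYSIS_GRADES = ("A", "B", "C", "D")

#: Adjacent grade pairs compared in the pairwise and causal analyses,
#: written (lower/less desirable, higher/more desirable).
GRADE_PAIRS = (("B", "A"), ("C", "B"), ("D", "C"))

REGIONS = ("Midwest", "Northeast", "South", "West")

#: The eight 1940 sociodemographic confounders, in a fixed column order.
COVARIATE_COLUMNS = (
    "pct_black",
    "pct_nonwhite",
    "pct_foreign_white",
    "median_home_value",
    "pct_college",
    "pct_unemployed",
    "pct_renter",
    "pop_density",
)

#: Columns measured as percentages of the tract population / dwelling stock.
PERCENT_COLUMNS = (
    "pct_black",
    "pct_nonwhite",
    "pct_foreign_white",
    "pct_college",
    "pct_unemployed",
    "pct_renter",
)

OUTCOME_COLUMNS = ("diabetes", "obesity", "hypertension")


class DataError(ValueError):
    """Raised when input data violate a structural contract."""


@dataclass(frozen=True)
class GradedArea:
    """One HOLC-graded polygon (possibly multi-part) with its grade label."""

    area_id: str
    grade: str
    geometry: BaseGeometry
    city_region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise DataError(
                f"graded area {self.area_id!r}: grade {self.grade!r} "
                f"not one of {GRADES}"
            )
        if self.geometry.is_empty or self.geometry.area <= 0:
            raise DataError(
                f"graded area {self.area_id!r}: empty or zero-area geometry"
            )


@dataclass(frozen=True)
class TractGeometry:
    """A census tract polygon with its precomputed planar area."""

    tract_id: str
    geometry: BaseGeometry
    area: float = 0.0

    def __post_init__(self) -> None:
        if self.geometry.is_empty or self.geometry.area <= 0:
            raise DataError(f"tract {self.tract_id!r}: empty or zero-area geometry")
        geom_area = self.geometry.area
        if self.area == 0.0:
            object.__setattr__(self, "area", geom_area)
        elif not math.isclose(self.area, geom_area, rel_tol=1e-9):
            raise DataError(
                f"tract {self.tract_id!r}: declared area {self.area} disagrees "
                f"with geometric area {geom_area}"
            )


@dataclass(frozen=True)
class Covariates1940:
    """The eight 1940 sociodemographic confounders for one tract.

    Percentages are on the 0-100 scale; ``median_home_value`` is in
    thousands of dollars and ``pop_density`` in thousands of persons
    per square kilometre.
    """

    pct_black: float
    pct_nonwhite: float
    pct_foreign_white: float
    median_home_value: float
    pct_college: float
    pct_unemployed: float
    pct_renter: float
    pop_density: float

    def __post_init__(self) -> None:
        for name in PERCENT_COLUMNS:
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise DataError(f"{name}={v} outside [0, 100]")
        # Black residents are a subset of non-White residents.
        if self.pct_black > self.pct_nonwhite + 1e-9:
            raise DataError(
                f"pct_black {self.pct_black} exceeds pct_nonwhite {self.pct_nonwhite}"
            )
        if self.median_home_value <= 0:
            raise DataError(f"median_home_value={self.median_home_value} not > 0")
        if self.pop_density <= 0:
            raise DataError(f"pop_density={self.pop_density} not > 0")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class OutcomePrevalence:
    """Crude prevalence (%) of the three cardiovascular risk factors.

    Hypertension may be missing (NaN): the source surfaces lack it for
    some states, so analyses are complete-case per outcome.
    """

    diabetes: float
    obesity: float
    hypertension: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("diabetes", "obesity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise DataError(f"{name}={v} outside [0, 100]")
        if not math.isnan(self.hypertension) and not (0.0 <= self.hypertension <= 100.0):
            raise DataError(f"hypertension={self.hypertension} outside [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TractLink:
    """Overlap of one tract with the graded layer, and the assigned grade.

    ``overlap_fraction_by_grade`` uses the tract's own area as denominator
    and includes grade E. ``method`` records whether the grade came from the
    maximal-area-overlap rule or from centroid containment.
    """

    tract_id: str
    overlap_fraction_by_grade: dict[str, float]
    total_graded_fraction: float
    assigned_grade: Optional[str] = None
    method: str = "area_overlap"
    passed_threshold: bool = False

    def __post_init__(self) -> None:
        for g, f in self.overlap_fraction_by_grade.items():
            if g not in GRADES:
                raise DataError(f"tract {self.tract_id!r}: unknown grade {g!r}")
            if not (-1e-9 <= f <= 1.0 + 1e-9):
                raise DataError(
                    f"tract {self.tract_id!r}: overlap fraction {f} for grade {g} "
                    "outside [0, 1]"
                )
        total = sum(self.overlap_fraction_by_grade.values())
        if abs(total - self.total_graded_fraction) > 1e-9:
            raise DataError(
                f"tract {self.tract_id!r}: total_graded_fraction "
                f"{self.total_graded_fraction} != sum of fractions {total}"
            )
        if self.method not in ("area_overlap", "centroid"):
            raise DataError(f"unknown linkage method {self.method!r}")


@dataclass(frozen=True)
class TractRecord:
    """One analysis row: linkage, 1940 covariates, region, and outcomes."""

    tract_id: str
    link: TractLink
    covariates: Covariates1940
    region: str
    outcomes: OutcomePrevalence

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise DataError(
                f"tract {self.tract_id!r}: region {self.region!r} not one of {REGIONS}"
            )


@dataclass
class Provenance:
    """Ordered exclusion counts along the dataset-assembly chain."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def record(self, step: str, n_remaining: int) -> None:
        if self.steps and n_remaining > self.steps[-1][1]:
            raise DataError(
                f"provenance step {step!r}: count {n_remaining} exceeds previous "
                f"step's {self.steps[-1][1]}"
            )
        self.steps.append((step, n_remaining))

    def as_dict(self) -> dict[str, int]:
        return dict(self.steps)


@dataclass
class AnalyticDataset:
    """The assembled analysis table with its exclusion provenance."""

    rows: list[TractRecord]
    provenance: Provenance
    overlap_threshold: float = 0.25
    linkage_method: str = "area_overlap"

    def __post_init__(self) -> None:
        ids = [r.tract_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise DataError("duplicate tract_id in analytic dataset")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self):
        """Flatten to a pandas DataFrame (one row per tract)."""
        import pandas as pd

        records = []
        for r in self.rows:
            d = {"tract_id": r.tract_id, "grade": r.link.assigned_grade,
                 "region": r.region}
            d.update(r.covariates.as_dict())
            d.update(r.outcomes.as_dict())
            records.append(d)
        return pd.DataFrame.from_records(records)
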