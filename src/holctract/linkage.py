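"""Assigning HOLC grades to census tracts by areal overlap or centroid.

The primary rule assigns each tract the grade whose polygons cover the
most land area within it, after discarding tracts whose total graded
coverage falls below a threshold (25% in the main analysis, 50% in
sensitivity runs). A centroid-containment rule is provided as the
alternative linkage, and the same centroid criterion builds the
2020-to-1940 tract crosswalk used to attach historical covariates.

Graded polygons of the same grade are unioned before intersection, so
internal seams between adjacent same-grade polygons cannot double-count
area. Polygons of *different* grades are assumed not to overlap; if they
do, a warning reports the overlapped area (fractions are still computed
against each grade union independently).

Tie-breaking is always toward the more desirable grade, in the fixed
order A < B < C < D < E: deterministic, and conservative against finding
adverse effects of less desirable grades. Ties are measure-zero on real
geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from shapely import make_valid
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .types import DataError, GradedArea, TractGeometry, TractLink, GRADES

#: Fractions smaller than this are treated as zero overlap (slivers from
#: floating-point intersection noise).
_ZERO_FRACTION = 1e-15


@dataclass
class Crosswalk1940:
    """Mapping from 2020 tract ids to the 1940 tract containing each centroid."""

    mapping: dict[str, Optional[str]] = field(default_factory=dict)

    def __getitem__(self, tract_id_2020: str) -> Optional[str]:
        return self.mapping[tract_id_2020]

    def __len__(self) -> int:
        return len(self.mapping)

    def matched(self) -> dict[str, str]:
        """Only the 2020 tracts that found a 1940 parent."""
        return {k: v for k, v in self.mapping.items() if v is not None}


def _valid_geometry(geom: BaseGeometry, label: str) -> BaseGeometry:
    """Return a valid version of *geom*, repairing if possible."""
    if geom.is_valid:
        return geom
    repaired = make_valid(geom)
    if not repaired.is_valid or repaired.is_empty:
        raise DataError(f"invalid geometry for {label!r} could not be repaired")
    return repaired


def grade_unions(areas: Iterable[GradedArea]) -> dict[str, BaseGeometry]:
    """Union the graded polygons grade by grade, warning on cross-grade overlap."""
    by_grade: dict[str, list[BaseGeometry]] = {}
    for a in areas:
        geom = _valid_geometry(a.geometry, a.area_id)
        by_grade.setdefault(a.grade, []).append(geom)
    unions = {g: unary_union(gs) for g, gs in by_grade.items()}

    grades = sorted(unions)
    for i, g1 in enumerate(grades):
        for g2 in grades[i + 1 :]:
            inter = unions[g1].intersection(unions[g2])
            if inter.area > 1e-9 * min(unions[g1].area, unions[g2].area):
                warnings.warn(
                    f"graded areas of grades {g1} and {g2} overlap "
                    f"(area {inter.area:g}); fractions may double-count",
                    stacklevel=2,
                )
    return unions


def compute_overlaps(
    tracts: Sequence[TractGeometry],
    areas: Sequence[GradedArea],
) -> list[TractLink]:
    """Per-tract overlap fraction with each grade's unioned polygons.

    The denominator is the tract's own area, so fractions lie in [0, 1]
    and sum to the total graded coverage of the tract. Grades are not yet
    assigned (``assigned_grade`` is None).
    """
    unions = grade_unions(areas)
    links: list[TractLink] = []
    for t in tracts:
        geom = _valid_geometry(t.geometry, t.tract_id)
        fractions: dict[str, float] = {}
        for g, u in unions.items():
            frac = geom.intersection(u).area / t.area
            if frac > _ZERO_FRACTION:
                fractions[g] = min(frac, 1.0)
        links.append(
            TractLink(
                tract_id=t.tract_id,
                overlap_fraction_by_grade=fractions,
                total_graded_fraction=sum(fractions.values()),
                assigned_grade=None,
                method="area_overlap",
                passed_threshold=False,
            )
        )
    return links


def _argmax_grade(
    fractions: Mapping[str, float], grade_set: Sequence[str]
) -> Optional[str]:
    """Grade with the largest fraction; ties go to the more desirable grade."""
    best: Optional[str] = None
    best_frac = 0.0
    for g in GRADES:  # fixed desirability order breaks ties toward A
        if g not in grade_set:
            continue
        f = fractions.get(g, 0.0)
        if f > best_frac:
            best, best_frac = g, f
    return best


def assign_grade_by_area(
    link: TractLink,
    threshold: float = 0.25,
    grade_set: Sequence[str] = GRADES,
) -> TractLink:
    """Apply the maximal-area-overlap rule and the coverage threshold.

    ``passed_threshold`` tests the *total* graded coverage (sum over all
    five grades), matching a filter applied before grade assignment; the
    winning grade is then the argmax over ``grade_set``. Grade E may win
    and is excluded downstream, never silently reassigned.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    fractions = link.overlap_fraction_by_grade
    return TractLink(
        tract_id=link.tract_id,
        overlap_fraction_by_grade=dict(fractions),
        total_graded_fraction=link.total_graded_fraction,
        assigned_grade=_argmax_grade(fractions, grade_set),
        method="area_overlap",
        passed_threshold=link.total_graded_fraction >= threshold,
    )


def assign_grade_by_centroid(
    tract: TractGeometry,
    areas: Sequence[GradedArea],
    unions: Optional[Mapping[str, BaseGeometry]] = None,
) -> TractLink:
    """Assign the grade of the polygon containing the tract's centroid.

    The geometric centroid is used even when it falls outside a non-convex
    tract. A centroid exactly on a shared boundary (measure-zero) goes to
    the more desirable grade. The overlap-fraction map is still populated
    for diagnostics; ``passed_threshold`` is True whenever a grade was
    found, since the centroid rule has no coverage threshold.
    """
    if unions is None:
        unions = grade_unions(areas)
    geom = _valid_geometry(tract.geometry, tract.tract_id)
    centroid = geom.centroid

    fractions: dict[str, float] = {}
    assigned: Optional[str] = None
    for g in GRADES:  # desirability order resolves boundary ties toward A
        u = unions.get(g)
        if u is None:
            continue
        frac = geom.intersection(u).area / tract.area
        if frac > _ZERO_FRACTION:
            fractions[g] = min(frac, 1.0)
        if assigned is None and u.covers(centroid):
            assigned = g
    return TractLink(
        tract_id=tract.tract_id,
        overlap_fraction_by_grade=fractions,
        total_graded_fraction=sum(fractions.values()),
        assigned_grade=assigned,
        method="centroid",
        passed_threshold=assigned is not None,
    )


def link_tracts(
    tracts: Sequence[TractGeometry],
    areas: Sequence[GradedArea],
    method: str = "area_overlap",
    threshold: float = 0.25,
) -> list[TractLink]:
    """Run the full linkage for a layer pair with either method."""
    if method == "area_overlap":
        return [
            assign_grade_by_area(lk, threshold=threshold)
            for lk in compute_overlaps(tracts, areas)
        ]
    if method == "centroid":
        unions = grade_unions(areas)
        return [assign_grade_by_centroid(t, areas, unions=unions) for t in tracts]
    raise ValueError(f"unknown linkage method {method!r}")


def build_crosswalk_1940(
    tracts_2020: Sequence[TractGeometry],
    tracts_1940: Sequence[TractGeometry],
) -> Crosswalk1940:
    """Link each 2020 tract to the 1940 tract containing its centroid.

    1940 tracts are assumed to partition their extent; two 1940 tracts
    both strictly containing a centroid is an error. A centroid on a
    shared boundary or outside the 1940 layer maps to None.
    """
    geoms_1940 = [
        (t.tract_id, _valid_geometry(t.geometry, t.tract_id)) for t in tracts_1940
    ]
    mapping: dict[str, Optional[str]] = {}
    for t in tracts_2020:
        centroid = _valid_geometry(t.geometry, t.tract_id).centroid
        parents = [tid for tid, g in geoms_1940 if g.contains(centroid)]
        if len(parents) > 1:
            raise DataError(
                f"2020 tract {t.tract_id!r}: centroid inside multiple 1940 "
                f"tracts {parents} (1940 layer is not a partition)"
            )
        mapping[t.tract_id] = parents[0] if parents else None
    return Crosswalk1940(mapping=mapping)
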