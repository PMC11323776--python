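"""Reading and writing the pipeline's file formats.

Polygon layers travel as GeoJSON FeatureCollections (grade under a
configurable property key, default ``"grade"``); tabular data as
comma-separated UTF-8 CSV with a header and a ``tract_id`` key column.
Missing values are encoded as empty fields and are legal only in the
``hypertension`` column.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry import MultiPolygon, Polygon

from .types import (
    ANALYSIS_GRADES,
    COVARIATE_COLUMNS,
    GRADES,
    OUTCOME_COLUMNS,
    REGIONS,
    AnalyticDataset,
    Covariates1940,
    DataError,
    GradedArea,
    OutcomePrevalence,
    Provenance,
    TractGeometry,
    TractLink,
    TractRecord,
)

PathLike = Union[str, Path]

_TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "covariates": COVARIATE_COLUMNS + ("region",),
    "outcomes": OUTCOME_COLUMNS,
    "crosswalk": ("assigned_grade",),
}


def read_polygon_layer(
    path: PathLike,
    kind: str,
    grade_property: str = "grade",
    id_property: str = "id",
) -> Union[list[GradedArea], list[TractGeometry]]:
    """Read a GeoJSON FeatureCollection as graded areas or tract geometries.

    Parameters
    ----------
    path : str or Path
        GeoJSON file with polygonal (Polygon/MultiPolygon) features.
    kind : {"graded_areas", "tracts"}
        Target record type.
    grade_property, id_property : str
        Feature property keys holding the grade label and the feature id.
    """
    if kind not in ("graded_areas", "tracts"):
        raise ValueError(f"kind must be 'graded_areas' or 'tracts', got {kind!r}")
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise DataError(f"{path}: not a GeoJSON FeatureCollection")

    records: list = []
    bad_grades: list[str] = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        fid = str(props.get(id_property, feat.get("id", f"feature{i}")))
        geom_json = feat.get("geometry")
        if geom_json is None:
            raise DataError(f"feature {fid!r}: empty geometry")
        geom = shape(geom_json)
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise DataError(
                f"feature {fid!r}: non-polygonal geometry {geom.geom_type}"
            )
        if geom.is_empty:
            raise DataError(f"feature {fid!r}: empty geometry")
        if kind == "graded_areas":
            if grade_property not in props:
                raise DataError(
                    f"feature {fid!r}: missing grade property {grade_property!r}"
                )
            grade = str(props[grade_property])
            if grade not in GRADES:
                bad_grades.append(grade)
                continue
            records.append(
                GradedArea(
                    area_id=fid,
                    grade=grade,
                    geometry=geom,
                    city_region=props.get("city_region"),
                )
            )
        else:
            records.append(TractGeometry(tract_id=fid, geometry=geom))
    if bad_grades:
        raise DataError(
            f"{path}: grade labels outside {GRADES}: {sorted(set(bad_grades))}"
        )
    _check_unique_ids(records, kind)
    return records


def _check_unique_ids(records: Sequence, kind: str) -> None:
    ids = [r.area_id if kind == "graded_areas" else r.tract_id for r in records]
    seen: set[str] = set()
    for rid in ids:
        if rid in seen:
            raise DataError(f"duplicate feature id {rid!r}")
        seen.add(rid)


def write_polygon_layer(
    path: PathLike,
    records: Iterable[Union[GradedArea, TractGeometry]],
    grade_property: str = "grade",
    id_property: str = "id",
) -> None:
    """Write graded areas or tract geometries back to GeoJSON."""
    features = []
    for r in records:
        props: dict = {}
        if isinstance(r, GradedArea):
            props[id_property] = r.area_id
            props[grade_property] = r.grade
            if r.city_region is not None:
                props["city_region"] = r.city_region
        else:
            props[id_property] = r.tract_id
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(r.geometry)}
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_table(path: PathLike, schema: str) -> pd.DataFrame:
    """Read a keyed CSV table and validate it against a named schema.

    Returns a DataFrame indexed by ``tract_id``. Empty cells are legal only
    in the ``hypertension`` column (become NaN); elsewhere they are an
    error, as are non-numeric values in numeric columns and duplicate keys.
    """
    if schema not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    want = _TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, dtype={"tract_id": str}, keep_default_na=False,
                     na_values=[""])
    missing_cols = [c for c in ("tract_id",) + want if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: missing columns {missing_cols}")
    if df["tract_id"].duplicated().any():
        dups = df.loc[df["tract_id"].duplicated(), "tract_id"].tolist()
        raise DataError(f"{path}: duplicate tract_id {sorted(set(dups))}")

    string_cols = {"region", "assigned_grade"}
    for col in want:
        if col in string_cols:
            bad = df[col].isna()
            if bad.any():
                raise DataError(
                    f"{path}: empty value in column {col!r} at row "
                    f"{int(np.flatnonzero(bad)[0]) + 2}"
                )
            continue
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header line
            raise DataError(
                f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column "
                f"{col!r} at row {row}"
            )
        empty = raw.isna()
        if empty.any() and col != "hypertension":
            row = int(np.flatnonzero(empty)[0]) + 2
            raise DataError(f"{path}: empty cell in column {col!r} at row {row}")
        df[col] = numeric
    if schema == "covariates":
        bad_region = ~df["region"].isin(REGIONS)
        if bad_region.any():
            raise DataError(
                f"{path}: region labels outside {REGIONS}: "
                f"{sorted(df.loc[bad_region, 'region'].unique())}"
            )
    return df.set_index("tract_id")


def write_table(path: PathLike, df: pd.DataFrame) -> None:
    """Write a results/interchange table as CSV (missing -> empty field)."""
    out = df.reset_index() if df.index.name == "tract_id" else df
    out.to_csv(path, index=False, na_rep="")


def links_to_frame(links: Iterable[TractLink]) -> pd.DataFrame:
    """Tabulate tract links as the crosswalk CSV layout."""
    rows = []
    for lk in links:
        row = {
            "tract_id": lk.tract_id,
            "assigned_grade": lk.assigned_grade or "",
            "method": lk.method,
            "total_graded_fraction": lk.total_graded_fraction,
            "passed_threshold": lk.passed_threshold,
        }
        for g in GRADES:
            row[f"frac_{g}"] = lk.overlap_fraction_by_grade.get(g, 0.0)
        rows.append(row)
    return pd.DataFrame.from_records(rows)


def assemble_dataset(
    links: Mapping[str, TractLink],
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
    overlap_threshold: float = 0.25,
    linkage_method: str = "area_overlap",
) -> AnalyticDataset:
    """Join linkage, covariates and outcomes into the analytic dataset.

    Exclusion order (each step recorded in provenance):

    1. tracts failing the overlap threshold (or with no assigned grade);
    2. tracts whose winning grade is E;
    3. tracts without a 1940 covariate/region record;
    4. tracts missing both diabetes and obesity prevalence.

    Rows missing only hypertension are retained; per-outcome analyses drop
    them later (complete-case per outcome).
    """
    prov = Provenance()
    prov.record("linked", len(links))

    kept = {
        t: lk
        for t, lk in links.items()
        if lk.passed_threshold and lk.assigned_grade is not None
    }
    prov.record("overlap_threshold", len(kept))

    kept = {t: lk for t, lk in kept.items() if lk.assigned_grade in ANALYSIS_GRADES}
    prov.record("grade_E_removed", len(kept))

    kept = {t: lk for t, lk in kept.items() if t in covariates.index}
    prov.record("covariate_join", len(kept))

    rows: list[TractRecord] = []
    for t in kept:
        if t not in outcomes.index:
            continue
        out = outcomes.loc[t]
        if pd.isna(out["diabetes"]) and pd.isna(out["obesity"]):
            continue
        cov = covariates.loc[t]
        rows.append(
            TractRecord(
                tract_id=t,
                link=kept[t],
                covariates=Covariates1940(
                    **{c: float(cov[c]) for c in COVARIATE_COLUMNS}
                ),
                region=str(cov["region"]),
                outcomes=OutcomePrevalence(
                    diabetes=float(out["diabetes"]),
                    obesity=float(out["obesity"]),
                    hypertension=float(out["hypertension"])
                    if "hypertension" in out and not pd.isna(out["hypertension"])
                    else math.nan,
                ),
            )
        )
    prov.record("outcome_join", len(rows))
    if not rows:
        raise DataError("no analyzable tracts after exclusions")
    return AnalyticDataset(
        rows=rows,
        provenance=prov,
        overlap_threshold=overlap_threshold,
        linkage_method=linkage_method,
    )
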