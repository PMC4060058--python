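"""File formats: measurement tables, contour files, and section measurement.

Two on-disk dialects are supported for traced contours — a flat CSV
(``contour_id,label,vertex_index,x_mm,y_mm``) and a JSON ROI document
(``{"section_id": ..., "contours": [{"label": ..., "vertices": [[x, y],
...]}]}``) — plus the long-format measurement-table CSV with columns
``individual,element,side,level,circumference_mm,area_mm2,thickness_mm,
status,partial_year``.  Absence reasons are encoded as explicit sentinel
statuses (``not_fully_traceable`` / ``not_observed`` / ``not_measured``)
rather than empty cells, so they survive round-trips.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contours import (AnnularSection, Contour, perimeter, enclosed_area,
                       principal_frame, radial_profile)
from .records import (ELEMENTS, STATUSES, ElementRecord, GrowthMark,
                      HatchlingBaseline, RecordError)

__all__ = [
    "MEASUREMENT_COLUMNS",
    "LEVELS",
    "read_measurement_table", "write_measurement_table",
    "records_from_table", "table_from_records",
    "read_contours_csv", "write_contours_csv",
    "read_section_json", "write_section_json",
    "measure_section",
]

MEASUREMENT_COLUMNS = ("individual", "element", "side", "level",
                       "circumference_mm", "area_mm2", "thickness_mm",
                       "status", "partial_year")
LEVELS = ("medullary", "hatchling") + tuple(f"cgm{i}" for i in range(1, 6)) \
    + ("surface",)

_CGM_RE = re.compile(r"^cgm(\d+)$")


# ---------------------------------------------------------------------------
# measurement tables

def read_measurement_table(path) -> pd.DataFrame:
    """Read and validate a Table-1-schema measurement CSV."""
    df = pd.read_csv(path, dtype={"partial_year": "boolean"})
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise RecordError(f"measurement table missing columns: {sorted(missing)}")
    bad_status = set(df["status"].dropna()) - set(STATUSES)
    if bad_status:
        raise RecordError(f"unknown status values: {sorted(bad_status)}")
    bad_level = set(df["level"]) - set(LEVELS)
    if bad_level:
        raise RecordError(f"unknown level values: {sorted(bad_level)}")
    bad_el = set(df["element"]) - set(ELEMENTS)
    if bad_el:
        raise RecordError(f"unknown elements: {sorted(bad_el)}")
    return df


def write_measurement_table(df: pd.DataFrame, path) -> None:
    df = df.loc[:, list(MEASUREMENT_COLUMNS)]
    df.to_csv(path, index=False)


def _opt(v) -> Optional[float]:
    return None if v is None or pd.isna(v) else float(v)


def records_from_table(df: pd.DataFrame
                       ) -> Tuple[List[ElementRecord], HatchlingBaseline]:
    """Build element records and the shared hatchling baseline from a table.

    Sides whose every row is ``not_measured`` are dropped.  The baseline is
    taken from the ``hatchling`` rows, which repeat identical neonate
    values across individuals.
    """
    base: Dict[str, Tuple[Optional[float], Optional[float], Optional[float]]] = {}
    for el, g in df[df["level"] == "hatchling"].groupby("element"):
        circ = g["circumference_mm"].dropna()
        area = g["area_mm2"].dropna()
        thick = g["thickness_mm"].dropna()
        base[el] = (float(circ.iloc[0]) if len(circ) else None,
                    float(area.iloc[0]) if len(area) else None,
                    float(thick.iloc[0]) if len(thick) else None)
    records: List[ElementRecord] = []
    for (ind, el, side), g in df.groupby(["individual", "element", "side"],
                                         sort=True):
        g = g[g["level"] != "hatchling"]
        if (g["status"] == "not_measured").all():
            continue
        rec = ElementRecord(individual_id=str(ind), element=el, side=side)
        marks = []
        for _, row in g.iterrows():
            level = row["level"]
            m = _CGM_RE.match(level)
            if level == "medullary":
                rec.medullary_circumference = _opt(row["circumference_mm"])
                rec.medullary_area = _opt(row["area_mm2"])
            elif m:
                marks.append(GrowthMark(
                    index=int(m.group(1)),
                    status=row["status"],
                    circumference=_opt(row["circumference_mm"]),
                    cortical_area=_opt(row["area_mm2"]),
                    cumulative_thickness=_opt(row["thickness_mm"])))
            elif level == "surface":
                rec.surface_circumference = _opt(row["circumference_mm"])
                rec.surface_area = _opt(row["area_mm2"])
                rec.surface_cumulative_thickness = _opt(row["thickness_mm"])
                pa = row["partial_year"]
                rec.surface_partial_year = None if pd.isna(pa) else bool(pa)
        rec.marks = sorted(marks, key=lambda m: m.index)
        rec._check_monotone_circumference()
        records.append(rec)
    return records, HatchlingBaseline(base)


def table_from_records(records: Sequence[ElementRecord],
                       baseline: HatchlingBaseline) -> pd.DataFrame:
    """Inverse of :func:`records_from_table` (lossless round-trip)."""
    rows = []
    for e in records:
        def row(level, circ, area, thick, status="fully_traceable",
                partial=None):
            rows.append({"individual": e.individual_id, "element": e.element,
                         "side": e.side, "level": level,
                         "circumference_mm": circ, "area_mm2": area,
                         "thickness_mm": thick, "status": status,
                         "partial_year": partial})
        row("medullary", e.medullary_circumference, e.medullary_area, None)
        if e.element in baseline:
            row("hatchling", baseline.circumference(e.element),
                baseline.cortical_area(e.element),
                baseline.thickness(e.element) if e.side == "left" else None)
        for m in e.marks:
            row(f"cgm{m.index}", m.circumference, m.cortical_area,
                m.cumulative_thickness, m.status)
        row("surface", e.surface_circumference, e.surface_area,
            e.surface_cumulative_thickness,
            partial=e.surface_partial_year)
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    df["partial_year"] = df["partial_year"].astype("boolean")
    return df


# ---------------------------------------------------------------------------
# contour files

def read_contours_csv(path) -> Dict[str, Contour]:
    """Flat contour CSV → mapping contour_id → Contour."""
    df = pd.read_csv(path)
    need = {"contour_id", "label", "vertex_index", "x_mm", "y_mm"}
    if not need <= set(df.columns):
        raise RecordError(f"contour CSV missing columns: "
                          f"{sorted(need - set(df.columns))}")
    if df.empty:
        raise RecordError(f"contour file {path} contains no vertices")
    out = {}
    for cid, g in df.groupby("contour_id", sort=False):
        g = g.sort_values("vertex_index")
        out[str(cid)] = Contour(g[["x_mm", "y_mm"]].to_numpy(float),
                                label=str(g["label"].iloc[0]))
    return out


def write_contours_csv(contours: Dict[str, Contour], path) -> None:
    rows = []
    for cid, c in contours.items():
        for i, (x, y) in enumerate(c.vertices):
            rows.append({"contour_id": cid, "label": c.label,
                         "vertex_index": i, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_section_json(path) -> Tuple[str, List[Contour]]:
    """JSON ROI document → (section_id, contours)."""
    doc = json.loads(Path(path).read_text())
    try:
        contours = [Contour(np.asarray(c["vertices"], float), label=c["label"])
                    for c in doc["contours"]]
        return str(doc["section_id"]), contours
    except (KeyError, TypeError) as exc:
        raise RecordError(f"malformed ROI document {path}: {exc}") from exc


def write_section_json(section_id: str, contours: Sequence[Contour],
                       path) -> None:
    doc = {"section_id": section_id,
           "contours": [{"label": c.label,
                         "vertices": np.asarray(c.vertices).tolist()}
                        for c in contours]}
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# section measurement (contours → measurement-table rows)

def measure_section(individual: str, element: str, side: str,
                    contours: Sequence[Contour]) -> List[dict]:
    """Measure one traced cross-section into measurement-table rows.

    The section's principal frame is computed once on the cortical annulus
    (periosteal surface minus medullary cavity); each growth mark's
    cumulative radial thickness is the mean of the four centroid-to-mark
    distances along the ±principal axes.  Cortical areas subtract the
    medullary area from the area a mark encloses.
    """
    by_label = {c.label: c for c in contours}
    if "surface" not in by_label:
        raise RecordError(f"section {individual}/{element}/{side}: "
                          "no surface contour")
    surface = by_label["surface"]
    medullary = by_label.get("medullary")
    frame = principal_frame(AnnularSection(surface, medullary))
    med_area = enclosed_area(medullary) if medullary is not None else 0.0

    rows: List[dict] = []

    def row(level, circ, area, thick):
        rows.append({"individual": individual, "element": element,
                     "side": side, "level": level, "circumference_mm": circ,
                     "area_mm2": area, "thickness_mm": thick,
                     "status": "fully_traceable", "partial_year": None})

    if medullary is not None:
        row("medullary", perimeter(medullary), med_area, None)
    cgm_labels = sorted((m.group(1) for m in map(_CGM_RE.match, by_label)
                         if m), key=int)
    for n in cgm_labels:
        c = by_label[f"cgm{n}"]
        row(f"cgm{n}", perimeter(c), enclosed_area(c) - med_area,
            radial_profile(frame, c).mean)
    row("surface", perimeter(surface), enclosed_area(surface) - med_area,
        radial_profile(frame, surface).mean)
    return rows
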