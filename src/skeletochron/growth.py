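"""Annual growth quantification from cumulative growth-mark measurements.

Cumulative cortical radial thickness T_n (the mean of four centroid-to-mark
distances along the principal axes) is converted into annual increments
ΔT_n = T_{n+1} − T_n and into daily apposition rates a_n = 1000·ΔT_n / D,
with D the number of growing days in a year (default 214, the active
season of a Louisiana alligator).  Cumulative cortical areas are
differenced the same way.

Year 0 is the hatchling baseline: its "increment" is the neonate cortex
itself and it is never converted to a rate (embryonic growing days are
unknown).  A growth mark merging with the periosteal surface bounds a zone
of less than one year; such a mark is dropped from the series and the final
increment spans from the previous measured mark to the surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .records import ElementRecord, HatchlingBaseline, RecordError

__all__ = [
    "GrowingSeason",
    "AnnualGrowth",
    "annual_increments",
    "apposition_rate",
    "series_increments",
    "element_growth",
    "growth_table",
    "cumulative_curve",
]

SURFACE = "surface"  # sentinel year label for the outermost boundary


@dataclass(frozen=True)
class GrowingSeason:
    """Number of days of active bone apposition per year."""

    days: float = 214.0

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValueError("growing season must be positive")


@dataclass(frozen=True)
class AnnualGrowth:
    """Per-year growth entry for one element (all on the left-side series)."""

    year: object  # 0 (hatchling), 1..n (marks), or "surface"
    level: str
    cumulative_thickness: Optional[float]
    annual_thickness: Optional[float]
    apposition_rate: Optional[float]  # µm/day
    cumulative_area: Optional[float] = None
    annual_area: Optional[float] = None
    excluded: Optional[str] = None  # "not_traceable" | "partial_year"


def apposition_rate(dt: Optional[float],
                    season: GrowingSeason = GrowingSeason()) -> Optional[float]:
    """Daily apposition rate in µm/day from an annual increment in mm."""
    if dt is None:
        return None
    if dt < 0:
        raise RecordError("negative annual increment: resorption not modeled")
    return 1000.0 * dt / season.days


def annual_increments(cumulative: Sequence[Optional[float]]
                      ) -> List[Optional[float]]:
    """Difference a cumulative series; entry 0 is its own increment.

    ``None`` entries propagate absence to both adjacent increments.  A
    strictly decreasing pair of present values is a data-integrity error.
    """
    _check_monotone(cumulative)
    out: List[Optional[float]] = []
    for i, t in enumerate(cumulative):
        if i == 0:
            out.append(t)
        elif t is None or cumulative[i - 1] is None:
            out.append(None)
        else:
            out.append(t - cumulative[i - 1])
    return out


def _check_monotone(values: Sequence[Optional[float]]) -> None:
    present = [v for v in values if v is not None]
    if any(b < a - 1e-9 for a, b in zip(present, present[1:])):
        raise RecordError("cumulative series decreases outward")


def series_increments(mark_values: Dict[int, Optional[float]],
                      surface_value: Optional[float],
                      partial_year: bool = False,
                      delta: float = 0.05,
                      ) -> Tuple[Dict[object, Optional[float]], Optional[int]]:
    """Annual increments for one cumulative series (thickness or area).

    ``mark_values`` maps year ordinal (0 = hatchling, 1.. = marks) to the
    cumulative value or None.  Interior increments require the year-adjacent
    predecessor; the surface increment bridges to the outermost retained
    measured mark (inner losses leave the early years absent, but the final
    zone is still bounded below by the last mark that was traced).

    When ``partial_year`` is set and the outermost measured mark lies within
    a relative gap ``delta`` of the surface, that mark merges with the
    surface: it is excluded from the series and the final increment spans
    from the previous mark.  Returns (increments keyed by year or
    ``"surface"``, excluded mark year or None).
    """
    years = sorted(y for y in mark_values if mark_values[y] is not None)
    ordered = [mark_values[y] for y in sorted(mark_values)]
    if surface_value is not None:
        ordered.append(surface_value)
    _check_monotone(ordered)

    excluded: Optional[int] = None
    if partial_year and years and surface_value is not None:
        t_last = mark_values[years[-1]]
        if t_last and t_last > 0 and years[-1] != 0:
            if (surface_value - t_last) / t_last < delta:
                excluded = years[-1]

    inc: Dict[object, Optional[float]] = {}
    for y in sorted(mark_values):
        t = mark_values[y]
        if y == 0:
            inc[y] = t
        elif t is None or y == excluded:
            inc[y] = None
        else:
            prev = mark_values.get(y - 1)
            inc[y] = (t - prev) if prev is not None else None

    pred_years = [y for y in years if y != excluded]
    if surface_value is not None and pred_years and pred_years[-1] != 0:
        inc[SURFACE] = surface_value - mark_values[pred_years[-1]]
    else:
        inc[SURFACE] = None
    return inc, excluded


def element_growth(e: ElementRecord,
                   baseline: HatchlingBaseline,
                   season: GrowingSeason = GrowingSeason(),
                   delta: float = 0.05) -> List[AnnualGrowth]:
    """Full annual-growth series (thickness, rate, area) for one element.

    Uses the record's explicit partial-year annotation when present; the
    year-0 entry is the hatchling baseline and carries no rate.
    """
    t_marks: Dict[int, Optional[float]] = {0: baseline.thickness(e.element)}
    a_marks: Dict[int, Optional[float]] = {0: baseline.cortical_area(e.element)}
    for m in e.marks:
        t_marks[m.index] = m.cumulative_thickness
        a_marks[m.index] = m.cortical_area
    partial = bool(e.surface_partial_year)
    t_inc, t_excl = series_increments(t_marks, e.surface_cumulative_thickness,
                                      partial, delta)
    a_inc, _ = series_increments(a_marks, e.surface_area, partial, delta)

    def level_name(y) -> str:
        if y == 0:
            return "hatchling"
        if y == SURFACE:
            return SURFACE
        return f"cgm{y}"

    out: List[AnnualGrowth] = []
    for y in sorted(t_marks) + [SURFACE]:
        cum_t = (e.surface_cumulative_thickness if y == SURFACE
                 else t_marks.get(y))
        cum_a = e.surface_area if y == SURFACE else a_marks.get(y)
        dt = t_inc.get(y)
        rate = apposition_rate(dt, season) if y != 0 else None
        reason = None
        if y == t_excl:
            reason = "partial_year"
        elif dt is None and y != 0:
            reason = "not_traceable"
        out.append(AnnualGrowth(
            year=y, level=level_name(y),
            cumulative_thickness=cum_t, annual_thickness=dt,
            apposition_rate=rate,
            cumulative_area=cum_a, annual_area=a_inc.get(y),
            excluded=reason))
    return out


def growth_table(records: Sequence[ElementRecord],
                 baseline: HatchlingBaseline,
                 season: GrowingSeason = GrowingSeason(),
                 delta: float = 0.05,
                 round_dp: Optional[int] = None) -> pd.DataFrame:
    """Annual-growth results for many elements as one tidy DataFrame.

    One row per (individual, element, year level): cumulative and annual
    cortical thickness (mm), apposition rate (µm/day), cumulative and
    annual cortical area (mm²).  ``round_dp`` applies half-up decimal
    rounding for report output; internal computation is full precision.
    """
    rows = []
    for e in records:
        if baseline.thickness(e.element) is None and not e.measurable_marks():
            continue
        for g in element_growth(e, baseline, season, delta):
            rows.append({
                "individual": e.individual_id,
                "element": e.element,
                "side": e.side,
                "level": g.level,
                "cumulative_mm": g.cumulative_thickness,
                "annual_mm": g.annual_thickness,
                "rate_um_day": g.apposition_rate,
                "cumulative_area_mm2": g.cumulative_area,
                "annual_area_mm2": g.annual_area,
                "excluded": g.excluded,
                "partial_year": bool(e.surface_partial_year)
                                and g.level == SURFACE,
            })
    df = pd.DataFrame(rows)
    if round_dp is not None and not df.empty:
        for col in ("cumulative_mm", "annual_mm", "rate_um_day",
                    "cumulative_area_mm2", "annual_area_mm2"):
            df[col] = df[col].map(lambda v: _round_half_up(v, round_dp))
    return df


def _round_half_up(v, dp: int):
    if v is None or pd.isna(v):
        return v
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -dp
    return float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))


def recompute_growth_columns(df: pd.DataFrame,
                             season: GrowingSeason = GrowingSeason(),
                             delta: float = 0.05) -> pd.DataFrame:
    """Recompute annual thickness and rate columns from a cumulative column.

    ``df`` must carry ``individual, element, level, cumulative_mm`` and a
    boolean ``partial_year`` flag on surface rows (the published asterisk).
    Returns the frame with ``annual_mm_computed`` and
    ``rate_um_day_computed`` columns derived solely from the cumulative
    series, for validation against independently reported values.
    """
    out = df.copy()
    out["annual_mm_computed"] = pd.NA
    out["rate_um_day_computed"] = pd.NA
    for (_ind, _el), g in df.groupby(["individual", "element"], sort=False):
        marks: Dict[int, Optional[float]] = {}
        surface = None
        partial = False
        for i, row in g.iterrows():
            v = row["cumulative_mm"]
            v = None if pd.isna(v) else float(v)
            if row["level"] == "hatchling":
                marks[0] = v
            elif row["level"] == SURFACE:
                surface = v
                partial = bool(row.get("partial_year")) \
                    and not pd.isna(row.get("partial_year"))
            else:
                marks[int(str(row["level"])[3:])] = v
        inc, _ = series_increments(marks, surface, partial, delta)
        for i, row in g.iterrows():
            y = (0 if row["level"] == "hatchling"
                 else SURFACE if row["level"] == SURFACE
                 else int(str(row["level"])[3:]))
            dt = inc.get(y)
            out.at[i, "annual_mm_computed"] = dt
            if y != 0:
                out.at[i, "rate_um_day_computed"] = apposition_rate(dt, season)
    return out


def cumulative_curve(series: List[AnnualGrowth]) -> List[Tuple[object, float]]:
    """Running sum of non-excluded annual thickness values (baseline first).

    Elements whose inner marks were resorbed start at their first
    measurable year, so the curve need not connect to the origin.
    """
    # the running sum of annual values telescopes to the measured
    # cumulative series, so the curve is the cumulative value at every year
    # with a defined annual increment (bridged outer gaps stay connected,
    # resorbed inner years leave the curve detached from the origin)
    return [(g.year, g.cumulative_thickness) for g in series
            if g.annual_thickness is not None
            and g.cumulative_thickness is not None]
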