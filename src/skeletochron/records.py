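"""Growth-mark records for individual skeletal elements.

An :class:`ElementRecord` is one bone's ordered series of cyclical growth
marks (CGMs) with the measurements obtained from its traced cross-section:
circumference, cumulative cortical area, and cumulative cortical radial
thickness, each of which may be absent when a mark was resorbed, not
observed, or could not be fully traced.

The module also implements the skeletochronological bookkeeping around
those series: deciding whether medullary expansion may have destroyed the
innermost marks (by comparison with a hatchling baseline), locating a
"narrow zone" of unusually low annual growth usable as a landmark year,
retrocalculating how many marks are missing by aligning an incomplete
record to a complete reference record, and flagging a final zone that
represents less than a full year of growth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "STATUSES",
    "ELEMENTS",
    "GrowthMark",
    "ElementRecord",
    "HatchlingBaseline",
    "RecordError",
    "assess_cgm_loss",
    "detect_narrow_zone",
    "retrocalculate_missing",
    "flag_partial_year",
]

STATUSES = ("fully_traceable", "not_fully_traceable", "not_observed",
            "not_measured")
ELEMENTS = ("humerus", "radius", "ulna", "femur", "tibia", "fibula",
            "scapula", "coracoid")
MARK_KINDS = ("LAG", "annulus", "annulus_then_LAG")


class RecordError(ValueError):
    """Raised for inconsistent growth-record data."""


@dataclass(frozen=True)
class GrowthMark:
    """One cyclical growth mark in an element's cortex.

    ``index`` is the year ordinal counted from the innermost *observed*
    mark outward (1-based); after retrocalculation indices refer to true
    skeleton years.  Measurements are present only for fully traceable
    marks.
    """

    index: int
    status: str = "fully_traceable"
    kind: str = "annulus"
    circumference: Optional[float] = None
    cortical_area: Optional[float] = None
    cumulative_thickness: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise RecordError(f"unknown status {self.status!r}")
        if self.kind not in MARK_KINDS:
            raise RecordError(f"unknown mark kind {self.kind!r}")

    @property
    def measurable(self) -> bool:
        return self.status == "fully_traceable"


@dataclass
class ElementRecord:
    """Growth-mark series and section measurements for one bone."""

    individual_id: str
    element: str
    side: str  # "left" or "right"
    marks: List[GrowthMark] = field(default_factory=list)
    medullary_circumference: Optional[float] = None
    medullary_area: Optional[float] = None
    surface_circumference: Optional[float] = None
    surface_area: Optional[float] = None
    surface_cumulative_thickness: Optional[float] = None
    #: True/False when annotated at measurement time; None when unknown
    surface_partial_year: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise RecordError(f"unknown element {self.element!r}")
        if self.side not in ("left", "right"):
            raise RecordError(f"side must be left/right, got {self.side!r}")
        idx = [m.index for m in self.marks]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise RecordError("mark indices must be strictly increasing")
        self._check_monotone_circumference()

    def _check_monotone_circumference(self) -> None:
        # Traceable circumferences must grow from the innermost mark out to
        # the surface.  The medullary boundary is excluded: cavity drift can
        # legitimately make its perimeter exceed inner-mark perimeters.
        circ = [m.circumference for m in self.marks if m.circumference is not None]
        if self.surface_circumference is not None:
            circ.append(self.surface_circumference)
        if any(b <= a for a, b in zip(circ, circ[1:])):
            raise RecordError(
                f"{self.individual_id} {self.side} {self.element}: traceable "
                "circumferences do not increase outward")

    # -- convenience accessors -------------------------------------------
    def mark(self, index: int) -> Optional[GrowthMark]:
        for m in self.marks:
            if m.index == index:
                return m
        return None

    def measurable_marks(self) -> List[GrowthMark]:
        return [m for m in self.marks if m.cumulative_thickness is not None]

    @property
    def n_marks(self) -> int:
        return len(self.marks)


class HatchlingBaseline:
    """Year-0 (neonate) section dimensions per element, shared across
    individuals; used to decide whether medullary expansion can have
    destroyed a juvenile bone's earliest growth marks."""

    def __init__(self, values: Dict[str, Tuple[Optional[float], Optional[float],
                                               Optional[float]]]) -> None:
        for el in values:
            if el not in ELEMENTS:
                raise RecordError(f"unknown element {el!r} in baseline")
        self._values = dict(values)

    def __contains__(self, element: str) -> bool:
        return element in self._values

    def circumference(self, element: str) -> Optional[float]:
        return self._get(element)[0]

    def cortical_area(self, element: str) -> Optional[float]:
        return self._get(element)[1]

    def thickness(self, element: str) -> Optional[float]:
        return self._get(element)[2]

    def _get(self, element: str):
        if element not in self._values:
            raise RecordError(f"no hatchling baseline for element {element!r}")
        return self._values[element]

    def elements(self) -> List[str]:
        return sorted(self._values)


# ---------------------------------------------------------------------------
# operations

def assess_cgm_loss(e: ElementRecord, h: HatchlingBaseline) -> bool:
    """Whether medullary expansion may have destroyed the earliest marks.

    True iff the element's medullary-cavity circumference is strictly
    larger than the homologous hatchling bone's diaphyseal circumference:
    the cavity has then grown past the entire year-0 cortex and any mark
    deposited inside that front is gone.
    """
    base = h.circumference(e.element)
    if base is None or e.medullary_circumference is None:
        raise RecordError(
            f"loss assessment needs medullary and baseline circumferences "
            f"for {e.element}")
    return e.medullary_circumference > base


def detect_narrow_zone(e: ElementRecord, theta: float = 0.5,
                       baseline: Optional["HatchlingBaseline"] = None
                       ) -> List[Tuple[int, int]]:
    """Adjacent mark pairs bounding an unusually thin annual zone.

    A pair ``(n, n+1)`` is flagged when the thickness increment between the
    two marks is below ``theta`` times the element's median annual
    increment.  The median is taken over every measurable annual increment
    of the element: consecutive mark pairs, the first year when a hatchling
    baseline is supplied, and the final mark-to-surface zone (unless that
    zone is flagged as a partial year).  Requires at least three measurable
    marks; returns ``[]`` otherwise.
    """
    if not 0 < theta <= 1:
        raise RecordError("theta must lie in (0, 1]")
    marks = e.measurable_marks()
    if len(marks) < 3:
        return []
    increments = {}
    for a, b in zip(marks, marks[1:]):
        if b.index == a.index + 1:
            increments[(a.index, b.index)] = (
                b.cumulative_thickness - a.cumulative_thickness)
    if len(increments) < 2:
        return []
    pool = list(increments.values())
    if (baseline is not None and e.element in baseline
            and baseline.thickness(e.element) is not None
            and marks[0].index == 1):
        pool.append(marks[0].cumulative_thickness
                    - baseline.thickness(e.element))
    if (e.surface_cumulative_thickness is not None
            and not e.surface_partial_year):
        pool.append(e.surface_cumulative_thickness
                    - marks[-1].cumulative_thickness)
    median = float(np.median(pool))
    return [pair for pair, dt in increments.items() if dt < theta * median]


@dataclass(frozen=True)
class Retrocalculation:
    """Result of aligning an incomplete record to a complete reference."""

    missing_count: int
    realigned_indices: Tuple[int, ...]
    method: str  # "landmark" or "count"


def retrocalculate_missing(e: ElementRecord, ref: ElementRecord,
                           theta: float = 0.5,
                           ref_loss: bool = False,
                           baseline: Optional[HatchlingBaseline] = None
                           ) -> Retrocalculation:
    """Number of marks lost to medullary expansion in ``e``.

    ``ref`` must hold a complete growth record (no loss suspected, pass the
    outcome of :func:`assess_cgm_loss` as ``ref_loss``).  If both records
    contain exactly one detected narrow zone, those landmark years are
    aligned; otherwise the mark-count difference (floored at zero) is used.
    The returned indices shift ``e``'s marks outward by the missing count.
    """
    if ref_loss:
        raise RecordError("reference record itself flagged for CGM loss")
    zone_e = detect_narrow_zone(e, theta, baseline)
    zone_r = detect_narrow_zone(ref, theta, baseline)
    if len(zone_e) == 1 and len(zone_r) == 1:
        missing = zone_r[0][0] - zone_e[0][0]
        method = "landmark"
    else:
        if zone_e or zone_r:
            logger.warning(
                "%s %s: ambiguous narrow zones (%s vs reference %s); "
                "falling back to count alignment",
                e.individual_id, e.element, zone_e, zone_r)
        missing = max(ref.n_marks - e.n_marks, 0)
        method = "count"
    if missing < 0:
        raise RecordError(
            f"negative alignment offset ({missing}) for {e.element}: "
            "record has more marks than the complete reference")
    realigned = tuple(m.index + missing for m in e.marks)
    return Retrocalculation(missing_count=missing,
                            realigned_indices=realigned, method=method)


def flag_partial_year(e: ElementRecord, delta: float = 0.05) -> ElementRecord:
    """Fill in the partial-final-year flag where it was not annotated.

    A growth mark lying very close to the periosteal surface means the
    final zone records less than a full year of apposition.  When the
    record carries no explicit annotation (``surface_partial_year`` is
    None), the flag is set iff the relative gap between the outermost
    measurable mark and the surface is below ``delta``.  An explicit
    annotation made at tracing time is authoritative and kept unchanged.
    """
    if not 0 < delta <= 1:
        raise RecordError("delta must lie in (0, 1]")
    if e.surface_partial_year is not None:
        return e
    flag = False
    marks = e.measurable_marks()
    if marks and e.surface_cumulative_thickness is not None:
        t_last = marks[-1].cumulative_thickness
        if t_last > 0:
            flag = (e.surface_cumulative_thickness - t_last) / t_last < delta
    out = replace_record(e)
    out.surface_partial_year = flag
    return out


def replace_record(e: ElementRecord) -> ElementRecord:
    """Shallow copy of an ElementRecord (marks are immutable)."""
    return ElementRecord(
        individual_id=e.individual_id, element=e.element, side=e.side,
        marks=list(e.marks),
        medullary_circumference=e.medullary_circumference,
        medullary_area=e.medullary_area,
        surface_circumference=e.surface_circumference,
        surface_area=e.surface_area,
        surface_cumulative_thickness=e.surface_cumulative_thickness,
        surface_partial_year=e.surface_partial_year)
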