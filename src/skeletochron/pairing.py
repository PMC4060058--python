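"""Bilateral paired statistics for homologous element pairs.

Left and right bones of the same element from one individual should record
the same growth history; this module quantifies that claim.  Circumference
measurements are paired level-by-level (growth marks and periosteal
surface), compared with a paired Student's t-test per element, and pooled
across individuals and elements into an ordinary least-squares regression
of right on left whose slope/R² measure overall bilateral agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .records import ElementRecord, RecordError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedComparison",
    "RegressionResult",
    "pair_measurements",
    "paired_t",
    "left_right_regression",
    "compare_skeleton",
]

#: levels entering bilateral comparison; medullary and hatchling are not
#: growth-record measurements of the sampled bone pair
PAIRED_LEVELS = tuple(f"cgm{i}" for i in range(1, 6)) + ("surface",)


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test result for one element pair."""

    individual_id: str
    element: str
    n_pairs: int
    mean_abs_difference: float  # |mean(left − right)| in mm
    sd_differences: float       # sample SD (n−1) of the differences, mm
    p_value: float
    ci_half_width: float        # 95% CI half-width of the mean difference
    alpha: float
    reject: bool
    degenerate: bool = False    # sd == 0: test limit case, p set by convention

    def summary_row(self) -> dict:
        return {
            "individual": self.individual_id,
            "element": self.element,
            "mean_difference_mm": self.mean_abs_difference,
            "sd_mm": self.sd_differences,
            "n": self.n_pairs,
            "p_value": self.p_value,
            "ci_half_width_mm": self.ci_half_width,
            "reject": self.reject,
        }


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of right-side on left-side circumference."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def pair_measurements(left: ElementRecord, right: ElementRecord
                      ) -> List[Tuple[float, float]]:
    """Mutually fully-traceable circumference pairs for one element.

    Pairs are formed at every growth-mark level and the surface where both
    sides carry a measured circumference.  An empty list means the element
    cannot be compared (logged and skipped upstream).
    """
    if (left.individual_id != right.individual_id
            or left.element != right.element):
        raise RecordError("can only pair the same element of one individual")
    lmap = {f"cgm{m.index}": m.circumference for m in left.marks}
    rmap = {f"cgm{m.index}": m.circumference for m in right.marks}
    lmap["surface"] = left.surface_circumference
    rmap["surface"] = right.surface_circumference
    pairs = []
    for level in PAIRED_LEVELS:
        lv, rv = lmap.get(level), rmap.get(level)
        if lv is not None and rv is not None:
            pairs.append((lv, rv))
    if not pairs:
        logger.info("%s %s: no mutually traceable levels; element skipped",
                    left.individual_id, left.element)
    return pairs


def paired_t(pairs: Sequence[Tuple[float, float]], alpha: float = 0.05,
             individual_id: str = "", element: str = "") -> PairedComparison:
    """Two-tailed paired Student's t-test on left−right differences.

    Reports |mean difference|, the sample SD of the differences, the
    p-value with n−1 degrees of freedom, and the 95% confidence half-width
    t_{0.975,n−1}·sd/√n.  With zero SD the test degenerates: p is reported
    as 0 (nonzero mean) or 1 (zero mean) with the ``degenerate`` flag set.
    """
    if len(pairs) < 2:
        raise RecordError("paired t-test needs at least two pairs")
    d = np.array([l - r for l, r in pairs], dtype=float)
    n = len(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    tcrit = float(stats.t.ppf(0.975, n - 1))
    degenerate = sd == 0.0
    if degenerate:
        p = 0.0 if mean != 0.0 else 1.0
        logger.warning("%s %s: zero-variance differences, p=%g by convention",
                       individual_id, element, p)
    else:
        tstat = mean / (sd / np.sqrt(n))
        p = float(2 * stats.t.sf(abs(tstat), n - 1))
    return PairedComparison(
        individual_id=individual_id, element=element, n_pairs=n,
        mean_abs_difference=abs(mean), sd_differences=sd, p_value=p,
        ci_half_width=tcrit * sd / np.sqrt(n), alpha=alpha,
        reject=p < alpha, degenerate=degenerate)


def left_right_regression(pairs: Sequence[Tuple[float, float]]
                          ) -> RegressionResult:
    """OLS of right (y) on left (x) over pooled circumference pairs."""
    if len(pairs) < 3:
        raise RecordError("regression needs at least three points")
    x = np.array([p[0] for p in pairs], float)
    y = np.array([p[1] for p in pairs], float)
    if np.ptp(x) == 0:
        raise RecordError("degenerate regression: no variance in left values")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            n_points=len(pairs))


def compare_skeleton(records: Sequence[ElementRecord], alpha: float = 0.05,
                     baseline=None, regression_levels: str = "all",
                     ) -> Tuple[List[PairedComparison], RegressionResult]:
    """Run every available left/right comparison and the pooled regression.

    Elements with only one mutually traceable level are excluded from the
    t-tests (a single pair has no variance estimate) but their point is
    retained in the pooled regression.

    The t-tests always compare growth-mark and surface circumferences.
    With ``regression_levels="all"`` (the default) the pooled left-versus-
    right regression additionally includes the medullary-cavity boundary
    and, when a :class:`~skeletochron.records.HatchlingBaseline` is passed,
    the shared hatchling level of every compared element — i.e. every
    mutually measured circumference of the section table enters the plot.
    ``regression_levels="marks"`` restricts it to the t-test pairs.
    """
    if regression_levels not in ("all", "marks"):
        raise RecordError("regression_levels must be 'all' or 'marks'")
    by_key = {}
    for e in records:
        by_key.setdefault((e.individual_id, e.element), {})[e.side] = e
    comparisons: List[PairedComparison] = []
    pooled: List[Tuple[float, float]] = []
    for (ind, el), sides in sorted(by_key.items()):
        if "left" not in sides or "right" not in sides:
            continue
        left, right = sides["left"], sides["right"]
        pairs = pair_measurements(left, right)
        pooled.extend(pairs)
        if regression_levels == "all":
            if (left.medullary_circumference is not None
                    and right.medullary_circumference is not None):
                pooled.append((left.medullary_circumference,
                               right.medullary_circumference))
            if baseline is not None and el in baseline:
                c = baseline.circumference(el)
                if c is not None:
                    pooled.append((c, c))
        if len(pairs) >= 2:
            comparisons.append(paired_t(pairs, alpha, ind, el))
        elif pairs:
            logger.info("%s %s: only one paired level; excluded from t-tests",
                        ind, el)
    regression = left_right_regression(pooled)
    return comparisons, regression
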