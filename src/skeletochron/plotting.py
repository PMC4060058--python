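"""Growth-curve figures: annual and cumulative cortical thickness."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .growth import GrowingSeason, cumulative_curve, element_growth
from .records import ElementRecord, HatchlingBaseline

__all__ = ["plot_growth_curves"]


def _year_pos(year) -> float:
    return float(year) if year != "surface" else -1.0


def plot_growth_curves(records: Sequence[ElementRecord],
                       baseline: HatchlingBaseline,
                       path: str,
                       season: GrowingSeason = GrowingSeason(),
                       delta: float = 0.05) -> None:
    """Annual (left) and cumulative (right) thickness curves per individual.

    One panel row per individual; the x-axis is growth-mark count, not
    numerical age.  Series with inner marks lost to medullary expansion do
    not connect to the origin.
    """
    individuals = sorted({r.individual_id for r in records})
    fig, axes = plt.subplots(len(individuals), 2,
                             figsize=(9, 3 * len(individuals)),
                             squeeze=False)
    for row, ind in enumerate(individuals):
        ax_annual, ax_cum = axes[row]
        for e in records:
            if e.individual_id != ind or e.side != "left":
                continue
            try:
                series = element_growth(e, baseline, season, delta)
            except Exception:
                continue
            pts = [(g.year, g.annual_thickness) for g in series
                   if g.annual_thickness is not None and g.year != 0]
            last = max((g.year for g in series if g.year != "surface"),
                       default=0)
            xs = [last + 1 if y == "surface" else y for y, _ in pts]
            if pts:
                ax_annual.plot(xs, [v for _, v in pts], "o-", label=e.element)
            cum = cumulative_curve(series)
            xs = [last + 1 if y == "surface" else y for y, _ in cum]
            if cum:
                ax_cum.plot(xs, [v for _, v in cum], "o-", label=e.element)
        ax_annual.set_title(f"{ind}: annual thickness (mm)")
        ax_cum.set_title(f"{ind}: cumulative thickness (mm)")
        for ax in (ax_annual, ax_cum):
            ax.set_xlabel("growth mark count")
            ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
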