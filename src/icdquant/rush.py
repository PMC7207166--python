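"""RUSH (retention using selective hooks) kinetic statistics.

A streptavidin hook retains an SBP-GFP reporter in the endoplasmic
reticulum until biotin releases it for secretion; after biotin washout and
avidin scavenging, newly synthesized reporter is retained again.  Reporter
accumulation over a 24-h once-per-hour time course therefore measures new
protein synthesis, and the four conditions bracket the effect:

- biotin control: reporter keeps being secreted (flat baseline)
- avidin control: full retention, maximal accumulation (0% inhibition)
- continuous drug: accumulation under sustained synthesis inhibition
- discontinuous drug (washout): accumulation once the drug is removed,
  probing reversibility of the inhibition

Inhibition is the complementary ratio of the continuous and avidin slopes;
reversibility is the area between the discontinuous and continuous curves
normalized by the maximal effect (the area between avidin and biotin
controls).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import WellSeries

__all__ = ["RushSet", "normalize_rush", "inhibition_percent", "reversibility_percent"]


@dataclass
class RushSet:
    """The four RUSH conditions on one common, strictly increasing time grid."""

    biotin_ctrl: WellSeries
    avidin_ctrl: WellSeries
    continuous: WellSeries
    discontinuous: WellSeries
    normalized: bool = False

    def __post_init__(self) -> None:
        grid = self.biotin_ctrl.timepoints
        for name in ("avidin_ctrl", "continuous", "discontinuous"):
            other = getattr(self, name).timepoints
            if other.size != grid.size or not np.array_equal(other, grid):
                raise ValueError(f"{name} is not on the common time grid")

    @property
    def timepoints(self) -> np.ndarray:
        return self.biotin_ctrl.timepoints

    def series(self) -> dict[str, WellSeries]:
        return {
            "biotin_ctrl": self.biotin_ctrl,
            "avidin_ctrl": self.avidin_ctrl,
            "continuous": self.continuous,
            "discontinuous": self.discontinuous,
        }


def normalize_rush(raw: RushSet, ctr: WellSeries) -> RushSet:
    """Divide every series pointwise by the control at each timepoint."""
    if ctr.timepoints.size != raw.timepoints.size or not np.array_equal(
        ctr.timepoints, raw.timepoints
    ):
        raise ValueError("control series is not on the set's time grid")
    if np.any(ctr.values <= 0):
        raise ValueError("control has non-positive values; cannot normalize")
    normalized = {
        name: WellSeries(s.subject_id, s.timepoints, s.values / ctr.values, s.condition)
        for name, s in raw.series().items()
    }
    return RushSet(**normalized, normalized=True)


def _slope(series: WellSeries) -> float:
    """Ordinary least-squares slope over the full window."""
    t, v = series.timepoints, series.values
    return float(np.polyfit(t, v, 1)[0])


def inhibition_percent(rush: RushSet, slope_tol: float = 1e-12) -> float:
    """Protein-synthesis inhibition from the continuous / avidin slope ratio.

    The avidin-control slope defines 0% inhibition; inhibition is the
    complementary ratio ``100 * (1 - slope(continuous) / slope(avidin))``.
    Negative values (accumulation faster than the control) are reported
    as-is.  Fails if the avidin control did not accumulate (assay failed).
    """
    if not rush.normalized:
        raise ValueError("set must be normalized first (normalize_rush)")
    s_avidin = _slope(rush.avidin_ctrl)
    if s_avidin <= slope_tol:
        raise ValueError(
            f"avidin control slope {s_avidin:.3g} <= tolerance; assay failed"
        )
    return 100.0 * (1.0 - _slope(rush.continuous) / s_avidin)


def reversibility_percent(rush: RushSet, area_tol: float = 1e-12) -> float:
    """Reversibility from the area between the discontinuous and continuous curves.

    The maximal effect is the trapezoid area between the avidin and biotin
    control curves; reversibility is
    ``100 * area(discontinuous - continuous) / area(avidin - biotin)``.
    Fails if the maximal-effect area is not positive.
    """
    if not rush.normalized:
        raise ValueError("set must be normalized first (normalize_rush)")
    t = rush.timepoints
    max_effect = float(np.trapezoid(rush.avidin_ctrl.values - rush.biotin_ctrl.values, t))
    if max_effect <= area_tol:
        raise ValueError(
            f"area between avidin and biotin controls {max_effect:.3g} <= tolerance; "
            "assay failed"
        )
    gain = float(np.trapezoid(rush.discontinuous.values - rush.continuous.values, t))
    return 100.0 * gain / max_effect
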