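"""Healthy/pyknotic/dead classification and 4-parameter log-logistic IC60.

Cells stained with Hoechst (DNA) and propidium iodide (PI) are clustered by
simple gates: dead if PI-positive, pyknotic if the nucleus is condensed and
Hoechst-bright, healthy otherwise.  The number of healthy cells per well,
as a fraction of total, is fitted against dose with the four-parameter
log-logistic model

    y(x) = c + (d - c) / (1 + (x / e)^b)

(b: Hill-type slope; c, d: lower/upper asymptotes; e: inflection dose, uM),
and the IC60 — the concentration at which 40% of the population remains
healthy — is read from the closed-form inverse of the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["FourPL", "ClassRule", "classify_cells", "fit_4pl", "ic60"]


@dataclass(frozen=True)
class FourPL:
    """Four-parameter log-logistic model ``y(x) = c + (d-c)/(1+(x/e)^b)``."""

    b: float  # slope (dimensionless)
    c: float  # lower asymptote (healthy fraction)
    d: float  # upper asymptote
    e: float  # inflection dose (uM)

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError("inflection dose e must be > 0")
        if self.d <= self.c:
            raise ValueError("upper asymptote d must exceed lower asymptote c")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.c + (self.d - self.c) / (1.0 + (x / self.e) ** self.b)


@dataclass(frozen=True)
class ClassRule:
    """Gates for the healthy / pyknotic / dead clustering.

    Dead takes precedence: PI at or above ``pi_threshold``.  Among PI-negative
    cells, pyknotic requires a condensed nucleus (area at or below
    ``condensed_area_threshold``) *and* bright Hoechst (at or above
    ``hoechst_high_threshold``); everything else is healthy.
    """

    pi_threshold: float
    hoechst_high_threshold: float
    condensed_area_threshold: float

    def __post_init__(self) -> None:
        for name in ("pi_threshold", "hoechst_high_threshold", "condensed_area_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_controls(cls, control_cells: pd.DataFrame,
                      pi_threshold: float,
                      hoechst_col: str = "nuclear_mean_dna",
                      area_col: str = "nuclear_area_px2") -> "ClassRule":
        """Derive Hoechst/area gates from control wells.

        Hoechst-high: control median + 2 MAD; condensed: 0.6 x control median
        area.  The PI gate is instrument-dependent and must be supplied.
        """
        hoechst = control_cells[hoechst_col].to_numpy(dtype=float)
        area = control_cells[area_col].to_numpy(dtype=float)
        mad = float(np.median(np.abs(hoechst - np.median(hoechst))))
        return cls(
            pi_threshold=pi_threshold,
            hoechst_high_threshold=float(np.median(hoechst) + 2.0 * mad),
            condensed_area_threshold=0.6 * float(np.median(area)),
        )


def classify_cells(cells: pd.DataFrame, rule: ClassRule,
                   pi_col: str = "nuclear_mean_pi",
                   hoechst_col: str = "nuclear_mean_dna",
                   area_col: str = "nuclear_area_px2") -> pd.DataFrame:
    """Assign each cell exactly one of healthy / pyknotic / dead.

    Returns a copy of ``cells`` with the ``class`` column filled; the three
    labels partition the table (every cell gets exactly one).
    """
    for col in (pi_col, hoechst_col, area_col):
        if col not in cells.columns:
            raise KeyError(f"required measurement column {col!r} missing")
    out = cells.copy()
    pi = out[pi_col].to_numpy(dtype=float)
    hoechst = out[hoechst_col].to_numpy(dtype=float)
    area = out[area_col].to_numpy(dtype=float)
    dead = pi >= rule.pi_threshold
    pyknotic = (~dead) & (area <= rule.condensed_area_threshold) & (
        hoechst >= rule.hoechst_high_threshold
    )
    labels = np.where(dead, "dead", np.where(pyknotic, "pyknotic", "healthy"))
    out["class"] = labels
    return out


def _model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, c, d, log_e = params
    return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - log_e)))


def fit_4pl(doses, healthy, total=None):
    """Least-squares 4PL fit of the healthy fraction against dose.

    ``healthy`` is either a healthy-cell fraction per well (values in
    [0, 1]) or a count, in which case ``total`` gives the per-well totals.
    Doses equal to 0 (untreated wells) are offset to one tenth of the
    smallest positive dose so they participate on the log scale.

    The fit runs a multi-start over slope guesses b in {0.5, 1, 2, 4} with
    bounds c >= 0 and d <= 1.05 x the maximal observed fraction, keeping the
    lowest residual sum of squares.  Returns ``(fit, diagnostics)`` where
    ``diagnostics`` has ``rss``, ``converged`` and ``n``.  A response with
    no dose effect (near-zero variance, or a collapsed dynamic range) is
    flagged non-converged and ``fit`` is None.
    """
    doses = np.asarray(doses, dtype=float)
    healthy = np.asarray(healthy, dtype=float)
    if total is not None:
        total = np.asarray(total, dtype=float)
        if np.any(total <= 0):
            raise ValueError("totals must be > 0")
        y = healthy / total
    else:
        y = healthy
        if y.max() > 1.0 + 1e-9:
            raise ValueError("fractions above 1; pass counts with total=")
    if np.unique(doses).size < 4:
        raise ValueError("need >= 4 distinct doses")
    if np.any(healthy < 0):
        raise ValueError("counts must be >= 0")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")

    positive = doses[doses > 0]
    if positive.size == 0:
        raise ValueError("need at least one positive dose")
    x = np.where(doses > 0, doses, positive.min() / 10.0)

    diagnostics = {"rss": float("nan"), "converged": False, "n": int(y.size)}
    if float(np.var(y)) < 1e-12:
        return None, diagnostics  # flat response: no dose effect to model

    y_max = float(y.max())
    lower = np.array([0.05, 0.0, 0.0, np.log(x.min()) - 5.0])
    upper = np.array([50.0, 1.05 * y_max, 1.05 * y_max, np.log(x.max()) + 5.0])
    log_e0 = float(np.log(np.median(x)))
    best = None
    for b0 in (0.5, 1.0, 2.0, 4.0):
        p0 = np.array([b0, max(float(y.min()), 0.0), y_max, log_e0])
        p0 = np.clip(p0, lower + 1e-9, upper - 1e-9)
        try:
            sol = least_squares(
                lambda p: _model(p, x) - y, p0, bounds=(lower, upper), method="trf"
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return None, diagnostics
    b, c, d, log_e = best.x
    if d - c < 1e-6:
        return None, {**diagnostics, "rss": float(2 * best.cost)}
    fit = FourPL(b=float(b), c=float(c), d=float(d), e=float(np.exp(log_e)))
    diagnostics = {"rss": float(2 * best.cost), "converged": True, "n": int(y.size)}
    return fit, diagnostics


def ic60(fit: FourPL) -> float:
    """Dose at which 40% of the population remains healthy.

    Closed-form inverse of the 4PL: ``x = e * ((d-c)/(0.4-c) - 1)^(1/b)``.
    Defined only when 0.4 lies strictly between the asymptotes.
    """
    if not (fit.c < 0.4 < fit.d):
        raise ValueError(
            f"IC60 undefined: 0.4 outside the fitted asymptotes "
            f"(c={fit.c:.4g}, d={fit.d:.4g})"
        )
    arg = (fit.d - fit.c) / (0.4 - fit.c) - 1.0
    return float(fit.e * arg ** (1.0 / fit.b))
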