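"""Per-assay hallmark statistics of immunogenic cell death.

Each function here computes one of the screen's scalar readouts from
per-cell measurements, images, or time series:

- :func:`anchored_inhibition` — intensity ranged between an untreated
  control (0% inhibition) and a blank/no-label control (100% inhibition);
  used for transcription (EU) and translation (AHA) incorporation assays.
- :func:`calr_dot_area` — area of bright calreticulin-GFP puncta after a
  white top-hat filter, normalized to the control at each timepoint, with
  an area-under-the-curve summary.
- :func:`hmgb1_release` — average speed of nuclear HMGB1-GFP loss from
  single-cell tracks normalized to their first timepoint.
- :func:`positive_fraction` — share of cells beyond a threshold placed
  between a negative and positive control distribution (MX1 reporter
  activation; quinacrine-negative calling with ``direction="below"``).
- :func:`soc` / :func:`soc_rank` — surface overlap coefficient of two
  thresholded channels (fibrillarin vs nucleolin nucleolar integrity) and
  its ranking into a percentage inhibition across wells.
- :func:`cv_translocation` — mean cytoplasmic coefficient of variation,
  reporting calreticulin redistribution in tissue sections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.morphology import disk, white_tophat

from .containers import AssayResult, WellSeries

__all__ = [
    "anchored_inhibition",
    "calr_dot_area",
    "hmgb1_release",
    "positive_fraction",
    "soc",
    "soc_rank",
    "cv_translocation",
]


class DegenerateAnchorsError(ValueError):
    """Control and blank anchors coincide; the anchored percentage is undefined."""


def anchored_inhibition(
    values,
    ctr_values,
    blank_values,
    clip: bool = False,
    anchor_tol: float = 1e-9,
) -> float:
    """Percentage inhibition anchored between untreated and blank controls.

    The readout intensity is ranged linearly between its mean in untreated
    cells (0% inhibition) and its mean in cells never exposed to the label
    (100% inhibition)::

        inhibition % = 100 * (mean(ctr) - mean(values)) / (mean(ctr) - mean(blank))

    Values outside [0, 100] are reported as-is unless ``clip`` is set.
    """
    values = np.asarray(values, dtype=float)
    ctr = float(np.mean(np.asarray(ctr_values, dtype=float)))
    blank = float(np.mean(np.asarray(blank_values, dtype=float)))
    span = ctr - blank
    if abs(span) <= anchor_tol:
        raise DegenerateAnchorsError(
            f"anchors coincide (ctr mean {ctr}, blank mean {blank}); "
            "cannot range the signal"
        )
    pct = 100.0 * (ctr - float(values.mean())) / span
    if clip:
        pct = float(np.clip(pct, 0.0, 100.0))
    return pct


def _dot_area_one(image: np.ndarray, cyto_mask: np.ndarray,
                  selem: np.ndarray, threshold: float) -> int:
    tophat = white_tophat(np.asarray(image, dtype=float), footprint=selem)
    return int(np.count_nonzero((tophat > threshold) & (cyto_mask > 0)))


def calr_dot_area(
    treated: list[tuple[np.ndarray, np.ndarray]],
    control: list[tuple[np.ndarray, np.ndarray]],
    timepoints,
    tophat_radius: int = 4,
    high_threshold: float | None = None,
):
    """Area of bright puncta over time, normalized to the control per timepoint.

    ``treated`` and ``control`` are sequences of ``(image, cytoplasm_mask)``
    pairs aligned with ``timepoints`` (hours).  At each timepoint a white
    top-hat with a disk structuring element of ``tophat_radius`` isolates
    puncta; pixels above ``high_threshold`` (default: mean + 3 sd of the
    control top-hat inside its cytoplasmic mask, pooled over timepoints)
    inside the cytoplasmic mask are counted, and the treated area is divided
    by the control area at the same timepoint.  The summary statistic is the
    trapezoid area under the normalized series.

    Timepoints where the control area is zero are flagged and excluded from
    the AUC.  Returns ``(normalized_series, auc_result, flagged_timepoints)``.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if len(treated) != len(control) or len(treated) != timepoints.size:
        raise ValueError("treated and control must share the acquisition timepoints")
    selem = disk(int(tophat_radius))

    if high_threshold is None:
        pooled = []
        for img, mask in control:
            tophat = white_tophat(np.asarray(img, dtype=float), footprint=selem)
            pooled.append(tophat[np.asarray(mask) > 0])
        pooled = np.concatenate([p for p in pooled if p.size]) if pooled else np.array([])
        if pooled.size == 0:
            raise ValueError("control cytoplasmic masks are empty; cannot set threshold")
        high_threshold = float(pooled.mean() + 3.0 * pooled.std())

    treated_area = np.array(
        [_dot_area_one(img, mask, selem, high_threshold) for img, mask in treated],
        dtype=float,
    )
    control_area = np.array(
        [_dot_area_one(img, mask, selem, high_threshold) for img, mask in control],
        dtype=float,
    )
    flagged = np.flatnonzero(control_area == 0)
    keep = control_area > 0
    if not keep.any():
        raise ValueError("control dot area is zero at every timepoint")
    normalized = WellSeries(
        subject_id="treated/control",
        timepoints=timepoints[keep],
        values=treated_area[keep] / control_area[keep],
        condition="normalized_dot_area",
    )
    auc = float(np.trapezoid(normalized.values, normalized.timepoints))
    result = AssayResult(
        assay="calr_dot_area_auc",
        value=auc,
        units="normalized area * h",
        anchors={"threshold": high_threshold},
        n=int(keep.sum()),
    )
    return normalized, result, flagged.tolist()


def hmgb1_release(tracks: list[WellSeries]):
    """Average speed of nuclear HMGB1 loss from single-cell tracks.

    Each track is normalized to its first timepoint; the release speed per
    interval is the consecutive difference of the normalized intensity, the
    per-cell speed is the mean of those differences, and the assay statistic
    is the mean over cells.  Release shows up as a negative speed (intensity
    loss).  Tracks whose first value is not positive are dropped and counted.

    Returns ``(result, normalized_tracks, n_dropped)``.
    """
    normalized: list[WellSeries] = []
    speeds: list[float] = []
    n_dropped = 0
    for track in tracks:
        if len(track) < 2:
            raise ValueError(f"track {track.subject_id!r} has fewer than 2 timepoints")
        first = track.values[0]
        if first <= 0:
            n_dropped += 1
            continue
        norm = track.values / first
        normalized.append(
            WellSeries(track.subject_id, track.timepoints, norm, track.condition)
        )
        speeds.append(float(np.diff(norm).mean()))
    if not speeds:
        raise ValueError("no usable tracks (all first values <= 0)")
    result = AssayResult(
        assay="hmgb1_release_speed",
        value=float(np.mean(speeds)),
        units="normalized intensity / interval",
        n=len(speeds),
    )
    return result, normalized, n_dropped


def positive_fraction(
    values,
    neg_ctrl_values,
    pos_ctrl_values,
    direction: str = "above",
):
    """Fraction of cells beyond a threshold set between two control distributions.

    The threshold is the intensity minimizing the total misclassification of
    the two control samples, found by exhaustive search over midpoints of
    the sorted pooled control values; ties resolve to the midpoint of the
    two control medians.  ``direction="above"`` counts test cells above the
    threshold as positive (reporter activation); ``direction="below"``
    counts cells below it (e.g. quinacrine-negative calling).

    Returns ``(fraction, threshold)``.  Raises if no threshold separates the
    controls better than chance (identical overlapping controls).
    """
    values = np.asarray(values, dtype=float)
    neg = np.sort(np.asarray(neg_ctrl_values, dtype=float))
    pos = np.sort(np.asarray(pos_ctrl_values, dtype=float))
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both control distributions must be non-empty")
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    lo, hi = (neg, pos) if direction == "above" else (pos, neg)
    # candidate cuts: midpoints between consecutive distinct pooled values
    pooled = np.unique(np.concatenate([lo, hi]))
    candidates = (pooled[:-1] + pooled[1:]) / 2.0
    if candidates.size == 0:
        raise ValueError("controls are a single point; no threshold exists")
    # misclassification: lo-sample values above the cut + hi-sample values <= cut
    err = np.array(
        [np.count_nonzero(lo > c) + np.count_nonzero(hi <= c) for c in candidates]
    )
    chance = min(lo.size, hi.size)  # error of the best trivial (one-sided) rule
    best = err.min()
    if best >= chance:
        raise ValueError(
            "control distributions are not separable better than chance; "
            "assay controls failed"
        )
    ties = candidates[err == best]
    if ties.size == 1:
        threshold = float(ties[0])
    else:
        threshold = float((np.median(lo) + np.median(hi)) / 2.0)
        if threshold < ties.min() or threshold > ties.max():
            threshold = float(ties[ties.size // 2])
    if direction == "above":
        fraction = float(np.mean(values > threshold))
    else:
        fraction = float(np.mean(values < threshold))
    return fraction, threshold


def soc(
    a: np.ndarray,
    b: np.ndarray,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
) -> float:
    """Surface overlap coefficient of two channels, in [0, 1].

    Boolean inputs are taken as masks directly; intensity images are
    binarized at the given thresholds (Otsu per channel by default).  The
    coefficient is the Jaccard-style overlap ``|A & B| / |A | B|``; the
    alternative normalization ``|A & B| / min(|A|, |B|)`` is isolated here
    should a different convention be needed.

    Raises if both masks are empty (the coefficient is undefined).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("channels must share dimensions")

    def to_mask(img, threshold):
        if img.dtype == bool:
            return img
        img = img.astype(float)
        if threshold is None:
            if img.max() - img.min() < 1e-12:
                return np.zeros(img.shape, dtype=bool)
            threshold = threshold_otsu(img)
        return img > threshold

    mask_a = to_mask(a, threshold_a)
    mask_b = to_mask(b, threshold_b)
    union = np.count_nonzero(mask_a | mask_b)
    if union == 0:
        raise ValueError("both masks are empty; SOC undefined")
    inter = np.count_nonzero(mask_a & mask_b)
    return inter / union


def soc_rank(soc_by_well: dict[str, float], ctr_well: str) -> dict[str, float]:
    """Range SOC values between the control (0% inhibition) and the dataset minimum (100%).

    ``inhibition(w) = 100 * (SOC(ctr) - SOC(w)) / (SOC(ctr) - min SOC)``.
    """
    if ctr_well not in soc_by_well:
        raise KeyError(f"control well {ctr_well!r} not in dataset")
    if len(set(soc_by_well.values())) < 2:
        raise ValueError("need >= 2 distinct SOC values to range")
    ctr = soc_by_well[ctr_well]
    low = min(soc_by_well.values())
    span = ctr - low
    if span <= 0:
        raise ValueError(
            "control SOC equals the dataset minimum; ranging is degenerate"
        )
    return {w: 100.0 * (ctr - s) / span for w, s in soc_by_well.items()}


def cv_translocation(cell_records: pd.DataFrame, channel: str = "signal") -> AssayResult:
    """Mean cytoplasmic coefficient of variation across cells.

    The CV (population sd / mean of the cytoplasmic intensity) rises when a
    homogeneous reticular signal redistributes into patches or a peripheral
    rim, reporting calreticulin translocation in tissue.
    """
    col = f"cyto_cv_{channel}"
    if col not in cell_records.columns:
        raise KeyError(f"column {col!r} missing from cell records")
    cv = cell_records[col].dropna()
    if cv.empty:
        raise ValueError("no cells with cytoplasmic measurements")
    return AssayResult(
        assay="cv_translocation",
        value=float(cv.mean()),
        units="dimensionless",
        n=int(cv.size),
    )
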