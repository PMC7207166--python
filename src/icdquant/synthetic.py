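"""Synthetic microscopy fields, time courses and compound tables with planted truth.

Every generator here emulates one input of the screening pipeline and returns
machine-readable ground truth alongside, so each downstream stage can be
tested as a recovery problem: plant an inhibition fraction, a decay rate, a
dose-response curve or a class shift, run the pipeline, and compare against
the planted value.

Images are 16-bit unsigned, single-plane, row-major, with 0-based pixel
coordinates and intensities in arbitrary units, matching sCMOS acquisition.
Nuclei are filled ellipses with a Gaussian edge blur (sd 1 px); noise is
Gaussian read noise only (shot-noise realism is a non-goal).  Time grids are
uniform in hours, emulating once-per-hour live-cell acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .containers import CHANNEL_ROLES, FieldImage, WellSeries

__all__ = [
    "ChannelSpec",
    "SyntheticFieldSpec",
    "SyntheticCurveSpec",
    "RushTruth",
    "OvercrowdedFieldError",
    "make_field",
    "make_hmgb1_tracks",
    "make_rush_curves",
    "make_dose_response",
    "make_compound_table",
]

MAX_INTENSITY = 65535  # 16-bit camera full well


class OvercrowdedFieldError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap after bounded retries."""


@dataclass(frozen=True)
class ChannelSpec:
    """One fluorescence channel of a synthetic field.

    role
        ``"dna"`` (nuclear stain), ``"signal"`` (per-cell intensity readout,
        subject to the planted inhibition), ``"dots"`` (punctate channel) or
        ``"pi"`` (viability stain).
    background
        Constant background level, a.u.
    per_cell_level
        Structure intensity painted for each cell, a.u.
    noise_sd
        Gaussian read-noise standard deviation, a.u.
    """

    role: str
    background: float = 100.0
    per_cell_level: float = 1000.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.background < 0 or self.per_cell_level < 0:
            raise ValueError("intensity levels must be >= 0")


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Recipe for one synthetic multi-channel field with planted ground truth."""

    width: int = 512
    height: int = 512
    n_cells: int = 50
    nucleus_radius_px: tuple[float, float] = (12.0, 1.5)  # mean, sd
    channels: tuple[ChannelSpec, ...] = (
        ChannelSpec("dna"),
        ChannelSpec("signal"),
    )
    planted_inhibition: float = 0.0
    planted_dots: tuple[int, float, float] | None = None  # (count/cell, radius px, amplitude a.u.)
    cyto_ring_px: int = 8
    n_touching_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        mean_r, sd_r = self.nucleus_radius_px
        if mean_r <= 0 or sd_r < 0:
            raise ValueError("nucleus radii must be > 0 (sd >= 0)")
        if not 0.0 <= self.planted_inhibition <= 1.0:
            raise ValueError("planted_inhibition must be in [0, 1]")
        if self.planted_dots is not None:
            count, radius, amp = self.planted_dots
            if count < 0 or radius <= 0 or amp < 0:
                raise ValueError("planted_dots must be (count>=0, radius>0, amplitude>=0)")
        if self.n_touching_pairs * 2 > self.n_cells:
            raise ValueError("n_touching_pairs exceeds available cells")
        if not self.channels:
            raise ValueError("at least one channel required")


def _place_nuclei(spec: SyntheticFieldSpec, rng: np.random.Generator):
    """Place nucleus centers by rejection sampling.

    Non-touching nuclei are separated by at least the sum of their radii plus
    a guard gap; touching pairs are planted at 90% of the radius sum so their
    binary footprints merge into one blob (overlapping ~20% at the waist)
    and must be split by watershed downstream.
    """
    mean_r, sd_r = spec.nucleus_radius_px
    gap = 4.0
    max_tries = 500
    centers: list[tuple[float, float]] = []
    radii: list[float] = []

    def fits(cy, cx, r, touching_partner=None):
        margin = r + 2.0
        if not (margin <= cy <= spec.height - margin and margin <= cx <= spec.width - margin):
            return False
        for j, (ocy, ocx) in enumerate(centers):
            if touching_partner is not None and j == touching_partner:
                continue
            d = math.hypot(cy - ocy, cx - ocx)
            if d < r + radii[j] + gap:
                return False
        return True

    n_single = spec.n_cells - 2 * spec.n_touching_pairs
    for _ in range(n_single):
        r = max(3.0, rng.normal(mean_r, sd_r))
        for _try in range(max_tries):
            cy = rng.uniform(0, spec.height)
            cx = rng.uniform(0, spec.width)
            if fits(cy, cx, r):
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise OvercrowdedFieldError(
                f"could not place nucleus {len(centers) + 1}/{spec.n_cells} "
                f"after {max_tries} tries; reduce n_cells or enlarge the field"
            )
    for _ in range(spec.n_touching_pairs):
        r1 = max(3.0, rng.normal(mean_r, sd_r))
        r2 = max(3.0, rng.normal(mean_r, sd_r))
        for _try in range(max_tries):
            cy = rng.uniform(0, spec.height)
            cx = rng.uniform(0, spec.width)
            theta = rng.uniform(0, 2 * math.pi)
            d = 0.9 * (r1 + r2)
            cy2 = cy + d * math.sin(theta)
            cx2 = cx + d * math.cos(theta)
            if fits(cy, cx, r1):
                centers.append((cy, cx))
                radii.append(r1)
                if fits(cy2, cx2, r2, touching_partner=len(centers) - 1):
                    centers.append((cy2, cx2))
                    radii.append(r2)
                    break
                centers.pop()
                radii.pop()
        else:
            raise OvercrowdedFieldError(
                f"could not place touching pair after {max_tries} tries"
            )
    return centers, radii


def make_field(spec: SyntheticFieldSpec):
    """Render one synthetic field.

    Returns
    -------
    field : FieldImage
        One uint16 image per channel role.
    labels : ndarray of int32
        Ground-truth nucleus label mask (0 = background).
    truth : pandas.DataFrame
        One row per cell: center, radius, nuclear area, and for every channel
        the expected measured nuclear mean (``<role>_mean_true``, averaged
        over the truth mask on the noiseless rendered image) plus the planted
        structure level (``<role>_planted_level``).

    Raises
    ------
    OvercrowdedFieldError
        If nuclei cannot be placed without overlap after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    centers, radii = _place_nuclei(spec, rng)

    labels = np.zeros((H, W), dtype=np.int32)
    orientations = rng.uniform(0, math.pi, size=len(centers))
    for k, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        rr, cc = draw_ellipse(cy, cx, r, 0.85 * r, shape=(H, W), rotation=orientations[k - 1])
        labels[rr, cc] = k

    # cell footprint: nucleus plus cytoplasmic ring (signal painted over both)
    if len(centers):
        dist_out = ndimage.distance_transform_edt(labels == 0)
        footprint = (labels > 0) | (dist_out <= spec.cyto_ring_px)
    else:
        footprint = np.zeros((H, W), dtype=bool)

    noiseless: dict[str, np.ndarray] = {}
    for ch in spec.channels:
        img = np.full((H, W), float(ch.background))
        if ch.role == "dna":
            img[labels > 0] += ch.per_cell_level
        elif ch.role == "signal":
            img[footprint] += ch.per_cell_level * (1.0 - spec.planted_inhibition)
        elif ch.role == "pi":
            img[labels > 0] += ch.per_cell_level
        elif ch.role == "dots":
            if spec.planted_dots is not None:
                count, dot_r, amp = spec.planted_dots
                for (cy, cx), r in zip(centers, radii):
                    for _ in range(count):
                        # uniform angle, radial position inside the annulus
                        theta = rng.uniform(0, 2 * math.pi)
                        rad = rng.uniform(r + dot_r + 1, r + spec.cyto_ring_px - dot_r)
                        dy = cy + rad * math.sin(theta)
                        dx = cx + rad * math.cos(theta)
                        rr, cc = draw_disk((dy, dx), dot_r, shape=(H, W))
                        img[rr, cc] += amp
        img = ndimage.gaussian_filter(img, sigma=1.0)  # edge blur, sd 1 px
        noiseless[ch.role] = img

    truth_rows = []
    for k, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        mask = labels == k
        row = {
            "cell_id": k,
            "center_y": cy,
            "center_x": cx,
            "radius_px": r,
            "nuclear_area_px2": int(mask.sum()),
        }
        for ch in spec.channels:
            row[f"{ch.role}_mean_true"] = float(noiseless[ch.role][mask].mean())
            level = ch.per_cell_level
            if ch.role == "signal":
                level *= 1.0 - spec.planted_inhibition
            row[f"{ch.role}_planted_level"] = level
        truth_rows.append(row)
    truth = pd.DataFrame(
        truth_rows,
        columns=(
            ["cell_id", "center_y", "center_x", "radius_px", "nuclear_area_px2"]
            + [f"{ch.role}_mean_true" for ch in spec.channels]
            + [f"{ch.role}_planted_level" for ch in spec.channels]
        ),
    )

    channels: dict[str, np.ndarray] = {}
    for ch in spec.channels:
        img = noiseless[ch.role]
        if ch.noise_sd > 0:
            img = img + rng.normal(0.0, ch.noise_sd, size=img.shape)
        channels[ch.role] = np.clip(np.round(img), 0, MAX_INTENSITY).astype(np.uint16)

    field = FieldImage(channels=channels)
    return field, labels, truth


def make_hmgb1_tracks(
    n_cells: int,
    n_timepoints: int,
    decay_per_interval: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    initial_intensity: tuple[float, float] = (1000.0, 100.0),
):
    """Per-cell nuclear-intensity tracks with multiplicative decay.

    Emulates live-cell tracking of nuclear HMGB1-GFP over a once-per-hour
    grid: cell i starts at I0_i and loses a fixed fraction of its intensity
    per interval, I_t = I0 * (1 - decay)^t, plus Gaussian noise.

    Returns ``(tracks, truth)`` where ``tracks`` is a list of
    :class:`WellSeries` and ``truth`` a DataFrame with the initial intensity
    and the planted decay.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if not 0.0 <= decay_per_interval <= 1.0:
        raise ValueError("decay_per_interval must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints, dtype=float)  # hours
    mu0, sd0 = initial_intensity
    tracks: list[WellSeries] = []
    rows = []
    for i in range(n_cells):
        i0 = max(1.0, rng.normal(mu0, sd0))
        values = i0 * (1.0 - decay_per_interval) ** t
        if noise_sd > 0:
            values = np.maximum(values + rng.normal(0.0, noise_sd, size=t.size), 0.0)
        tracks.append(WellSeries(subject_id=f"cell_{i:04d}", timepoints=t, values=values))
        rows.append({"subject_id": f"cell_{i:04d}", "initial_intensity": i0,
                     "decay_per_interval": decay_per_interval})
    truth = pd.DataFrame(rows, columns=["subject_id", "initial_intensity", "decay_per_interval"])
    return tracks, truth


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for one RUSH retention experiment (all four conditions).

    The reporter accumulates linearly in the avidin control at ``rate``
    a.u./h; a planted inhibition fraction scales the accumulation rate under
    continuous drug exposure, and a planted reversibility fraction restores
    part of it after drug washout (discontinuous exposure).
    """

    timepoints: tuple[float, ...] = tuple(float(t) for t in range(25))  # 0..24 h
    planted_inhibition: float = 1.0
    planted_reversibility: float = 0.5
    noise_sd: float = 0.0
    baseline: float = 100.0
    rate: float = 20.0  # a.u. per hour in the avidin control
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 3:
            raise ValueError("need >= 3 timepoints")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not np.allclose(dt, dt[0]):
            raise ValueError("time grid must be uniform (once-per-hour acquisition)")
        for name in ("planted_inhibition", "planted_reversibility"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class RushTruth:
    planted_inhibition: float
    planted_reversibility: float
    rate: float
    baseline: float


def make_rush_curves(spec: SyntheticCurveSpec):
    """Generate the four RUSH conditions on a common time grid.

    Before per-timepoint normalization the planted construction is linear:

    - biotin control: flat at ``baseline`` (reporter secreted, no retention)
    - avidin control: ``baseline + rate * t`` (full retention of new protein)
    - continuous drug: slope ``rate * (1 - inhibition)``
    - discontinuous drug (washout): slope
      ``rate * (1 - inhibition * (1 - reversibility))``

    Returns ``(rush_set, truth)`` where ``rush_set`` is an *unnormalized*
    :class:`icdquant.rush.RushSet`.
    """
    from .rush import RushSet  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    f, r = spec.planted_inhibition, spec.planted_reversibility
    slopes = {
        "biotin_ctrl": 0.0,
        "avidin_ctrl": spec.rate,
        "continuous": spec.rate * (1.0 - f),
        "discontinuous": spec.rate * (1.0 - f * (1.0 - r)),
    }
    series = {}
    for condition, slope in slopes.items():
        values = spec.baseline + slope * t
        if spec.noise_sd > 0:
            values = np.maximum(values + rng.normal(0.0, spec.noise_sd, size=t.size), 1e-6)
        series[condition] = WellSeries(
            subject_id=condition, timepoints=t, values=values, condition=condition
        )
    rush_set = RushSet(
        biotin_ctrl=series["biotin_ctrl"],
        avidin_ctrl=series["avidin_ctrl"],
        continuous=series["continuous"],
        discontinuous=series["discontinuous"],
        normalized=False,
    )
    truth = RushTruth(
        planted_inhibition=f,
        planted_reversibility=r,
        rate=spec.rate,
        baseline=spec.baseline,
    )
    return rush_set, truth


def make_dose_response(
    params: tuple[float, float, float, float],
    doses: Sequence[float],
    n_cells_per_well: int = 500,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
):
    """Healthy-cell counts drawn around a 4-parameter log-logistic curve.

    ``params = (b, c, d, e)`` with response ``y(x) = c + (d-c)/(1+(x/e)^b)``
    giving the healthy fraction at dose ``x``.  Noise is multiplicative
    Gaussian on the fraction (``noise_sd`` is a fraction of the true value).

    Returns ``(plate, true_ic60)``; the plate table has one row per
    (dose, replicate) with ``healthy`` counts and ``total`` cells.  The true
    IC60 (dose at which the healthy fraction is 0.4) is computed in closed
    form and returned for recovery tests; ``None`` if 0.4 is outside (c, d).
    """
    b, c, d, e = params
    if e <= 0:
        raise ValueError("inflection dose e must be > 0")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and strictly increasing")
    rng = np.random.default_rng(seed)

    def y(x):
        return c + (d - c) / (1.0 + (x / e) ** b)

    if min(c, d) < 0.4 < max(c, d):
        true_ic60 = e * ((d - c) / (0.4 - c) - 1.0) ** (1.0 / b)
    else:
        true_ic60 = None

    rows = []
    for rep in range(n_replicates):
        for j, x in enumerate(doses):
            frac = y(x)
            if noise_sd > 0:
                frac = frac * (1.0 + rng.normal(0.0, noise_sd))
            frac = float(np.clip(frac, 0.0, 1.0))
            rows.append(
                {
                    "well": f"D{j:02d}R{rep}",
                    "dose_uM": float(x),
                    "replicate": rep,
                    "healthy": frac * n_cells_per_well,
                    "total": n_cells_per_well,
                }
            )
    plate = pd.DataFrame(rows, columns=["well", "dose_uM", "replicate", "healthy", "total"])
    return plate, true_ic60


def make_compound_table(
    n_compounds: int,
    n_annotated: int,
    planted_shift: float = 0.0,
    seed: int = 0,
    annotation_label: str = "transcription inhibitor",
):
    """Compound screening table with a planted class shift.

    ICD prediction scores are standard normal for the background population;
    the first ``n_annotated`` compounds carry ``annotation_label`` and their
    scores are shifted by ``planted_shift`` standard deviations.  IC50s are
    log-uniform between 0.01 and 100 uM; a random half of compounds carry the
    clinical flag.
    """
    if not 0 <= n_annotated <= n_compounds:
        raise ValueError("need 0 <= n_annotated <= n_compounds")
    rng = np.random.default_rng(seed)
    scores = rng.standard_normal(n_compounds)
    scores[:n_annotated] += planted_shift
    ic50 = 10.0 ** rng.uniform(-2, 2, size=n_compounds)  # uM
    clinical = rng.random(n_compounds) < 0.5
    table = pd.DataFrame(
        {
            "compound_id": [f"CPD{i:05d}" for i in range(n_compounds)],
            "icd_score": scores,
            "ic50_uM": ic50,
            "clinical_flag": clinical,
            "annotations": [
                annotation_label if i < n_annotated else "" for i in range(n_compounds)
            ],
        }
    )
    return table
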