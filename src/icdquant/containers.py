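"""Core in-memory containers shared across the pipeline.

A high-content screen produces three kinds of objects that every stage
consumes or emits: multi-channel fields of view (:class:`FieldImage`),
per-subject time series (:class:`WellSeries`) and named scalar statistics
with their provenance (:class:`AssayResult`).  Label masks are plain
``numpy`` integer arrays (0 = background, k >= 1 = object k) validated by
:func:`validate_label_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "FieldImage",
    "WellSeries",
    "AssayResult",
    "validate_label_mask",
]

#: channel roles understood by the pipeline
CHANNEL_ROLES = ("dna", "signal", "dots", "pi")


@dataclass
class FieldImage:
    """One multi-channel 2-D microscopy field.

    Parameters
    ----------
    channels
        Mapping from channel role (e.g. ``"dna"``, ``"signal"``) to a 2-D
        intensity array in arbitrary units.  All channels must share
        dimensions and be non-negative.
    pixel_size_um
        Physical pixel size in micrometres per pixel, if known.
    well, site, timepoint
        Acquisition identifiers (well name, field-of-view index, hours).
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float | None = None
    well: str = ""
    site: int = 0
    timepoint: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {np.asarray(img).shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on dimensions: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2-D, got shape {shape}")
        for role, img in self.channels.items():
            arr = np.asarray(img)
            if np.issubdtype(arr.dtype, np.floating) and np.any(arr < 0):
                raise ValueError(f"channel {role!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        """Return a channel as float64, raising a clear error if absent."""
        if role not in self.channels:
            raise KeyError(
                f"channel role {role!r} missing; have {sorted(self.channels)}"
            )
        return np.asarray(self.channels[role], dtype=float)


@dataclass
class WellSeries:
    """A per-well or per-cell-track intensity time series.

    ``timepoints`` are hours on a strictly increasing grid; ``values`` are
    intensities (a.u.) or normalized ratios, all finite.
    """

    subject_id: str
    timepoints: np.ndarray
    values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.ndim != 1 or self.values.ndim != 1:
            raise ValueError("timepoints and values must be 1-D")
        if self.timepoints.size != self.values.size:
            raise ValueError("timepoints and values differ in length")
        if self.timepoints.size and np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.timepoints.size


@dataclass
class AssayResult:
    """A named scalar statistic with its provenance.

    ``anchors`` records the control identifiers used whenever the statistic
    is an anchored percentage (untreated control = 0%, blank = 100%).
    """

    assay: str
    value: float
    units: str = ""
    anchors: dict = field(default_factory=dict)
    n: int = 0

    def as_row(self) -> dict:
        return {
            "assay": self.assay,
            "value": self.value,
            "units": self.units,
            "anchors": ";".join(f"{k}={v}" for k, v in sorted(self.anchors.items())),
            "n": self.n,
        }


def validate_label_mask(mask: np.ndarray) -> np.ndarray:
    """Validate and return a label mask (2-D, integer, non-negative)."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("label mask must have an integer dtype")
    if arr.size and arr.min() < 0:
        raise ValueError("label mask has negative labels")
    return arr
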