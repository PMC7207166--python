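"""Disk formats: per-channel TIFFs, label-mask TIFFs, CSV tables, YAML configs.

Filenames follow the plate convention ``{plate}_{well}_{site}_{t}_{channel}.tif``
with one single-plane 16-bit TIFF per channel per site per timepoint.
Tables are plain CSV: cell records, long-format tracks
(``subject_id,t_hours,value``) and assay results.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import FieldImage, WellSeries

__all__ = [
    "write_field_tiffs",
    "read_field_tiffs",
    "write_label_mask",
    "read_label_mask",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_yaml",
    "read_yaml",
]

_TIFF_PATTERN = re.compile(
    r"(?P<plate>[^_]+)_(?P<well>[^_]+)_(?P<site>\d+)_(?P<t>[^_]+)_(?P<channel>[^_.]+)\.tif$"
)


def write_field_tiffs(field: FieldImage, outdir: str | Path, plate: str = "P1") -> list[Path]:
    """Write one 16-bit TIFF per channel; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for role in sorted(field.channels):
        img = np.asarray(field.channels[role])
        if img.dtype != np.uint16:
            img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        path = outdir / f"{plate}_{field.well}_{field.site}_{field.timepoint:g}_{role}.tif"
        tifffile.imwrite(path, img)
        paths.append(path)
    return paths


def read_field_tiffs(directory: str | Path, well: str, site: int = 0,
                     timepoint: float = 0.0, plate: str = "P1") -> FieldImage:
    """Assemble a FieldImage from the per-channel TIFFs of one site."""
    directory = Path(directory)
    channels: dict[str, np.ndarray] = {}
    for path in sorted(directory.glob(f"{plate}_{well}_{site}_{timepoint:g}_*.tif")):
        m = _TIFF_PATTERN.match(path.name)
        if m:
            channels[m.group("channel")] = tifffile.imread(path)
    if not channels:
        raise FileNotFoundError(
            f"no TIFFs for plate={plate} well={well} site={site} t={timepoint} in {directory}"
        )
    return FieldImage(channels=channels, well=well, site=site, timepoint=timepoint)


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    if mask.max() > 65535:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_tracks_csv(tracks: list[WellSeries], path: str | Path) -> None:
    rows = [
        {"subject_id": s.subject_id, "t_hours": t, "value": v, "condition": s.condition}
        for s in tracks
        for t, v in zip(s.timepoints, s.values)
    ]
    pd.DataFrame(rows, columns=["subject_id", "t_hours", "value", "condition"]).to_csv(
        path, index=False
    )


def read_tracks_csv(path: str | Path) -> list[WellSeries]:
    df = pd.read_csv(path)
    tracks = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("t_hours")
        condition = str(grp["condition"].iloc[0]) if "condition" in grp else ""
        if condition == "nan":
            condition = ""
        tracks.append(
            WellSeries(
                subject_id=str(subject_id),
                timepoints=grp["t_hours"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
                condition=condition,
            )
        )
    return tracks


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
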