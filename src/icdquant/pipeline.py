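"""Reproducible runs: plate layouts, run configuration, per-assay dispatch, aggregation.

A :class:`PlateLayout` maps wells to compounds, doses and control roles; a
:class:`RunConfig` carries every tunable parameter plus the master seed and
is serialized (and hashed) into every output for provenance.  Exclusions of
cells, tracks or fields are always logged with a reason — never silent.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import FieldImage
from .hallmarks import anchored_inhibition
from .integration import zscore
from .segmentation import measure_cells, segment_cytoplasm, segment_nuclei

__all__ = ["PlateLayout", "RunConfig", "MissingControlError", "run_assay", "aggregate"]

ROLES = ("treated", "untreated_ctrl", "blank_ctrl", "pos_ctrl", "neg_ctrl")


class MissingControlError(ValueError):
    """A required control role is absent from the plate layout."""


@dataclass
class PlateLayout:
    """Well -> (compound, dose, role) map for one assay plate."""

    wells: pd.DataFrame  # columns: well, compound_id, dose_uM, role
    assay: str = ""

    def __post_init__(self) -> None:
        required = {"well", "compound_id", "dose_uM", "role"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"layout missing columns: {sorted(missing)}")
        bad = set(self.wells["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    def wells_with_role(self, role: str) -> list[str]:
        return self.wells.loc[self.wells["role"] == role, "well"].tolist()

    def require_roles(self, roles: tuple[str, ...]) -> None:
        for role in roles:
            if not self.wells_with_role(role):
                raise MissingControlError(
                    f"assay {self.assay or '?'} requires a {role!r} well; none in layout"
                )

    @classmethod
    def from_csv(cls, path, assay: str = "") -> "PlateLayout":
        return cls(wells=pd.read_csv(path), assay=assay)


@dataclass(frozen=True)
class RunConfig:
    """All tunables of one pipeline run; hashed into every output."""

    seed: int = 0
    min_area_px2: float = 50.0
    max_area_px2: float = 5000.0
    smooth_sigma: float = 2.0
    ring_width_px: int = 8
    tophat_radius_px: int = 4
    reference_compound: str = "mitoxantrone"
    exclusions: tuple[str, ...] = ()
    skip_fields: tuple[str, ...] = ()  # explicit out-of-focus skip-list
    output_dir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclusions"] = list(self.exclusions)
        d["skip_fields"] = list(self.skip_fields)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @property
    def config_hash(self) -> str:
        # the output location carries no scientific provenance
        d = self.to_dict()
        d.pop("output_dir", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        for key in ("exclusions", "skip_fields"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _well_signal_means(
    fields: list[FieldImage], config: RunConfig, log: list[dict], well: str
) -> np.ndarray:
    """Per-cell nuclear signal means pooled over a well's fields."""
    means = []
    for f in fields:
        field_id = f"{well}/site{f.site}"
        if field_id in config.skip_fields:
            log.append({"well": well, "what": field_id, "reason": "skip_list", "n": 1})
            continue
        nuclei = segment_nuclei(
            f,
            min_area=config.min_area_px2,
            max_area=config.max_area_px2,
            smooth_sigma=config.smooth_sigma,
        )
        cyto = segment_cytoplasm(nuclei, ring_width=config.ring_width_px)
        cells = measure_cells(f, nuclei, cyto)
        n_missing = int(cells["cyto_missing"].sum()) if len(cells) else 0
        if n_missing:
            log.append(
                {"well": well, "what": "cells", "reason": "zero_area_cytoplasm", "n": n_missing}
            )
        if len(cells):
            means.append(cells["nuclear_mean_signal"].to_numpy(dtype=float))
    return np.concatenate(means) if means else np.array([])


def run_assay(
    layout: PlateLayout,
    fields_by_well: dict[str, list[FieldImage]],
    config: RunConfig,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run an anchored-intensity assay (EU/AHA style) over a plate.

    Controls are validated before any computation: the assay needs at least
    one ``untreated_ctrl`` (0% inhibition anchor) and one ``blank_ctrl``
    (100% anchor, cells never exposed to the label).  Each well's fields are
    segmented, per-cell nuclear signal means are pooled, and treated wells
    are ranged between the anchors.

    Returns ``(results, exclusion_log)``; results carry anchors, cell counts
    and the config hash.
    """
    layout.require_roles(("untreated_ctrl", "blank_ctrl"))
    log: list[dict] = []

    ctr_wells = layout.wells_with_role("untreated_ctrl")
    blank_wells = layout.wells_with_role("blank_ctrl")
    ctr_vals = np.concatenate(
        [_well_signal_means(fields_by_well[w], config, log, w) for w in ctr_wells]
    )
    blank_vals = np.concatenate(
        [_well_signal_means(fields_by_well[w], config, log, w) for w in blank_wells]
    )

    rows = []
    anchors = {"untreated_ctrl": ",".join(ctr_wells), "blank_ctrl": ",".join(blank_wells)}
    for _, entry in layout.wells.sort_values("well").iterrows():
        well = entry["well"]
        if well not in fields_by_well:
            log.append({"well": well, "what": "well", "reason": "no_images", "n": 1})
            continue
        values = _well_signal_means(fields_by_well[well], config, log, well)
        if values.size == 0:
            log.append({"well": well, "what": "well", "reason": "no_cells", "n": 1})
            continue
        pct = anchored_inhibition(values, ctr_vals, blank_vals)
        rows.append(
            {
                "well": well,
                "compound_id": entry["compound_id"],
                "dose_uM": entry["dose_uM"],
                "role": entry["role"],
                "assay": layout.assay,
                "inhibition_pct": pct,
                "n_cells": int(values.size),
                "anchors": f"ctr={anchors['untreated_ctrl']};blank={anchors['blank_ctrl']}",
                "config_hash": config.config_hash,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "well", "compound_id", "dose_uM", "role", "assay",
            "inhibition_pct", "n_cells", "anchors", "config_hash",
        ],
    )
    return results, log


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Fold per-assay results into one z-scored row per compound.

    ``results`` needs columns ``compound_id``, ``assay``, ``value`` and
    optionally a boolean ``is_replicate``.  Replicate-flagged duplicates are
    averaged before standardization; unflagged duplicates are an error.
    Assays a compound was never run in yield NaN.  Columns with too few
    values to standardize (fewer than two, or zero spread) pass through
    unscaled.
    """
    required = {"compound_id", "assay", "value"}
    if missing := required - set(results.columns):
        raise ValueError(f"results missing columns: {sorted(missing)}")
    df = results.copy()
    if "is_replicate" not in df.columns:
        df["is_replicate"] = False
    dup = df.duplicated(subset=["compound_id", "assay"], keep=False) & ~df["is_replicate"]
    if dup.any():
        pairs = df.loc[dup, ["compound_id", "assay"]].drop_duplicates().values.tolist()
        raise ValueError(f"duplicate (compound, assay) without replicate flag: {pairs}")
    collapsed = df.groupby(["compound_id", "assay"], sort=True)["value"].mean().reset_index()
    wide = collapsed.pivot(index="compound_id", columns="assay", values="value")
    for col in wide.columns:
        try:
            wide[col] = zscore(wide[col].to_numpy())
        except ValueError:
            pass  # single value or zero spread: pass through unscaled
    wide.columns = [f"z_{c}" for c in wide.columns]
    return wide.reset_index()
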