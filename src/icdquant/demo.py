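"""End-to-end demonstration run on synthetic data with planted ground truth.

One call exercises every stage: an anchored transcription-inhibition plate
(image synthesis, segmentation, per-cell measurement, anchored percentages),
a dose-response plate with IC60, a RUSH time course, HMGB1 release tracks
and a compound table with hit gating and KS class enrichment.  All outputs
are CSV files in ``config.output_dir``; identical config and seed produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FieldImage
from .dose_response import fit_4pl, ic60
from .hallmarks import hmgb1_release
from .integration import ks_enrichment, select_hits
from .pipeline import PlateLayout, RunConfig, aggregate, run_assay
from .rush import inhibition_percent, normalize_rush, reversibility_percent
from .synthetic import (
    ChannelSpec,
    SyntheticCurveSpec,
    SyntheticFieldSpec,
    make_compound_table,
    make_dose_response,
    make_field,
    make_hmgb1_tracks,
    make_rush_curves,
)

__all__ = ["run_demo", "make_eu_plate"]

#: planted transcription-inhibition fractions of the demo EU plate
DEMO_INHIBITIONS = {"CPD_A": 0.3, "CPD_B": 0.7}


def make_eu_plate(
    seed: int,
    inhibitions: dict[str, float] | None = None,
    n_cells: int = 70,
    n_sites: int = 1,
    field_size: int = 512,
    noise_sd: float = 25.0,
) -> tuple[PlateLayout, dict[str, list[FieldImage]], dict[str, pd.DataFrame]]:
    """Synthesize an anchored EU-incorporation plate.

    One untreated control well (0% inhibition anchor), one blank well (cells
    never exposed to the label, 100% anchor) and one treated well per entry
    of ``inhibitions``.  Returns the layout, the per-well fields and the
    per-well truth tables.
    """
    inhibitions = DEMO_INHIBITIONS if inhibitions is None else inhibitions
    plan = [("W01", "control", "untreated_ctrl", 0.0), ("W02", "blank", "blank_ctrl", 1.0)]
    for i, (compound, f) in enumerate(sorted(inhibitions.items())):
        plan.append((f"W{i + 3:02d}", compound, "treated", f))
    layout = PlateLayout(
        wells=pd.DataFrame(
            [
                {"well": w, "compound_id": c, "dose_uM": 3.0 if role == "treated" else 0.0,
                 "role": role}
                for w, c, role, _ in plan
            ]
        ),
        assay="eu_transcription",
    )
    fields: dict[str, list[FieldImage]] = {}
    truths: dict[str, pd.DataFrame] = {}
    for j, (well, _compound, _role, f) in enumerate(plan):
        fields[well] = []
        per_well_truth = []
        for site in range(n_sites):
            spec = SyntheticFieldSpec(
                width=field_size,
                height=field_size,
                n_cells=n_cells,
                channels=(
                    ChannelSpec("dna", background=100, per_cell_level=2000, noise_sd=noise_sd),
                    ChannelSpec("signal", background=100, per_cell_level=1500, noise_sd=noise_sd),
                ),
                planted_inhibition=f,
                seed=(seed * 10007 + j * 101 + site) % (2**31 - 1),
            )
            field, _labels, truth = make_field(spec)
            field.well = well
            field.site = site
            fields[well].append(field)
            per_well_truth.append(truth.assign(site=site))
        truths[well] = pd.concat(per_well_truth, ignore_index=True)
    return layout, fields, truths


def run_demo(config: RunConfig) -> dict:
    """Run every stage on generated data; returns a summary of key numbers."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())
    seed = config.seed
    summary: dict[str, object] = {"config_hash": config.config_hash}

    # --- anchored transcription-inhibition plate -------------------------
    layout, fields, _truths = make_eu_plate(seed)
    results, log = run_assay(layout, fields, config)
    results.to_csv(outdir / "assay_results.csv", index=False)
    pd.DataFrame(log, columns=["well", "what", "reason", "n"]).to_csv(
        outdir / "exclusions.csv", index=False
    )
    treated = results[results["role"] == "treated"].set_index("compound_id")
    for compound, planted in DEMO_INHIBITIONS.items():
        summary[f"inhibition_pct[{compound}] (planted {100 * planted:g}%)"] = round(
            float(treated.loc[compound, "inhibition_pct"]), 2
        )

    # --- dose-response / IC60 -------------------------------------------
    true_params = (1.2, 0.05, 0.95, 2.0)
    doses = np.geomspace(0.1, 30.0, 8)
    plate, true_ic60 = make_dose_response(
        true_params, doses, n_cells_per_well=500, noise_sd=0.02,
        n_replicates=3, seed=seed + 1,
    )
    fit, diag = fit_4pl(plate["dose_uM"], plate["healthy"], plate["total"])
    est_ic60 = ic60(fit)
    pd.DataFrame(
        [{
            "compound": "demo_drug", "b": fit.b, "c": fit.c, "d": fit.d, "e": fit.e,
            "ic60_uM": est_ic60, "true_ic60_uM": true_ic60,
            "rss": diag["rss"], "converged": diag["converged"],
            "config_hash": config.config_hash,
        }]
    ).to_csv(outdir / "dose_response.csv", index=False)
    summary["ic60_uM (true {:.3f})".format(true_ic60)] = round(est_ic60, 3)

    # --- RUSH kinetics ---------------------------------------------------
    curve_spec = SyntheticCurveSpec(
        planted_inhibition=0.8, planted_reversibility=0.6, noise_sd=1.0, seed=seed + 2
    )
    raw, truth = make_rush_curves(curve_spec)
    rush = normalize_rush(raw, raw.biotin_ctrl)
    inh = inhibition_percent(rush)
    rev = reversibility_percent(rush)
    pd.DataFrame(
        [{
            "compound": "demo_drug", "inhibition_pct": inh, "reversibility_pct": rev,
            "planted_inhibition_pct": 100 * truth.planted_inhibition,
            "planted_reversibility_pct": 100 * truth.planted_reversibility,
            "n_timepoints": len(rush.timepoints), "config_hash": config.config_hash,
        }]
    ).to_csv(outdir / "rush.csv", index=False)
    summary["rush_inhibition_pct (planted 80%)"] = round(inh, 2)
    summary["rush_reversibility_pct"] = round(rev, 2)

    # --- HMGB1 release ---------------------------------------------------
    tracks, _truth = make_hmgb1_tracks(
        n_cells=50, n_timepoints=24, decay_per_interval=0.08,
        noise_sd=5.0, seed=seed + 3,
    )
    speed, _normalized, n_dropped = hmgb1_release(tracks)
    pd.DataFrame(
        [{
            "assay": speed.assay, "mean_release_speed": speed.value,
            "n_tracks": speed.n, "n_dropped": n_dropped,
            "config_hash": config.config_hash,
        }]
    ).to_csv(outdir / "hmgb1.csv", index=False)
    summary["hmgb1_mean_speed"] = round(speed.value, 4)

    # --- compound table: hits + enrichment -------------------------------
    table = make_compound_table(2000, 30, planted_shift=3.0, seed=seed + 4)
    reference = pd.DataFrame(
        [{
            "compound_id": config.reference_compound, "icd_score": 1.5,
            "ic50_uM": 0.5, "clinical_flag": True, "annotations": "",
        }]
    )
    table = pd.concat([table, reference], ignore_index=True)
    hits = select_hits(table, config.reference_compound)
    hits.to_csv(outdir / "hits.csv", index=False)
    enr, _ecdfs = ks_enrichment(table, "transcription inhibitor")
    pd.DataFrame(
        [{
            "class": enr.class_label, "n_class": enr.n_class,
            "n_population": enr.n_population, "ks_D": enr.statistic,
            "p_value": enr.pvalue, "direction": enr.direction,
            "config_hash": config.config_hash,
        }]
    ).to_csv(outdir / "enrichment.csv", index=False)
    summary["n_positive_hits"] = int((hits["hit_class"] == "positive").sum())
    summary["ks_p (planted shift 3 sd)"] = float(enr.pvalue)

    # --- compound-level aggregation --------------------------------------
    long = results[results["role"] == "treated"][["compound_id", "assay", "inhibition_pct"]]
    long = long.rename(columns={"inhibition_pct": "value"})
    aggregate(long).to_csv(outdir / "aggregated.csv", index=False)
    return summary
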