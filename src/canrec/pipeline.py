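"""End-to-end pipeline: simulate (optional) -> filter -> build maps ->
landscape statistics -> interference fits, with a JSON run manifest."""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .filters import FilterConfig, apply_all_filters
from .gmap import build_map, effective_meioses, sex_average
from .interference import fit, to_genetic_scale
from .landscape import concentration_curve, telomere_proportion
from .simulate import SimConfig, marker_grid, simulate_dataset

__version__ = "0.1.0"


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the pipeline described by a config mapping.

    Recognised keys: ``simulate`` (SimConfig fields; when present the
    inputs are generated), ``calls``/``spans`` (paths, used otherwise),
    ``filters`` (FilterConfig fields), ``interference``
    (model/bootstrap_n/seed), ``landscape`` (bootstrap_n/gap_bp).
    Writes every stage's outputs plus manifest.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "started": time.time()}
    stage = "setup"
    try:
        if "simulate" in config:
            stage = "simulate"
            sim_kwargs = dict(config["simulate"] or {})
            from .simulate import ArtifactRates
            if "artifact_rates" in sim_kwargs:
                sim_kwargs["artifact_rates"] = ArtifactRates(**sim_kwargs["artifact_rates"])
            sim_cfg = SimConfig(**sim_kwargs)
            data = simulate_dataset(sim_cfg)
            calls, spans = data["calls"], data["spans"]
            chrom_lengths = sim_cfg.chrom_lengths
            io.write_crossover_calls(calls.drop(columns=["artifact"]), outdir / "calls.tsv")
            io.write_spans(spans, outdir / "spans.tsv")
            data["truth"].to_csv(outdir / "truth.tsv", sep="\t", index=False)
            manifest["stages"]["simulate"] = {
                "n_true_events": int(len(data["truth"])),
                "n_observed_calls": int(len(calls)),
                "seed": sim_cfg.seed,
            }
            calls = calls.drop(columns=["artifact"])
            marker_edges = {c: marker_grid(sim_cfg, c) for c in chrom_lengths}
        else:
            stage = "load"
            calls = io.read_crossover_calls(config["calls"])
            spans = io.read_spans(config["spans"])
            chrom_lengths = {
                c: int(e) for c, e in
                pd.concat([spans.groupby("chrom")["last_het_bp"].max(),
                           calls.groupby("chrom")["right_bp"].max()], axis=1)
                .max(axis=1).items()
            }
            spacing = float(config.get("marker_spacing_bp", 100_000))
            marker_edges = {c: np.arange(0.0, L + spacing, spacing)
                            for c, L in chrom_lengths.items()}
            manifest["stages"]["load"] = {"n_calls": int(len(calls))}

        stage = "filter"
        fcfg = FilterConfig(**(config.get("filters") or {}))
        filtered, reports = apply_all_filters(calls, fcfg)
        manifest["stages"]["filter"] = {
            r.rule: {"input": r.n_input, "removed": r.n_removed, "surviving": r.n_surviving}
            for r in reports
        }
        io.write_crossover_calls(filtered, outdir / "calls.filtered.tsv")

        stage = "build_map"
        maps = {}
        for sex in ("female", "male"):
            sub = filtered[filtered["parent_sex"] == sex]
            sub_spans = spans[spans["duo_id"].isin(
                calls.loc[calls["parent_sex"] == sex, "meiosis_id"].unique()
            )] if "duo_id" in spans.columns else spans
            prof = effective_meioses(sub_spans, marker_edges)
            maps[sex] = build_map(sub, prof, marker_edges, sex)
            io.write_genetic_map(maps[sex], outdir / f"map.{sex}.tsv")
        maps["sex-averaged"] = sex_average(maps["female"], maps["male"])
        io.write_genetic_map(maps["sex-averaged"], outdir / "map.sex-averaged.tsv")
        manifest["stages"]["build_map"] = {
            s: {"total_cM": round(m.total_cm(), 3)} for s, m in maps.items()
        }

        stage = "landscape"
        land_cfg = config.get("landscape") or {}
        land = {}
        for sex, m in maps.items():
            if m.total_cm() <= 0:
                land[sex] = {"note": "empty map; landscape skipped"}
                continue
            curve = concentration_curve(
                m, gap_bp=float(land_cfg.get("gap_bp", 1e9)),
                bootstrap_n=int(land_cfg.get("bootstrap_n", 100)),
                seed=int(land_cfg.get("seed", 0)),
            )
            land[sex] = {
                "telomere_proportion_5Mb": round(telomere_proportion(m), 4),
                "seq_fraction_80pct": round(curve.sequence_fraction_at(0.8), 4),
            }
        manifest["stages"]["landscape"] = land

        stage = "interference"
        icfg = config.get("interference") or {}
        fits = {}
        for sex in ("female", "male"):
            sub = filtered[filtered["parent_sex"] == sex]
            if len(sub) == 0 or maps[sex].total_cm() <= 0:
                fits[sex] = {"note": "no calls; fit skipped"}
                continue
            seqs = to_genetic_scale(sub, maps[sex])
            f = fit(seqs, model=icfg.get("model", "gamma"),
                    bootstrap_n=int(icfg.get("bootstrap_n", 0)),
                    seed=int(icfg.get("seed", 0)))
            fits[sex] = f.to_dict()
        manifest["stages"]["interference"] = fits
        (outdir / "interference.json").write_text(json.dumps(fits, indent=2))

        manifest["completed"] = True
    except Exception as exc:
        manifest["completed"] = False
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
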