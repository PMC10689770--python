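"""End-to-end orchestration: simulate -> harmonize -> classify -> establish
-> infer -> flows, with a run manifest and table validation.

Every artifact is UTF-8 CSV (RFC 4180, header row) or JSON; the manifest
records the config hash, seed, per-stage row counts and timestamps so a run
is auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (CLASSES, classify_records, country_richness,
                       species_alien_status, share_metrics, venn_counts)
from .config import SimConfig
from .establishment import breadth_summary, match_established, trade_breadth
from .flows import export_chord, flow_matrix, region_totals
from .harmonize import NameKey, build_key_index, clean_trade_records, \
    exclude_isis_threatened
from .inference import (PREDICTORS, conditional_average, enumerate_and_fit,
                        top_models, transform_predictors)
from .synthetic import generate_all, generate_establishment

log = logging.getLogger("colpress")

__all__ = ["run_all", "validate_tables"]


def _config_hash(config: SimConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False)
    return len(df)


def run_all(config: SimConfig, outdir) -> dict:
    """Run the full pipeline on a synthetic world; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "colpress", "version": __version__,
                      "seed": config.seed, "config_hash": _config_hash(config),
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "stages": []}

    def stage(name, rows_in, rows_out, **extra):
        log.info("stage %s: %d -> %d rows", name, rows_in, rows_out)
        manifest["stages"].append({"stage": name, "rows_in": int(rows_in),
                                   "rows_out": int(rows_out), **extra})

    # --- simulate ----------------------------------------------------------
    world, species, keys, raw, ledger = generate_all(config)
    _write(world, outdir / "world.csv")
    _write(species, outdir / "species.csv")
    _write(keys, outdir / "keys.csv")
    raw_all = pd.concat(raw.values(), ignore_index=True)
    _write(raw_all, outdir / "raw_trade.csv")
    ledger["plan"].to_csv(outdir / "truth_trade_plan.csv", index=False)
    stage("simulate", 0, len(raw_all),
          n_countries=len(world), n_species=len(species))

    # --- harmonize ---------------------------------------------------------
    index = build_key_index(
        NameKey(key_string=k, accepted_name=a, key_type=t)
        for k, t, a in zip(keys["key_string"], keys["key_type"],
                           keys["accepted_name"]))
    clean, report = clean_trade_records(raw_all, index,
                                        countries=set(world["country"]))
    n_before_isis = len(clean)
    clean = exclude_isis_threatened(clean, species)
    report["isis_threatened"] = n_before_isis - len(clean)
    _write(clean, outdir / "clean.csv")
    (outdir / "harmonize_report.json").write_text(json.dumps(report, indent=2))
    stage("harmonize", len(raw_all), len(clean))

    # --- classify ----------------------------------------------------------
    classified = classify_records(clean, species)
    _write(classified, outdir / "classified.csv")
    status = species_alien_status(classified)
    _write(status, outdir / "species_status.csv")
    per_source = {s: set(clean.loc[clean["source"] == s, "accepted_name"])
                  for s in config.source_marginals}
    venn = venn_counts(per_source)
    stage("classify", len(clean), len(classified))

    # --- establishment (synthetic truth) ------------------------------------
    est_records, truth = generate_establishment(config, world, species,
                                                classified)
    _write(est_records, outdir / "establishment.csv")
    (outdir / "truth_establishment.json").write_text(
        json.dumps(truth, indent=2))
    stage("establish", len(classified), len(est_records))

    summary = country_richness(classified, est_records).merge(
        world, on="country")
    _write(summary, outdir / "country_summary.csv")

    alien_traded = set(classified.loc[classified["label"] == "alien",
                                      "accepted_name"])
    established_all = set(est_records["accepted_name"])
    match = match_established(established_all, alien_traded)
    breadth = trade_breadth(classified, world,
                            set(truth["flagged_traded"]))
    _write(breadth, outdir / "breadth.csv")
    bsum = breadth_summary(breadth)
    _write(bsum, outdir / "breadth_summary.csv")

    n_traded = int(status["accepted_name"].nunique())
    n_alien = int(status["alien_anywhere"].sum())
    totals = {
        "extant": int(len(species)),
        "traded": n_traded,
        "alien_traded": n_alien,
        "native_only": int(status["native_only"].sum()),
        "both_alien_and_native": int(status["both_alien_and_native"].sum()),
        "established_traded_alien": len(established_all & alien_traded),
        "established_all": len(established_all),
    }
    shares = share_metrics(totals)
    (outdir / "shares.json").write_text(json.dumps(
        {"totals": totals, "shares": shares, "venn": venn,
         "match_established": {k: v for k, v in match.items()
                               if k != "established_by_trade"}},
        indent=2))

    # --- inference ---------------------------------------------------------
    coef_rows, top_rows = [], []
    for cls in CLASSES:
        if f"established_{cls}" not in summary.columns:
            continue
        try:
            design = transform_predictors(summary, cls)
            ms = enumerate_and_fit(design)
        except ValueError as exc:
            log.warning("inference skipped for %s: %s", cls, exc)
            continue
        for c in conditional_average(ms):
            coef_rows.append({"class": cls, "predictor": c.predictor,
                              "estimate": c.estimate, "se": c.se,
                              "z": c.z, "p": c.pvalue,
                              "significant": c.significant})
        for m in top_models(ms):
            top_rows.append({"class": cls,
                             "predictors": "+".join(m.subset) or "(intercept)",
                             "aicc": m.aicc, "delta_aicc": m.delta,
                             "weight": m.weight,
                             "r2m": m.fit.marginal_r2()})
    _write(pd.DataFrame(coef_rows), outdir / "averaged_coefficients.csv")
    _write(pd.DataFrame(top_rows), outdir / "top_models.csv")
    stage("infer", len(summary), len(coef_rows))

    # --- flows --------------------------------------------------------------
    region_map = world[["country", "region"]]
    mat_all = flow_matrix(classified, species, region_map, which="all")
    established_by_trade = established_all & alien_traded
    mat_est = flow_matrix(classified, species, region_map,
                          which="established",
                          established=established_by_trade)
    mat_all.to_csv(outdir / "flows_all.csv")
    mat_est.to_csv(outdir / "flows_established.csv")
    _write(export_chord(mat_all), outdir / "flows_all_edges.csv")
    _write(export_chord(mat_est), outdir / "flows_established_edges.csv")
    stage("flows", len(classified), int(mat_all.to_numpy().sum()),
          grand_total_established=region_totals(mat_est)["grand_total"])

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_tables(directory) -> dict:
    """Schema / referential-integrity report over a run's artifact directory."""
    directory = Path(directory)
    violations: list[str] = []

    def load(name):
        p = directory / name
        return pd.read_csv(p) if p.exists() else None

    world = load("world.csv")
    species = load("species.csv")
    clean = load("clean.csv")
    classified = load("classified.csv")
    summary = load("country_summary.csv")
    est = load("establishment.csv")

    if world is not None:
        if world["country"].duplicated().any():
            violations.append("world: duplicate country ids")
        if not world["insularity"].isin([0, 1]).all():
            violations.append("world: insularity outside {0,1}")
    if species is not None and species["accepted_name"].duplicated().any():
        violations.append("species: duplicate accepted names")
    for name, df in (("clean", clean), ("classified", classified),
                     ("establishment", est)):
        if df is None or world is None or species is None:
            continue
        if not df["country"].isin(set(world["country"])).all():
            violations.append(f"{name}: country not in world table")
        if not df["accepted_name"].isin(set(species["accepted_name"])).all():
            violations.append(f"{name}: species not in master")
    if summary is not None:
        counts = summary[[c for c in summary.columns
                          if c.startswith(("alien_", "native_", "established_"))]]
        if (counts.to_numpy() < 0).any():
            violations.append("country_summary: negative richness")
        if classified is not None:
            cp = (classified[classified["label"] == "alien"]
                  .drop_duplicates(["accepted_name", "country"])
                  .groupby("country").size())
            merged = summary.set_index("country")["alien_total"]
            if not np.array_equal(cp.reindex(merged.index).fillna(0).astype(int),
                                  merged.astype(int)):
                violations.append(
                    "country_summary: colonization pressure mismatch")
    return {"violations": violations, "ok": not violations}
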