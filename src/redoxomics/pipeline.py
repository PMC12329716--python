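"""End-to-end orchestration of the analysis stages.

`run_pipeline` executes simulate (optional) -> clean -> transform ->
stats -> gas totals -> pathway expression -> MAG curation -> methane
modules, writing every intermediate artifact under the run directory
plus a JSON manifest recording parameters, input checksums and stage row
counts.  Identical configuration and seed yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .cleaning import CleaningParams, clean
from .gas import HenryConstants, total_gas
from .mags import CurationParams, build_profiles, encoding_proportion
from .netmodules import NetworkParams, correlate_modules_with_gas, detect_modules, \
    signed_adjacency, topological_overlap
from .pathways import getmm_normalize, ko_expression, score_pathways_matrix
from .stats import GlogParams, fit_feature_models, glog_transform, pareto_scale, \
    spearman_gas_correlation
from .synth import SynthConfig, default_pathway_definitions, generate_feature_table, \
    generate_gas_series, generate_methane_module_data, generate_transcript_counts

STAGES = ["simulate", "clean", "transform", "stats", "gas_totals",
          "pathway_expression", "mag_curation", "methane_modules"]


@dataclass
class AnalysisConfig:
    """Everything one run needs: input paths (or a synthetic seed),
    per-stage parameters, and the output directory."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    features_path: str | None = None
    counts_path: str | None = None
    catalog_path: str | None = None
    pathway_defs_path: str | None = None
    gas_path: str | None = None
    design_path: str | None = None
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    glog: GlogParams = field(default_factory=GlogParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    curation: CurationParams = field(default_factory=CurationParams)
    henry: HenryConstants = field(default_factory=HenryConstants)
    synth: SynthConfig | None = None


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def validate_inputs(config: AnalysisConfig) -> list[dict]:
    """Schema checks on every configured input; fatal findings block a run."""
    findings: list[dict] = []

    def fatal(msg):
        findings.append({"severity": "fatal", "message": msg})

    def warning(msg):
        findings.append({"severity": "warning", "message": msg})

    if not config.simulate:
        for name in ("features_path", "counts_path", "catalog_path", "gas_path"):
            p = getattr(config, name)
            if p is None:
                fatal(f"{name} is required when simulate is off")
            elif not Path(p).exists():
                fatal(f"{name}: file not found: {p}")
    if config.counts_path and config.catalog_path and \
            Path(config.counts_path).exists() and Path(config.catalog_path).exists():
        counts = rio.read_counts(config.counts_path)
        catalog = rio.read_catalog(config.catalog_path)
        orphans = set(counts.index) - set(catalog.frame["gene_id"])
        if orphans:
            fatal(f"{len(orphans)} genes in counts absent from catalog")
    if config.features_path and Path(config.features_path).exists():
        _, meta = rio.read_feature_table(config.features_path)
        n_empty = sum(1 for m in meta if not m.ms2_fragments)
        if n_empty:
            warning(f"{n_empty} features have empty MS2 lists")
    return findings


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run all stages; returns the manifest (also written as JSON)."""
    findings = validate_inputs(config)
    if any(f["severity"] == "fatal" for f in findings):
        raise PipelineError("validate", "; ".join(
            f["message"] for f in findings if f["severity"] == "fatal"))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "stages": [],
        "parameters": {
            "seed": config.seed,
            "rt_tolerance": config.cleaning.rt_tolerance,
            "correlation_threshold": config.cleaning.correlation_threshold,
            "ppm_tolerance": config.cleaning.ppm_tolerance,
            "soft_power": config.network.beta,
            "top_n": config.network.top_n,
            "activity_threshold": config.curation.activity_threshold,
            "encoding_fraction": config.curation.encoding_fraction,
        },
        "findings": findings,
        "checksums": {},
    }

    def record(stage: str, rows: int, *paths: Path):
        manifest["stages"].append({"stage": stage, "rows": rows})
        for p in paths:
            manifest["checksums"][p.name] = _sha256(p)

    defs = (rio.read_pathway_definitions(config.pathway_defs_path)
            if config.pathway_defs_path else default_pathway_definitions())

    # --- simulate -----------------------------------------------------------
    try:
        if config.simulate:
            synth = config.synth or SynthConfig(seed=config.seed)
            table, meta, feat_truth = generate_feature_table(synth)
            counts, catalog, mag_truth = generate_transcript_counts(synth, defs)
            gas_series, gas_truth = generate_gas_series(synth, config.henry)
            f_feat = out / "features_raw.tsv"
            rio.write_feature_table(f_feat, table, meta)
            f_counts, f_cat = out / "counts.tsv", out / "gene_catalog.tsv"
            rio.write_counts(f_counts, counts)
            rio.write_catalog(f_cat, catalog)
            f_gas = out / "gas_series.csv"
            rio.write_gas_series(f_gas, gas_series)
            truth_path = out / "truth_labels.json"
            truth_path.write_text(feat_truth.to_json())
            record("simulate", len(table.features) + len(counts),
                   f_feat, f_counts, f_cat, f_gas, truth_path)
        else:
            table, meta = rio.read_feature_table(config.features_path)
            counts = rio.read_counts(config.counts_path)
            catalog = rio.read_catalog(config.catalog_path)
            gas_series = rio.read_gas_series(config.gas_path)
            record("simulate", 0)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("simulate", str(exc)) from exc

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(name, str(exc)) from exc

    # --- clean --------------------------------------------------------------
    def _clean():
        cleaned, report = clean(table, meta, config.cleaning)
        p = out / "features_cleaned.tsv"
        rio.write_feature_table(p, cleaned, meta)
        rp = out / "cleaning_report.json"
        rio.write_json(rp, report.to_dict())
        record("clean", len(cleaned.features), p, rp)
        return cleaned

    cleaned = stage("clean", _clean)

    # --- transform ----------------------------------------------------------
    def _transform():
        transformed = pareto_scale(glog_transform(cleaned, config.glog))
        p = out / "features_transformed.tsv"
        rio.write_feature_table(p, transformed, meta)
        record("transform", len(transformed.features), p)
        return transformed

    transformed = stage("transform", _transform)

    # --- per-feature stats --------------------------------------------------
    design = pd.DataFrame({
        "sample_id": cleaned.samples,
        "habitat": [s.split("_")[0] for s in cleaned.samples],
        "day": [int(s.split("_d")[1][:2]) for s in cleaned.samples],
    })

    def _stats():
        results = fit_feature_models(transformed, design)
        df = pd.DataFrame([r.__dict__ for r in results])
        p = out / "habitat_contrasts.tsv"
        df.to_csv(p, sep="\t", index=False)
        record("stats", len(df), p)
        return df

    stage("stats", _stats)

    # --- gas totals ---------------------------------------------------------
    def _gas():
        rows = [{
            "sample_id": s.sample_id, "day": s.day, "gas": s.gas,
            "total_mol": total_gas(s, config.henry),
        } for s in gas_series]
        df = pd.DataFrame(rows)
        p = out / "gas_totals.csv"
        df.to_csv(p, index=False)
        record("gas_totals", len(df), p)
        return df

    gas_totals_df = stage("gas_totals", _gas)

    # --- pathway expression -------------------------------------------------
    def _pathways():
        normalized = getmm_normalize(counts, catalog)
        ko_mat = ko_expression(normalized, catalog)
        scores = score_pathways_matrix(defs, ko_mat)
        p = out / "pathway_scores.tsv"
        scores.to_csv(p, sep="\t", index_label="pathway_id")
        record("pathway_expression", len(scores), p)
        return normalized, scores

    normalized, pathway_scores = stage("pathway_expression", _pathways)

    # --- MAG curation -------------------------------------------------------
    def _curation():
        profiles = build_profiles(counts, catalog, defs, normalized,
                                  config.curation)
        rows = []
        for prof in profiles:
            for pid, flag in prof.encoded.items():
                rows.append({"mag_id": prof.mag_id, "pathway_id": pid,
                             "encoded": flag,
                             "n_active_samples": len(prof.active_in)})
        df = pd.DataFrame(rows)
        p = out / "mag_profiles.tsv"
        df.to_csv(p, sep="\t", index=False)
        props = pd.DataFrame([
            {"pathway_id": d.pathway_id,
             "encoding_proportion": encoding_proportion(profiles, d.pathway_id)}
            for d in defs
        ])
        pp = out / "encoding_proportions.tsv"
        props.to_csv(pp, sep="\t", index=False)
        record("mag_curation", len(df), p, pp)
        return profiles

    stage("mag_curation", _curation)

    # --- methane modules ----------------------------------------------------
    def _modules():
        ch4 = gas_totals_df[gas_totals_df["gas"] == "CH4"]
        # align a per-sample methane covariate to metabolite samples by day
        by_day = ch4.groupby("day")["total_mol"].mean()
        days = [int(s.split("_d")[1][:2]) for s in transformed.samples]
        nearest = [min(by_day.index, key=lambda d, t=t: abs(d - t)) for t in days]
        gas_vec = np.array([by_day.loc[d] for d in nearest])
        corr = np.corrcoef(transformed.values)
        adj = signed_adjacency(corr, config.network.beta)
        tom = topological_overlap(adj)
        assignments = detect_modules(tom, transformed.features, config.network)
        annotated = {m.feature_id for m in meta
                     if m.annotation_level is not None
                     and m.feature_id in transformed.features}
        results = correlate_modules_with_gas(transformed, assignments, gas_vec,
                                             config.network, annotated)
        rows = [{
            "module_id": m.module_id, "n_members": len(m.members),
            "gas_correlation": m.gas_correlation,
            "n_retained": len(m.retained),
        } for m in results]
        df = pd.DataFrame(rows) if rows else pd.DataFrame(
            columns=["module_id", "n_members", "gas_correlation", "n_retained"])
        p = out / "methane_modules.tsv"
        df.to_csv(p, sep="\t", index=False)
        pm = out / "module_membership.tsv"
        assignments.rename("module_id").to_csv(pm, sep="\t", index_label="feature_id")
        record("methane_modules", len(assignments), p, pm)
        return results

    stage("methane_modules", _modules)

    manifest_path = out / "manifest.json"
    rio.write_json(manifest_path, manifest)
    return manifest
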