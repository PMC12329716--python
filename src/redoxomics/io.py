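"""Readers and writers for the pipeline's tabular dialects.

All artifacts are plain text: feature tables and metadata as TSV (MS2
fragment lists semicolon-joined), transcript counts and gene catalogs as
TSV, gas series and designs as CSV, pathway definitions as TSV, truth
labels and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cleaning import FeatureMeta, FeatureTable
from .formula import MolecularFormula
from .gas import GasSample
from .pathways import GeneCatalog, PathwayDefinition

META_COLS = ["feature_id", "mz", "rt", "formula", "ms2", "annotation_level"]


def write_feature_table(path, table: FeatureTable, meta: list[FeatureMeta]) -> None:
    """One TSV row per feature: metadata columns then per-sample intensities."""
    meta_by_id = {m.feature_id: m for m in meta}
    rows = []
    for fid in table.features:
        m = meta_by_id[fid]
        rows.append({
            "feature_id": fid,
            "mz": m.mz,
            "rt": m.rt,
            "formula": str(m.formula) if m.formula else "",
            "ms2": ";".join(f"{v:.6f}" for v in m.ms2_fragments),
            "annotation_level": m.annotation_level if m.annotation_level else "",
        })
    df = pd.DataFrame(rows).set_index("feature_id")
    out = pd.concat([df, table.data], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_feature_table(path) -> tuple[FeatureTable, list[FeatureMeta]]:
    df = pd.read_csv(path, sep="\t", index_col="feature_id",
                     keep_default_na=False, na_values=[])
    meta_cols = [c for c in META_COLS if c != "feature_id"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    meta = []
    for fid, row in df.iterrows():
        ms2 = tuple(float(v) for v in str(row["ms2"]).split(";") if v)
        formula = (MolecularFormula.parse(row["formula"])
                   if row["formula"] else None)
        level = int(row["annotation_level"]) if str(row["annotation_level"]).strip() else None
        meta.append(FeatureMeta(
            feature_id=str(fid), mz=float(row["mz"]), rt=float(row["rt"]),
            ms2_fragments=ms2, formula=formula, annotation_level=level,
        ))
    table = FeatureTable(df[sample_cols].astype(float), require_nonnegative=False)
    return table, meta


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_catalog(path, catalog: GeneCatalog) -> None:
    catalog.frame.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> GeneCatalog:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    df["length_bp"] = df["length_bp"].astype(int)
    return GeneCatalog(df)


def write_pathway_definitions(path, defs: list[PathwayDefinition]) -> None:
    pd.DataFrame([{
        "pathway_id": d.pathway_id, "name": d.name,
        "category": d.category, "expression": d.expression,
    } for d in defs]).to_csv(path, sep="\t", index=False)


def read_pathway_definitions(path) -> list[PathwayDefinition]:
    df = pd.read_csv(path, sep="\t")
    return [PathwayDefinition(r.pathway_id, r.name, r.category, r.expression)
            for r in df.itertuples()]


def write_gas_series(path, samples: list[GasSample]) -> None:
    pd.DataFrame([{
        "sample_id": s.sample_id, "day": s.day, "gas": s.gas,
        "ppm": s.headspace_ppm, "temp_C": s.temperature - 273.15, "pH": s.pH,
        "headspace_mL": s.headspace_volume * 1000.0,
        "liquid_mL": s.liquid_volume * 1000.0,
        "pressure_atm": s.total_pressure,
    } for s in samples]).to_csv(path, index=False)


def read_gas_series(path) -> list[GasSample]:
    df = pd.read_csv(path)
    return [GasSample(
        sample_id=str(r.sample_id), day=int(r.day), gas=str(r.gas),
        headspace_ppm=float(r.ppm), temperature=float(r.temp_C) + 273.15,
        pH=float(r.pH), headspace_volume=float(r.headspace_mL) / 1000.0,
        liquid_volume=float(r.liquid_mL) / 1000.0,
        total_pressure=float(getattr(r, "pressure_atm", 1.0)),
    ) for r in df.itertuples()]


def write_design(path, design: pd.DataFrame) -> None:
    design.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
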