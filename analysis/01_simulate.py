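"""Generate the synthetic study inputs with ground-truth labels.

Writes the LC-MS feature table (with planted in-source fragment and
halogen artifacts), the MAG-structured transcript counts and gene
catalog, the headspace gas series, the pathway definitions, and the
truth-label sidecar under results/data/.
"""

from pathlib import Path

from redoxomics import io as rio
from redoxomics.synth import (SynthConfig, default_pathway_definitions,
                              generate_feature_table, generate_gas_series,
                              generate_transcript_counts)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(seed=SEED)
    defs = default_pathway_definitions()

    table, meta, truth = generate_feature_table(cfg)
    counts, catalog, mag_truth = generate_transcript_counts(cfg, defs)
    gas_series, gas_truth = generate_gas_series(cfg)

    rio.write_feature_table(OUT / "features_raw.tsv", table, meta)
    rio.write_counts(OUT / "counts.tsv", counts)
    rio.write_catalog(OUT / "gene_catalog.tsv", catalog)
    rio.write_gas_series(OUT / "gas_series.csv", gas_series)
    rio.write_pathway_definitions(OUT / "pathway_definitions.tsv", defs)
    truth.active_mag_ids = mag_truth.active_mag_ids
    truth.encoded_pathways = mag_truth.encoded_pathways
    truth.gas_truth = gas_truth.gas_truth
    (OUT / "truth_labels.json").write_text(truth.to_json())

    print(f"feature table: {len(table.features)} features "
          f"({len(truth.fragment_parents)} planted fragments, "
          f"{len(truth.artifact_feature_ids) - len(truth.fragment_parents)} "
          f"halogen artifacts) x {len(table.samples)} samples")
    print(f"counts: {counts.shape[0]} genes in {cfg.n_mags} MAGs "
          f"x {counts.shape[1]} samples")
    print(f"gas series: {len(gas_series)} measurements")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
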