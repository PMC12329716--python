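"""Normalize the cleaned feature table and test habitat differences.

glog + Pareto transform, PCA overview, per-feature OLS with
habitat-by-timepoint contrasts under BH correction, and NOSC scores for
every feature with a predicted formula.
"""

from pathlib import Path

import pandas as pd

from redoxomics import io as rio
from redoxomics.formula import nosc
from redoxomics.stats import (GlogParams, fit_feature_models, glog_transform,
                              pareto_scale, pca_scores)

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table, meta = rio.read_feature_table(BASE / "features_cleaned.tsv")
    transformed = pareto_scale(glog_transform(table, GlogParams()))
    rio.write_feature_table(BASE / "features_transformed.tsv", transformed, meta)

    design = pd.DataFrame({
        "sample_id": table.samples,
        "habitat": [s.split("_")[0] for s in table.samples],
        "day": [int(s.split("_d")[1][:2]) for s in table.samples],
    })
    results = fit_feature_models(transformed, design)
    df = pd.DataFrame([r.__dict__ for r in results])
    df.to_csv(BASE / "habitat_contrasts.tsv", sep="\t", index=False)

    _, _, ev = pca_scores(transformed, 2)
    nosc_rows = [{"feature_id": m.feature_id, "nosc": nosc(m.formula)}
                 for m in meta if m.formula is not None
                 and m.feature_id in set(table.features)
                 and m.formula.count("C") >= 1]
    pd.DataFrame(nosc_rows).to_csv(BASE / "feature_nosc.tsv", sep="\t",
                                   index=False)

    n_sig = (df["q_value"] < 0.05).sum()
    print(f"PC1/PC2 explain {ev[0]:.1%} / {ev[1]:.1%} of variance")
    print(f"{n_sig} of {len(df)} feature-timepoint contrasts at q < 0.05")
    print(f"NOSC computed for {len(nosc_rows)} features with formulas")


if __name__ == "__main__":
    main()
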