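"""MAG activity and pathway-encoding curation.

A metagenome-assembled genome (MAG) is called *active* in a sample when
its genes recruit strictly more than 15 transcripts there; an active MAG
*encodes* a pathway when its annotated KO set covers at least 60% of the
pathway's steps.  Encoding proportions are compared between habitats
with the Wilcoxon rank-sum test, and per-MAG coupling of oxidative to
fermentative expression is summarized by a Pearson correlation over MAGs
at each timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pathways import Complex, GeneCatalog, Group, Leaf, PathwayAST, Step

__all__ = [
    "CurationParams",
    "MagPathwayProfile",
    "active_mags",
    "pathway_encoded",
    "encoding_proportion",
    "wilcoxon_habitat_test",
    "mag_redox_coupling",
]


@dataclass(frozen=True)
class CurationParams:
    """Activity threshold (transcripts per sample, strict >) and minimum
    encoded-step fraction (inclusive >=)."""

    activity_threshold: int = 15
    encoding_fraction: float = 0.60
    complex_rule: str = "all"  # "all": every subunit required; "any": one suffices

    def __post_init__(self) -> None:
        if self.activity_threshold < 0:
            raise ValueError("activity_threshold must be nonnegative")
        if not 0 < self.encoding_fraction <= 1:
            raise ValueError("encoding_fraction must be in (0, 1]")
        if self.complex_rule not in ("all", "any"):
            raise ValueError("complex_rule must be 'all' or 'any'")


@dataclass
class MagPathwayProfile:
    mag_id: str
    active_in: set[str] = field(default_factory=set)
    encoded: dict[str, bool] = field(default_factory=dict)
    expression: dict[str, pd.Series] = field(default_factory=dict)


def active_mags(counts: pd.DataFrame, catalog: GeneCatalog,
                params: CurationParams | None = None) -> dict[str, set[str]]:
    """Per-sample sets of active MAGs (total transcript count > threshold)."""
    params = params or CurationParams()
    cat = catalog.frame.set_index("gene_id")
    missing = set(counts.index) - set(cat.index)
    if missing:
        raise ValueError(f"genes without MAG assignment: {sorted(missing)[:5]}")
    mags = cat.loc[counts.index, "mag_id"]
    if mags.isna().any():
        raise ValueError("genes without MAG assignment")
    totals = counts.groupby(mags.values).sum()  # MAG x sample
    return {
        sample: set(totals.index[totals[sample] > params.activity_threshold])
        for sample in counts.columns
    }


def _step_satisfied(node, kos: set[str], complex_rule: str) -> bool:
    if isinstance(node, Leaf):
        return node.ko in kos
    if isinstance(node, Complex):
        op = all if complex_rule == "all" else any
        return op(_step_satisfied(m, kos, complex_rule) for m in node.members)
    if isinstance(node, Step):
        return any(_step_satisfied(a, kos, complex_rule) for a in node.alternatives)
    if isinstance(node, Group):
        # a nested sequence acts as one alternative: all its steps required
        return all(_step_satisfied(s, kos, complex_rule) for s in node.steps)
    raise TypeError(type(node))


def pathway_encoded(kos: set[str], ast: PathwayAST, fraction: float = 0.60,
                    complex_rule: str = "all") -> tuple[bool, int]:
    """Whether a KO set encodes a pathway; returns (flag, encoded steps).

    A step counts as encoded when at least one of its alternatives is
    satisfied; a complex alternative requires all subunits by default.
    The pathway is encoded when encoded_steps / total_steps >= fraction.
    """
    encoded_steps = sum(
        _step_satisfied(step, kos, complex_rule) for step in ast.steps
    )
    return encoded_steps / len(ast.steps) >= fraction, encoded_steps


def encoding_proportion(profiles: list[MagPathwayProfile],
                        pathway_id: str) -> float:
    """Fraction of active MAGs (active in >=1 sample) encoding a pathway."""
    active = [p for p in profiles if p.active_in]
    if not active:
        raise ValueError("no active MAGs: encoding proportion undefined")
    encoded = sum(bool(p.encoded.get(pathway_id)) for p in active)
    return encoded / len(active)


def wilcoxon_habitat_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when n_a + n_b <= 20 and there are no ties;
    normal approximation with tie and continuity correction otherwise.
    Returns ``(U statistic of the first sample, p value)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def mag_redox_coupling(expression: pd.DataFrame,
                       oxidative_ids: list[str],
                       fermentation_ids: list[str]) -> float:
    """Pearson r over MAGs between summed oxidative and summed
    fermentative pathway expression at one timepoint.

    ``expression`` is MAG x pathway (already restricted to the timepoint,
    e.g. replicate-averaged scores).  Requires >=3 MAGs; returns NaN when
    either summed axis is constant (flagged, not an error).
    """
    if len(expression) < 3:
        raise ValueError("need at least 3 active MAGs for a correlation")
    ox = expression[list(oxidative_ids)].sum(axis=1)
    fe = expression[list(fermentation_ids)].sum(axis=1)
    if ox.std(ddof=0) == 0 or fe.std(ddof=0) == 0:
        return float("nan")
    return float(np.corrcoef(ox, fe)[0, 1])


def redox_coupling_by_timepoint(profiles: list[MagPathwayProfile],
                                oxidative_ids: list[str],
                                fermentation_ids: list[str],
                                design: pd.DataFrame) -> pd.Series:
    """Per-timepoint oxidative-vs-fermentative Pearson r over MAGs.

    For each day in ``design`` (columns sample_id, day), every MAG's
    pathway expression is averaged over that day's samples, oxidative and
    fermentative pathway sets are each summed, and the correlation is
    taken across MAGs with expression profiles.  Days with fewer than 3
    such MAGs yield NaN (flagged, not an error).
    """
    design = design.set_index("sample_id")
    out = {}
    for day in sorted(design["day"].unique()):
        samples = design.index[design["day"] == day]
        rows = {}
        for prof in profiles:
            if not prof.expression:
                continue
            rows[prof.mag_id] = {
                pid: float(series.loc[samples].mean())
                for pid, series in prof.expression.items()
            }
        mat = pd.DataFrame.from_dict(rows, orient="index")
        try:
            out[day] = mag_redox_coupling(mat, oxidative_ids, fermentation_ids)
        except ValueError:
            out[day] = float("nan")
    return pd.Series(out, name="oxidative_fermentative_r")


def build_profiles(counts: pd.DataFrame, catalog: GeneCatalog,
                   definitions, normalized: pd.DataFrame | None = None,
                   params: CurationParams | None = None) -> list[MagPathwayProfile]:
    """Full curation pass: activity, encoding, and per-MAG pathway expression.

    Encoding uses the MAG's annotated KO set (genomic potential); pathway
    expression, when a normalized matrix is supplied, sums the MAG's
    normalized gene expression per KO and applies the pathway logic.
    """
    from .pathways import ko_expression, score_pathway

    params = params or CurationParams()
    activity = active_mags(counts, catalog, params)
    cat = catalog.frame
    profiles = []
    for mag_id, genes in cat.groupby("mag_id"):
        prof = MagPathwayProfile(mag_id=mag_id)
        prof.active_in = {s for s, mags in activity.items() if mag_id in mags}
        kos = set(genes["ko"].dropna()) - {""}
        if prof.active_in:
            ko_mat = None
            if normalized is not None:
                ko_mat = ko_expression(normalized, catalog, mag_scope={mag_id})
            for d in definitions:
                ast = d.ast
                flag, _ = pathway_encoded(kos, ast, params.encoding_fraction,
                                          params.complex_rule)
                prof.encoded[d.pathway_id] = flag
                if ko_mat is not None:
                    prof.expression[d.pathway_id] = pd.Series(
                        [score_pathway(ast, ko_mat[c].to_dict())
                         for c in ko_mat.columns],
                        index=ko_mat.columns, dtype=float,
                    )
        profiles.append(prof)
    return profiles
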