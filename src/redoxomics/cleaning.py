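"""In-source fragment and halogen artifact removal for LC-MS feature tables.

Electrospray ionization fragments a share of each parent ion in the
source, so an untargeted feature table contains "features" that are
really pieces of a heavier co-eluting compound.  These artifacts (i)
share the parent's retention time, (ii) track the parent's intensity
almost perfectly across samples, and (iii) have an m/z that appears in
the parent's MS2 spectrum.  The cleaning procedure is:

1. bin features by retention time (single-linkage, gap tolerance);
2. within a bin, group features whose raw intensities have Pearson
   r above a threshold (connected components);
3. in each correlated group, call the heaviest ion the parent and remove
   lighter members whose m/z matches a parent MS2 fragment within a ppm
   tolerance;
4. drop features whose predicted formula contains a halogen (F/Cl/Br/I),
   implausible in natural peat organic matter.

Every decision is recorded in a :class:`CleaningReport` for human review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula import MolecularFormula

__all__ = [
    "FeatureMeta",
    "FeatureTable",
    "CleaningParams",
    "CleaningReport",
    "bin_by_rt",
    "coeluting_pairs",
    "match_fragment_to_parent",
    "remove_halogen_features",
    "clean",
]


@dataclass(frozen=True)
class FeatureMeta:
    """Per-feature metadata: masses, retention time, MS2 fragments, formula."""

    feature_id: str
    mz: float
    rt: float
    ms2_fragments: tuple[float, ...] = ()
    formula: MolecularFormula | None = None
    annotation_level: int | None = None  # 1 = library standard ... 3 = formula only

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if any(f <= 0 for f in self.ms2_fragments):
            raise ValueError("MS2 fragment m/z must be positive")
        if self.annotation_level is not None and self.annotation_level not in (1, 2, 3):
            raise ValueError("annotation_level must be 1, 2, or 3")


class FeatureTable:
    """Feature x sample intensity matrix with ordered, unique feature ids.

    Thin wrapper around a pandas DataFrame (rows = features, columns =
    samples); intensities must be nonnegative.
    """

    def __init__(self, data: pd.DataFrame, require_nonnegative: bool = True):
        if data.index.has_duplicates:
            raise ValueError("duplicate feature_id in table")
        if require_nonnegative and (data.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")
        self.data = data.astype(float)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(feature_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"FeatureTable({self.data.shape[0]} features x {self.data.shape[1]} samples)"


@dataclass(frozen=True)
class CleaningParams:
    """Thresholds of the artifact-removal procedure (defaults as used
    throughout: RT gap 0.005, Pearson r > 0.98, 5 ppm mass tolerance)."""

    rt_tolerance: float = 0.005
    correlation_threshold: float = 0.98
    ppm_tolerance: float = 5.0
    drop_halogens: bool = True

    def __post_init__(self) -> None:
        if self.rt_tolerance <= 0:
            raise ValueError("rt_tolerance must be positive")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be positive")


@dataclass
class CleaningReport:
    """Accounting of what `clean` did to every input feature."""

    removed_as_fragment: list[tuple[str, str, float, float]] = field(default_factory=list)
    removed_as_halogen: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def removed_ids(self) -> set[str]:
        return {f for f, *_ in self.removed_as_fragment} | set(self.removed_as_halogen)

    def to_dict(self) -> dict:
        return {
            "removed_as_fragment": [
                {"fragment_id": f, "parent_id": p, "r": r, "ppm_error": e}
                for f, p, r, e in self.removed_as_fragment
            ],
            "removed_as_halogen": list(self.removed_as_halogen),
            "retained": list(self.retained),
        }


def bin_by_rt(meta: list[FeatureMeta], tol: float) -> list[set[str]]:
    """Single-linkage retention-time bins.

    Features are sorted by RT; a gap greater than ``tol`` between
    consecutive features starts a new bin (a gap exactly equal to the
    tolerance still joins).  Bins partition the input.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if not meta:
        return []
    ordered = sorted(meta, key=lambda m: (m.rt, m.feature_id))
    bins: list[set[str]] = [{ordered[0].feature_id}]
    prev_rt = ordered[0].rt
    for m in ordered[1:]:
        if m.rt - prev_rt > tol:
            bins.append(set())
        bins[-1].add(m.feature_id)
        prev_rt = m.rt
    return bins


def coeluting_pairs(bin_ids: set[str], table: FeatureTable,
                    threshold: float) -> list[tuple[str, str, float]]:
    """Unordered feature pairs within a bin with Pearson r strictly above
    ``threshold`` on raw intensities; zero-variance features are skipped."""
    if len(table.samples) < 3:
        raise ValueError("at least 3 samples required for correlation grouping")
    ids = sorted(bin_ids)
    if len(ids) < 2:
        return []
    mat = table.data.loc[ids].to_numpy()
    sd = mat.std(axis=1)
    keep = sd > 0
    if keep.sum() < 2:
        return []
    live = [i for i, k in zip(range(len(ids)), keep) if k]
    sub = mat[live]
    corr = np.corrcoef(sub)
    out = []
    for a in range(len(live)):
        for b in range(a + 1, len(live)):
            r = float(corr[a, b])
            if r > threshold:
                out.append((ids[live[a]], ids[live[b]], r))
    return out


def match_fragment_to_parent(candidate: FeatureMeta, parent: FeatureMeta,
                             ppm: float) -> tuple[float, float] | None:
    """Best parent-MS2 fragment match for a lighter candidate ion.

    Returns ``(matched_mz, ppm_error)`` for the MS2 fragment of the
    parent closest in relative mass to the candidate, provided the error
    is within ``ppm``; ``None`` when nothing qualifies.
    """
    if candidate.mz >= parent.mz:
        raise ValueError("candidate must be lighter than the parent ion")
    if not parent.ms2_fragments:
        return None
    best = None
    for frag_mz in parent.ms2_fragments:
        err = abs(frag_mz - candidate.mz) / candidate.mz * 1e6
        if best is None or err < best[1]:
            best = (frag_mz, err)
    if best is not None and best[1] <= ppm:
        return best
    return None


def remove_halogen_features(meta: list[FeatureMeta]) -> tuple[list[FeatureMeta], list[FeatureMeta]]:
    """Split features into (kept, removed) by the halogen-formula rule.

    Features without a predicted formula are kept: absence of a
    prediction is not evidence of halogens.
    """
    kept, removed = [], []
    for m in meta:
        if m.formula is not None and m.formula.contains_halogen:
            removed.append(m)
        else:
            kept.append(m)
    return kept, removed


def _connected_components(ids: set[str], edges: list[tuple[str, str, float]]):
    """Connected components of the correlation graph (co-elution clusters)."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return [c for c in comps.values() if len(c) > 1]


def clean(table: FeatureTable, meta: list[FeatureMeta],
          params: CleaningParams | None = None) -> tuple[FeatureTable, CleaningReport]:
    """Full artifact-removal pass; returns the cleaned table and a report.

    The report partitions the input exactly: every feature is retained,
    removed as an in-source fragment (with its parent, correlation and
    ppm error), or removed by the halogen rule.
    """
    params = params or CleaningParams()
    meta_by_id = {m.feature_id: m for m in meta}
    missing = set(table.features) - set(meta_by_id)
    if missing:
        raise ValueError(f"features missing metadata: {sorted(missing)[:5]}")

    report = CleaningReport()
    fragment_removed: set[str] = set()

    table_meta = [meta_by_id[f] for f in table.features]
    for bin_ids in bin_by_rt(table_meta, params.rt_tolerance):
        edges = coeluting_pairs(bin_ids, table, params.correlation_threshold)
        if not edges:
            continue
        r_lookup = {}
        for a, b, r in edges:
            r_lookup[(a, b)] = r
            r_lookup[(b, a)] = r
        for group in _connected_components(bin_ids, edges):
            # parent = heaviest ion; m/z ties broken by feature_id
            parent_id = max(group, key=lambda i: (meta_by_id[i].mz, i))
            parent = meta_by_id[parent_id]
            for cand_id in sorted(group - {parent_id}):
                cand = meta_by_id[cand_id]
                if cand.mz >= parent.mz:
                    continue
                hit = match_fragment_to_parent(cand, parent, params.ppm_tolerance)
                if hit is not None:
                    r = r_lookup.get((cand_id, parent_id), float("nan"))
                    report.removed_as_fragment.append((cand_id, parent_id, r, hit[1]))
                    fragment_removed.add(cand_id)

    halogen_removed: set[str] = set()
    if params.drop_halogens:
        survivors = [meta_by_id[f] for f in table.features if f not in fragment_removed]
        _, removed = remove_halogen_features(survivors)
        halogen_removed = {m.feature_id for m in removed}
        report.removed_as_halogen = sorted(halogen_removed)

    report.retained = [
        f for f in table.features
        if f not in fragment_removed and f not in halogen_removed
    ]
    cleaned = table.subset(report.retained)
    return cleaned, report
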