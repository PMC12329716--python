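"""Signed weighted co-expression modules and their methane correlation.

A simplified signed WGCNA workflow for metabolite features: Pearson
correlation across samples, signed soft-thresholded adjacency
``a_ij = ((1 + r_ij) / 2)^beta`` at power 14, topological overlap (TOM)
similarity, average-linkage clustering of ``1 - TOM`` with a static cut,
module eigengenes (first principal component of the standardized member
submatrix), eigengene-methane Pearson correlation, and retention of the
top members of the most positively and most negatively methane-correlated
modules ranked by per-feature Spearman correlation with methane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cleaning import FeatureTable
from .stats import spearman_gas_correlation

__all__ = [
    "NetworkParams",
    "ModuleResult",
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "correlate_modules_with_gas",
]

UNASSIGNED = "grey"


@dataclass(frozen=True)
class NetworkParams:
    """Network construction and module-retention settings.

    ``beta`` is the soft-thresholding power (14); modules come from a
    static cut of the average-linkage TOM dendrogram at ``cut_height``
    with clusters below ``min_module_size`` left unassigned; ``top_n``
    members are retained for the extreme methane-correlated modules.
    """

    beta: int = 14
    min_module_size: int = 30
    cut_height: float = 0.995
    top_n: int = 100
    require_annotation: bool = True
    rank_by: str = "gas_spearman"  # or "kme" (module-membership strength)

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.rank_by not in ("gas_spearman", "kme"):
            raise ValueError("rank_by must be 'gas_spearman' or 'kme'")


@dataclass
class ModuleResult:
    module_id: str
    members: list[str]
    eigengene: pd.Series
    gas_correlation: float
    member_gas_rho: pd.Series
    retained: list[str] = field(default_factory=list)


def signed_adjacency(corr: np.ndarray, beta: int = 14) -> np.ndarray:
    """Signed soft-thresholded adjacency; diagonal zeroed for connectivity."""
    corr = np.asarray(corr, dtype=float)
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    corr = np.clip(corr, -1.0, 1.0)
    adj = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM similarity: shared-neighborhood-weighted adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    unit diagonal.
    """
    a = np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(tom: np.ndarray, feature_ids: list[str],
                   params: NetworkParams | None = None) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` are left unassigned
    ("grey").  Labels are deterministic: modules ordered by decreasing
    size, ties by lexicographically smallest member id.
    """
    params = params or NetworkParams()
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    if len(feature_ids) != diss.shape[0]:
        raise ValueError("feature_ids length must match TOM dimension")
    if len(feature_ids) < 2:
        return pd.Series(UNASSIGNED, index=feature_ids)
    z = linkage(squareform(diss, checks=False), method="average")
    flat = fcluster(z, t=params.cut_height, criterion="distance")
    labels = pd.Series(flat, index=feature_ids)
    assignments = pd.Series(UNASSIGNED, index=feature_ids, dtype=object)
    clusters = []
    for cl in np.unique(flat):
        members = sorted(labels.index[labels == cl])
        if len(members) >= params.min_module_size:
            clusters.append(members)
    clusters.sort(key=lambda m: (-len(m), m[0]))
    for rank, members in enumerate(clusters, start=1):
        assignments[members] = f"M{rank}"
    return assignments


def module_eigengene(table: FeatureTable, members: list[str]) -> pd.Series:
    """First principal component of the standardized member submatrix.

    Sign is oriented so the mean member-eigengene correlation is
    positive, making the eigengene a representative module profile.
    """
    if len(members) < 2:
        raise ValueError("eigengene needs at least 2 member features")
    x = table.data.loc[members].to_numpy()  # members x samples
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mu) / sd
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    eig = vt[0]  # per-sample scores of PC1
    member_corr = xs @ eig
    if member_corr.mean() < 0:
        eig = -eig
    return pd.Series(eig, index=table.samples, name="eigengene")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def correlate_modules_with_gas(table: FeatureTable, assignments: pd.Series,
                               gas: np.ndarray | pd.Series,
                               params: NetworkParams | None = None,
                               annotated: set[str] | None = None) -> list[ModuleResult]:
    """Eigengene-methane correlation per module plus top-member retention.

    For the most positively and most negatively correlated modules, up to
    ``top_n`` members are retained, ranked by |Spearman rho| between raw
    member intensity and methane (or by module-membership strength when
    ``rank_by="kme"``); when ``require_annotation`` is on, features not in
    ``annotated`` are dropped before ranking.  Ties break by feature id.
    """
    params = params or NetworkParams()
    gas = np.asarray(gas, dtype=float)
    if gas.size != len(table.samples):
        raise ValueError("gas vector must align with samples")
    constant_gas = np.ptp(gas) == 0
    rho_all = spearman_gas_correlation(table, gas)

    results = []
    for module_id in sorted(set(assignments) - {UNASSIGNED}):
        members = sorted(assignments.index[assignments == module_id])
        eig = module_eigengene(table, members)
        r = float("nan") if constant_gas else _pearson(eig.to_numpy(), gas)
        results.append(ModuleResult(
            module_id=module_id,
            members=members,
            eigengene=eig,
            gas_correlation=r,
            member_gas_rho=rho_all.loc[members],
        ))

    if constant_gas or not results:
        return results

    finite = [m for m in results if np.isfinite(m.gas_correlation)]
    if not finite:
        return results
    most_pos = max(finite, key=lambda m: m.gas_correlation)
    most_neg = min(finite, key=lambda m: m.gas_correlation)
    for mod in {id(m): m for m in (most_pos, most_neg)}.values():
        pool = mod.members
        if params.require_annotation and annotated is not None:
            pool = [f for f in pool if f in annotated]
        if params.rank_by == "kme":
            eig = mod.eigengene.to_numpy()
            strength = {
                f: abs(_pearson(table.data.loc[f].to_numpy(), eig)) for f in pool
            }
        else:
            strength = {f: abs(mod.member_gas_rho.get(f, np.nan)) for f in pool}
        ranked = sorted(pool, key=lambda f: (-np.nan_to_num(strength[f]), f))
        mod.retained = ranked[: params.top_n]
    return results
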