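"""Normalization and per-feature statistics for metabolite intensities.

Covers the transform/scale/test chain applied to a cleaned feature
table: generalized-log transform (handles zeros via an offset equal to
the smallest nonzero intensity), Pareto scaling, PCA, per-feature linear
models with habitat-by-day interaction and per-timepoint habitat
contrasts under Benjamini-Hochberg correction, NOSC scoring, and
Spearman correlations of raw intensities with methane totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cleaning import FeatureTable

__all__ = [
    "GlogParams",
    "ContrastResult",
    "glog_transform",
    "pareto_scale",
    "bh_adjust",
    "fit_feature_models",
    "pca_scores",
    "spearman_gas_correlation",
]


@dataclass(frozen=True)
class GlogParams:
    """Generalized-log parameters.

    ``a`` ("lambda") is the transform offset; when ``None`` it is derived
    as the minimum nonzero intensity across the whole dataset.  ``mode``
    selects the standard glog ``log2((x + sqrt(x^2 + a^2)) / 2)`` or the
    ``literal`` variant ``sqrt(x^2 + a^2) / 2`` (no logarithm), kept for
    faithfulness audits.
    """

    a: float | None = None
    mode: str = "standard"

    def __post_init__(self) -> None:
        if self.a is not None and self.a < 0:
            raise ValueError("offset a must be nonnegative")
        if self.mode not in ("standard", "literal"):
            raise ValueError("mode must be 'standard' or 'literal'")


@dataclass(frozen=True)
class ContrastResult:
    """Bog-vs-fen difference for one feature at one timepoint."""

    feature_id: str
    timepoint: str
    estimate: float
    p_value: float
    q_value: float


def derive_glog_offset(table: FeatureTable) -> float:
    """Minimum nonzero intensity across all features and samples."""
    vals = table.values
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("table contains no nonzero intensities")
    return float(nonzero.min())


def glog_transform(table: FeatureTable, params: GlogParams | None = None) -> FeatureTable:
    """Generalized-log transform of every intensity."""
    params = params or GlogParams()
    a = derive_glog_offset(table) if params.a is None else params.a
    x = table.values
    if params.mode == "standard":
        if a == 0 and (x == 0).any():
            raise ValueError("a=0 with zero intensities: log of 0")
        out = np.log2((x + np.sqrt(x**2 + a**2)) / 2.0)
    else:
        out = np.sqrt(x**2 + a**2) / 2.0
    return FeatureTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
                        require_nonnegative=False)


def pareto_scale(table: FeatureTable) -> FeatureTable:
    """Divide each feature row by the square root of its standard
    deviation (n-1 denominator); zero-variance rows pass through."""
    if len(table.samples) < 2:
        raise ValueError("Pareto scaling needs at least 2 samples")
    x = table.values
    sd = x.std(axis=1, ddof=1)
    divisor = np.where(sd > 0, np.sqrt(sd), 1.0)
    out = x / divisor[:, None]
    return FeatureTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
                        require_nonnegative=False)


def bh_adjust(p: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _align_final_day(design: pd.DataFrame) -> pd.Series:
    """Map day labels to timepoint levels, pooling each habitat's last
    sampling day into a shared 'final' level (bog day 28 = fen day 35)."""
    design = design.copy()
    levels = design["day"].astype(str)
    final = {}
    for hab, sub in design.groupby("habitat"):
        final[hab] = sub["day"].max()
    is_final = design.apply(lambda r: r["day"] == final[r["habitat"]], axis=1)
    # only pool when the habitats' final days differ; otherwise keep the label
    finals = set(final.values())
    if len(finals) > 1:
        return pd.Series(np.where(is_final, "final", levels), index=design.index)
    return levels


def fit_feature_models(table: FeatureTable, design: pd.DataFrame,
                       align_final: bool = True,
                       bh_family: str = "per_timepoint") -> list[ContrastResult]:
    """Per-feature OLS with habitat, day (categorical) and interaction;
    bog-vs-fen contrast at every timepoint.

    ``design`` needs columns ``sample_id``, ``habitat`` (bog/fen), ``day``.
    The model is fit in cell-means form (one coefficient per
    habitat-by-timepoint cell), so the contrast at timepoint t is the
    difference of cell means; p-values are two-sided t tests on the
    residual degrees of freedom, BH-adjusted across features within each
    timepoint (``bh_family="pooled"`` adjusts across all contrasts at once).
    """
    if bh_family not in ("per_timepoint", "pooled"):
        raise ValueError("bh_family must be 'per_timepoint' or 'pooled'")
    design = design.set_index("sample_id").loc[table.samples]
    habitats = sorted(design["habitat"].unique())
    if len(habitats) != 2:
        raise ValueError("exactly two habitats required")
    tp = _align_final_day(design) if align_final else design["day"].astype(str)
    design = design.assign(timepoint=tp.values)

    cells = sorted(set(zip(design["habitat"], design["timepoint"])))
    timepoints = sorted(design["timepoint"].unique(), key=str)
    for t in timepoints:
        for h in habitats:
            if (h, t) not in cells:
                raise ValueError(f"design cell missing: habitat={h!r} timepoint={t!r}")

    # cell-means design matrix
    cell_index = {c: j for j, c in enumerate(cells)}
    n = len(design)
    X = np.zeros((n, len(cells)))
    for i, (h, t) in enumerate(zip(design["habitat"], design["timepoint"])):
        X[i, cell_index[(h, t)]] = 1.0

    Y = table.values.T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n - len(cells)
    if df <= 0:
        raise ValueError("no residual degrees of freedom (need replication)")
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)

    bog, fen = habitats[0], habitats[-1]
    if "bog" in habitats:
        bog, fen = "bog", [h for h in habitats if h != "bog"][0]

    rows: dict[str, list] = {t: [] for t in timepoints}
    for t in timepoints:
        c = np.zeros(len(cells))
        c[cell_index[(bog, t)]] = 1.0
        c[cell_index[(fen, t)]] = -1.0
        est = c @ beta  # per-feature estimates
        se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
        pvals = 2.0 * sps.t.sf(np.abs(tstat), df)
        pvals = np.where(se > 0, pvals, 1.0)
        rows[t] = [est, pvals]

    results: list[ContrastResult] = []
    features = table.features
    if bh_family == "per_timepoint":
        for t in timepoints:
            est, pvals = rows[t]
            qvals = bh_adjust(pvals)
            results += [
                ContrastResult(f, str(t), float(e), float(p), float(q))
                for f, e, p, q in zip(features, est, pvals, qvals)
            ]
    else:
        all_p = np.concatenate([rows[t][1] for t in timepoints])
        all_q = bh_adjust(all_p)
        k = len(features)
        for j, t in enumerate(timepoints):
            est, pvals = rows[t]
            qvals = all_q[j * k:(j + 1) * k]
            results += [
                ContrastResult(f, str(t), float(e), float(p), float(q))
                for f, e, p, q in zip(features, est, pvals, qvals)
            ]
    return results


def pca_scores(table: FeatureTable, n_components: int = 2):
    """Mean-centered SVD PCA of samples over features.

    Returns ``(scores, loadings, explained_variance_fraction)``; sign of
    each component fixed so its largest-magnitude loading is positive.
    """
    x = table.values.T  # samples x features
    n_samples, n_features = x.shape
    if n_components > min(n_samples, n_features):
        raise ValueError("n_components exceeds matrix rank bound")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    total_var = (xc**2).sum()
    if total_var == 0:
        explained = np.zeros(n_components)
    else:
        explained = (s[:n_components] ** 2) / total_var
    return scores, loadings, explained


def spearman_gas_correlation(table: FeatureTable, gas: np.ndarray | pd.Series) -> pd.Series:
    """Per-feature Spearman rho between raw intensity and methane totals.

    A constant gas vector yields NaN for every feature (flagged, not an
    error); ties are handled by average ranks.
    """
    gas = np.asarray(gas, dtype=float)
    if gas.size != len(table.samples):
        raise ValueError("gas vector length must match sample count")
    if gas.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(gas) == 0:
        return pd.Series(np.nan, index=table.data.index, name="spearman_rho")
    gas_rank = sps.rankdata(gas)
    ranks = np.apply_along_axis(sps.rankdata, 1, table.values)
    gr = gas_rank - gas_rank.mean()
    rr = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rr**2).sum(axis=1) * (gr**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rr @ gr) / denom, np.nan)
    return pd.Series(rho, index=table.data.index, name="spearman_rho")
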