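"""KEGG-style pathway logic, geTMM normalization, and pathway scoring.

A pathway definition is a logical expression over KO (KEGG Orthology)
identifiers, written in the KEGG module grammar: whitespace separates
sequential steps, a comma separates interchangeable alternatives within
a step, and a plus sign joins subunits of an enzyme complex.  Parentheses
group.  Expression is aggregated with the matching arithmetic: complex
subunits are averaged, alternatives are summed, and the pathway score is
the mean over steps.

Transcript counts are made comparable across samples with geTMM:
reads-per-kilobase values normalized by TMM (trimmed mean of M-values)
scale factors, reported per million.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PathwayDefinition",
    "PathwayAST",
    "Leaf",
    "Complex",
    "Step",
    "Group",
    "GeneCatalog",
    "parse_pathway_logic",
    "PathwayParseError",
    "getmm_normalize",
    "tmm_factors",
    "ko_expression",
    "score_pathway",
    "pathway_timeseries",
]


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Leaf:
    ko: str


@dataclass(frozen=True)
class Complex:
    members: tuple  # Leaf | Group

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a complex needs at least 2 members")


@dataclass(frozen=True)
class Group:
    """Parenthesized sub-expression, itself a sequence of steps."""

    steps: tuple  # of Step


@dataclass(frozen=True)
class Step:
    alternatives: tuple  # Leaf | Complex | Group

    def __post_init__(self):
        if not self.alternatives:
            raise ValueError("a step needs at least one alternative")


@dataclass(frozen=True)
class PathwayAST:
    steps: tuple  # of Step

    def __post_init__(self):
        if not self.steps:
            raise ValueError("a pathway needs at least one step")

    @property
    def kos(self) -> set[str]:
        out: set[str] = set()

        def walk(node):
            if isinstance(node, Leaf):
                out.add(node.ko)
            elif isinstance(node, Complex):
                for m in node.members:
                    walk(m)
            elif isinstance(node, (Group, PathwayAST)):
                for s in node.steps:
                    walk(s)
            elif isinstance(node, Step):
                for a in node.alternatives:
                    walk(a)

        walk(self)
        return out


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    category: str  # oxidative | reductive | TEA | other
    expression: str

    @property
    def ast(self) -> PathwayAST:
        return parse_pathway_logic(self.expression)


@dataclass(frozen=True)
class GeneCatalog:
    """gene -> MAG / KO / length mapping, backed by a DataFrame with
    columns gene_id, mag_id, ko, length_bp (gene_id unique)."""

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "mag_id", "ko", "length_bp"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"catalog missing columns {required - set(self.frame.columns)}")
        if self.frame["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in catalog")
        if (self.frame["length_bp"] <= 0).any():
            raise ValueError("gene lengths must be positive")

    def lengths_for(self, genes) -> pd.Series:
        s = self.frame.set_index("gene_id")["length_bp"]
        missing = set(genes) - set(s.index)
        if missing:
            raise ValueError(f"genes missing from catalog: {sorted(missing)[:5]}")
        return s.loc[genes]


# ---------------------------------------------------------------------------
# Parser


class PathwayParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


def _split_top(text: str, seps: str, offset: int) -> list[tuple[str, int]]:
    """Split on any char in `seps` at paren depth 0; returns (piece, abs_pos)."""
    parts, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise PathwayParseError("unbalanced ')'", offset + i)
        elif depth == 0 and ch in seps:
            parts.append((text[start:i], offset + start))
            start = i + 1
    if depth != 0:
        raise PathwayParseError("unbalanced '('", offset + len(text))
    parts.append((text[start:], offset + start))
    return parts


def _strip_optional(text: str) -> str:
    """Drop KEGG non-essential markers: standalone '--' and '-Kxxxxx' tails."""
    cleaned = re.sub(r"(?<![\w)])--(?![\w(])", " ", text)
    new = re.sub(r"-K\d{5}", "", cleaned)
    if new != text:
        warnings.warn("non-essential pathway components ('-' / '--') stripped",
                      stacklevel=3)
    return new


_KO_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.]*$")


def _parse_atom(text: str, pos: int):
    text = text.strip()
    if not text:
        raise PathwayParseError("empty term", pos)
    if text.startswith("(") and text.endswith(")"):
        # confirm the outer parens actually match each other
        depth = 0
        for i, ch in enumerate(text):
            depth += ch == "("
            depth -= ch == ")"
            if depth == 0 and i < len(text) - 1:
                break
        else:
            inner = _parse_steps(text[1:-1], pos + 1)
            return Group(tuple(inner))
    if not _KO_RE.match(text):
        raise PathwayParseError(f"unrecognized token {text!r}", pos)
    return Leaf(text)


def _parse_alternative(text: str, pos: int):
    pieces = _split_top(text, "+", pos)
    atoms = []
    for piece, p in pieces:
        if not piece.strip():
            raise PathwayParseError("empty complex member", p)
        atoms.append(_parse_atom(piece, p))
    if len(atoms) == 1:
        return atoms[0]
    return Complex(tuple(atoms))


def _parse_step(text: str, pos: int) -> Step:
    pieces = _split_top(text, ",", pos)
    alts = []
    for piece, p in pieces:
        if not piece.strip():
            raise PathwayParseError("empty alternative", p)
        alts.append(_parse_alternative(piece, p))
    return Step(tuple(alts))


def _parse_steps(text: str, offset: int) -> list[Step]:
    steps = []
    for piece, p in _split_top(text, " \t", offset):
        if piece.strip():
            steps.append(_parse_step(piece, p))
    if not steps:
        raise PathwayParseError("expression has no steps", offset)
    return steps


def parse_pathway_logic(expression: str) -> PathwayAST:
    """Parse a KEGG-style logical expression into a :class:`PathwayAST`.

    Precedence (loosest to tightest): whitespace (steps), ',' (alternatives),
    '+' (complex members); parentheses group.  KEGG's non-essential markers
    '-Kxxxxx' and '--' are stripped with a warning.
    """
    if not expression or not expression.strip():
        raise PathwayParseError("empty expression", 0)
    return PathwayAST(tuple(_parse_steps(_strip_optional(expression), 0)))


def serialize(node) -> str:
    """Inverse of the parser (parse(serialize(ast)) is parse-equivalent)."""
    if isinstance(node, Leaf):
        return node.ko
    if isinstance(node, Complex):
        return "+".join(serialize(m) for m in node.members)
    if isinstance(node, Group):
        return "(" + " ".join(serialize(s) for s in node.steps) + ")"
    if isinstance(node, Step):
        return ",".join(serialize(a) for a in node.alternatives)
    if isinstance(node, PathwayAST):
        return " ".join(serialize(s) for s in node.steps)
    raise TypeError(type(node))


# ---------------------------------------------------------------------------
# geTMM


def _quantile_factor(mat: np.ndarray, lib: np.ndarray, q: float = 0.75) -> np.ndarray:
    return np.quantile(mat, q, axis=0) / lib


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     lib_obs: float, lib_ref: float,
                     trim_m: float, trim_a: float,
                     depth_weights: bool) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 0.0
    p_obs = obs[keep] / lib_obs
    p_ref = ref[keep] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if depth_weights:
        w = (1 - p_obs) / (lib_obs * p_obs) + (1 - p_ref) / (lib_ref * p_ref)
    else:
        # depth-free binomial-shape weights: keeps factors invariant to
        # rescaling any single sample's counts (composition invariance)
        w = (1 - p_obs) / p_obs + (1 - p_ref) / p_ref
    n = m.size
    if np.ptp(m) == 0:
        return float(m[0])
    # two-sided rank trimming, 30% of M and 5% of A by default
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    from scipy.stats import rankdata

    rm, ra = rankdata(m), rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep2.sum() == 0 or np.isclose(w[keep2].sum(), 0):
        return 0.0
    inv_w = 1.0 / w[keep2]
    return float((inv_w * m[keep2]).sum() / inv_w.sum())


def tmm_factors(mat: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05,
                ref_sample: int | None = None,
                depth_weights: bool = False) -> np.ndarray:
    """TMM scale factors for a gene x sample matrix, geometric mean 1.

    Reference = sample whose upper-quartile proportion is closest to the
    mean upper quartile (overridable).  Weights are the inverse of the
    asymptotic binomial variance of each M-value, in a depth-free form by
    default (``depth_weights=True`` restores the library-size-weighted
    variant).
    """
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("all-zero sample in count matrix")
    if ref_sample is None:
        f75 = _quantile_factor(mat, lib)
        ref_sample = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = mat[:, ref_sample]
    log_f = np.array([
        _tmm_pair_factor(mat[:, j], ref, lib[j], lib[ref_sample],
                         trim_m, trim_a, depth_weights)
        for j in range(mat.shape[1])
    ])
    f = 2.0 ** log_f
    return f / np.exp(np.mean(np.log(f)))


def getmm_normalize(counts: pd.DataFrame, catalog: GeneCatalog,
                    trim_m: float = 0.30, trim_a: float = 0.05,
                    ref_sample: int | None = None,
                    depth_weights: bool = False) -> pd.DataFrame:
    """geTMM: gene-length-corrected TMM-normalized expression per million.

    ``counts`` is gene x sample (rows indexed by gene_id).  RPK values
    (count / kilobase of gene) are scaled by effective library size
    (RPK library size x TMM factor) and reported per million.
    """
    lengths = catalog.lengths_for(list(counts.index)).to_numpy(dtype=float)
    rpk = counts.to_numpy(dtype=float) / (lengths[:, None] / 1000.0)
    factors = tmm_factors(rpk, trim_m=trim_m, trim_a=trim_a,
                          ref_sample=ref_sample, depth_weights=depth_weights)
    eff_lib = rpk.sum(axis=0) * factors
    out = rpk / eff_lib[None, :] * 1e6
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Aggregation


def ko_expression(normalized: pd.DataFrame, catalog: GeneCatalog,
                  mag_scope: set[str] | None = None) -> pd.DataFrame:
    """Sum normalized expression over genes sharing a KO.

    ``mag_scope`` restricts to genes of the given MAGs (empty set means
    no genes, hence an empty result).  Result is KO x sample.
    """
    cat = catalog.frame.set_index("gene_id")
    genes = [g for g in normalized.index if g in cat.index]
    cat = cat.loc[genes]
    mask = cat["ko"].notna() & (cat["ko"] != "")
    if mag_scope is not None:
        mask &= cat["mag_id"].isin(mag_scope)
    sub = normalized.loc[cat.index[mask]]
    kos = cat.loc[mask, "ko"]
    if sub.empty:
        return pd.DataFrame(columns=normalized.columns, dtype=float)
    return sub.groupby(kos.values).sum()


def score_pathway(ast: PathwayAST, ko_values: dict[str, float]) -> float:
    """Aggregate KO expression to a pathway score.

    Complex subunits are averaged, alternatives within a step are summed,
    and steps are averaged across the pathway; a KO absent from
    ``ko_values`` contributes 0.
    """

    def value(node) -> float:
        if isinstance(node, Leaf):
            return float(ko_values.get(node.ko, 0.0))
        if isinstance(node, Complex):
            return float(np.mean([value(m) for m in node.members]))
        if isinstance(node, Step):
            return float(sum(value(a) for a in node.alternatives))
        if isinstance(node, (Group, PathwayAST)):
            return float(np.mean([value(s) for s in node.steps]))
        raise TypeError(type(node))

    return value(ast)


def score_pathways_matrix(definitions: list[PathwayDefinition],
                          ko_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pathway x sample score matrix from a KO x sample expression matrix."""
    out = {}
    for d in definitions:
        ast = d.ast
        out[d.pathway_id] = [
            score_pathway(ast, ko_matrix[c].to_dict()) for c in ko_matrix.columns
        ]
    return pd.DataFrame(out, index=ko_matrix.columns).T


def pathway_timeseries(scores: pd.DataFrame, design: pd.DataFrame):
    """Replicate means, standard errors, and z-scored series per pathway.

    ``scores`` is pathway x sample; ``design`` maps sample_id to day.
    Returns ``(mean, sem, zscored)`` DataFrames, pathway x timepoint.
    The z-score uses the across-timepoint mean and n-1 standard deviation
    of the replicate means; constant series z-score to 0.
    """
    design = design.set_index("sample_id").loc[scores.columns]
    days = sorted(design["day"].unique())
    if len(days) < 2:
        raise ValueError("need at least 2 timepoints for a series")
    groups = {d: design.index[design["day"] == d] for d in days}
    mean = pd.DataFrame({
        d: scores[groups[d]].mean(axis=1) for d in days
    })
    sem = pd.DataFrame({
        d: scores[groups[d]].std(axis=1, ddof=1) / np.sqrt(len(groups[d]))
        for d in days
    })
    sd = mean.std(axis=1, ddof=1)
    centered = mean.sub(mean.mean(axis=1), axis=0)
    z = centered.div(sd.where(sd > 0, 1.0), axis=0)
    return mean, sem, z
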