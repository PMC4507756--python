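"""Hard-thresholded Pearson co-expression networks over guide genes.

The screen declares a correlation "positive" when the Pearson
product-moment coefficient exceeds ``r_min`` (default 0.65) AND its
two-tailed t-test P-value is below ``p_max`` (default 0.05). The t statistic
is t = r*sqrt(df)/sqrt(1-r^2) with df = n_obs - 2 by default; ``df_override``
replicates analyses that fixed the degrees of freedom a priori (e.g. 11 df
for 13 genotype observations). Note that at 11 df the two-tailed critical r
at P=0.05 is about 0.553, so r > 0.65 is the binding condition there.

Negative correlations are computed and reported but never form positive
edges. A zero-variance profile makes r undefined; such comparisons are
recorded as undefined (r = NaN) and excluded from edges rather than being
silently coerced to r = 0, which would corrupt degree counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, GuideGeneSet


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its t-test significance.

    ``defined`` is False when either input had zero variance; r, t and p are
    NaN in that case and the pair can never form an edge.
    """

    r: float
    t_stat: float
    df: int
    p_two_tailed: float
    n_obs: int
    defined: bool = True

    @property
    def undefined(self) -> bool:
        return not self.defined


@dataclass(frozen=True)
class NetworkConfig:
    """Thresholds and options for edge construction.

    transform "log2p1" correlates log2(RPKM+1) profiles instead of raw RPKM.
    """

    r_min: float = 0.65
    p_max: float = 0.05
    df_override: int | None = None
    transform: str = "none"

    def __post_init__(self) -> None:
        if not 0 < self.r_min < 1:
            raise ValueError(f"r_min must be in (0, 1), got {self.r_min}")
        if not 0 < self.p_max < 1:
            raise ValueError(f"p_max must be in (0, 1), got {self.p_max}")
        if self.df_override is not None and self.df_override < 1:
            raise ValueError("df_override must be a positive integer")
        if self.transform not in ("none", "log2p1"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def is_positive(self, result: CorrelationResult) -> bool:
        """Strict thresholds: r > r_min and P < p_max; ties excluded."""
        return (result.defined
                and result.r > self.r_min
                and result.p_two_tailed < self.p_max)


@dataclass(frozen=True)
class CorrelationEdge:
    gene_a: str
    gene_b: str
    result: CorrelationResult
    positive: bool

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge on {self.gene_a!r}")


@dataclass
class CorrelationNetwork:
    """Positive edges among ``nodes`` with per-node degree counts."""

    nodes: tuple[str, ...]
    edges: tuple[CorrelationEdge, ...]
    all_results: Mapping[frozenset, CorrelationResult] = field(default_factory=dict)
    config: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e.gene_a not in node_set or e.gene_b not in node_set:
                raise ValueError(f"edge {e.gene_a}-{e.gene_b} outside node set")

    @property
    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.gene_a] += 1
            deg[e.gene_b] += 1
        return deg

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _critical_t(p_max: float, df: int) -> float:
    return float(stats.t.ppf(1 - p_max / 2, df))


def critical_r(p_max: float = 0.05, df: int = 11) -> float:
    """Two-tailed critical |r| for the Pearson t-test at the given df.

    Solves |t| = t_crit for r: r = t / sqrt(t^2 + df).
    """
    t = _critical_t(p_max, df)
    return t / math.sqrt(t * t + df)


def pearson(x, y, df_override: int | None = None) -> CorrelationResult:
    """Pearson product-moment correlation with two-tailed t-test P-value.

    Returns an undefined result (NaN fields) when either vector has zero
    variance; raises on length mismatch or fewer than 3 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    df = int(df_override) if df_override is not None else n - 2
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0.0:
        return CorrelationResult(math.nan, math.nan, df, math.nan, n,
                                 defined=False)
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:
        # collinear up to rounding: limiting values, infinite t and P -> 0
        r = math.copysign(1.0, r)
        return CorrelationResult(r, math.copysign(math.inf, r), df, 0.0, n)
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(r, t, df, p, n)


def _maybe_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(values + 1.0)
    return values


def pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Correlation of every row of X against every row of Y (vectorised).

    Rows with zero variance yield NaN in their slots.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc ** 2).sum(axis=1))
    yn = np.sqrt((Yc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Yc.T) / np.outer(xn, yn)
    return np.clip(r, -1.0, 1.0)


def p_from_r(r: np.ndarray, df: int) -> np.ndarray:
    """Two-tailed t-test P-values for an array of Pearson coefficients."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, p)


def _pair_results(matrix: ExpressionMatrix, ids_a, ids_b, cfg: NetworkConfig):
    """CorrelationResult for each (a, b) id pair, vectorised over the matrix."""
    vals_a = _maybe_transform(matrix.data.loc[list(ids_a)].to_numpy(float),
                              cfg.transform)
    vals_b = _maybe_transform(matrix.data.loc[list(ids_b)].to_numpy(float),
                              cfg.transform)
    n = matrix.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    df = cfg.df_override if cfg.df_override is not None else n - 2
    r = pearson_rows(vals_a, vals_b)
    p = p_from_r(r, df)
    return r, p, df, n


def build_guide_network(matrix: ExpressionMatrix, guides: GuideGeneSet,
                        cfg: NetworkConfig | None = None) -> CorrelationNetwork:
    """Evaluate every unordered guide pair and keep positive edges.

    Nodes are pathway role labels; the degree map is the per-role count of
    positive correlations (the statistic behind the published pathway graph,
    e.g. the CHS1/CHS2/CHI hub degrees).
    """
    cfg = cfg or NetworkConfig()
    missing = [role for role, gid in guides.entries.items()
               if gid not in matrix.data.index]
    if missing:
        raise KeyError(f"guide genes missing from matrix for roles: {missing}")
    roles = guides.roles
    ids = [guides.entries[r] for r in roles]
    rmat, pmat, df, n = _pair_results(matrix, ids, ids, cfg)
    edges = []
    results: dict[frozenset, CorrelationResult] = {}
    for i in range(len(roles)):
        for j in range(i + 1, len(roles)):
            res = _result_from_cells(rmat[i, j], pmat[i, j], df, n)
            results[frozenset((roles[i], roles[j]))] = res
            if cfg.is_positive(res):
                edges.append(CorrelationEdge(roles[i], roles[j], res, True))
    return CorrelationNetwork(tuple(roles), tuple(edges), results, cfg)


def _result_from_cells(r: float, p: float, df: int, n: int) -> CorrelationResult:
    if np.isnan(r):
        return CorrelationResult(math.nan, math.nan, df, math.nan, n,
                                 defined=False)
    r = float(r)
    if abs(r) >= 1.0 - 1e-14:
        r = math.copysign(1.0, r)
        return CorrelationResult(r, math.copysign(math.inf, r), df, 0.0, n)
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return CorrelationResult(r, t, df, float(p), n)


def correlate_to_guides(matrix: ExpressionMatrix, guides: GuideGeneSet,
                        gene: str, cfg: NetworkConfig | None = None
                        ) -> dict[str, CorrelationEdge]:
    """Correlate one gene against every guide role.

    Returns a role -> edge map with positivity flags; the per-candidate row
    behind the published per-guide coefficient tables.
    """
    cfg = cfg or NetworkConfig()
    if gene not in matrix.data.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    missing = [role for role, gid in guides.entries.items()
               if gid not in matrix.data.index]
    if missing:
        raise KeyError(f"guide genes missing from matrix for roles: {missing}")
    roles = guides.roles
    ids = [guides.entries[r] for r in roles]
    rmat, pmat, df, n = _pair_results(matrix, [gene], ids, cfg)
    out: dict[str, CorrelationEdge] = {}
    for j, role in enumerate(roles):
        res = _result_from_cells(rmat[0, j], pmat[0, j], df, n)
        out[role] = CorrelationEdge(gene, guides.entries[role], res,
                                    cfg.is_positive(res))
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted P-values (optional multiplicity control across a pair set;
    never applied in replication mode, which uses raw per-pair P-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    if mask.any():
        adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj
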