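"""Expressed-gene filtering, fold-change DEG counting and genotype clustering.

A transcript counts as expressed in a sample when its RPKM is strictly
greater than the threshold (default 0.5). A gene is differentially expressed
between two genotypes when the RPKM ratio strictly exceeds the fold
threshold (default 2) in either direction; genes expressed in neither
compared sample are excluded before counting, which removes 0/0 ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Expression filter: strict RPKM > rpkm_min.

    scope "per_sample" reports per-sample expressed-gene tallies without
    dropping genes; "any_sample" keeps genes expressed in at least one sample.
    """

    rpkm_min: float = 0.5
    scope: str = "per_sample"

    def __post_init__(self) -> None:
        if self.rpkm_min < 0:
            raise ValueError("rpkm_min must be >= 0")
        if self.scope not in ("per_sample", "any_sample"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class DEGCounts:
    """Per-pair differential-expression tallies.

    n_up counts genes with query/comparator ratio > fold_threshold; n_down
    the reciprocal. By construction n_up(A, B) == n_down(B, A) on the same
    gene universe.
    """

    query_sample: str
    comparator_sample: str
    n_up: int
    n_down: int
    fold_threshold: float
    n_genes_considered: int


@dataclass
class GenotypeDendrogram:
    """Agglomerative merge tree over the samples.

    ``linkage_matrix`` is in scipy hierarchical-clustering form; ``leaves``
    are sample IDs in matrix order.
    """

    leaves: tuple[str, ...]
    linkage_matrix: np.ndarray
    metric: str
    linkage_method: str

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix,
                                            list(self.leaves))
        return str(tree)

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def filter_expressed(matrix: ExpressionMatrix,
                     cfg: FilterConfig | None = None
                     ) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Apply the expressed-transcript filter.

    Returns the (possibly reduced) matrix and per-sample expressed-gene
    counts — the "number of expressed genes" statistic reported per genotype.
    Strict inequality: a gene sitting exactly at the threshold is not counted.
    """
    cfg = cfg or FilterConfig()
    expressed = matrix.data.to_numpy() > cfg.rpkm_min
    counts = {s: int(c) for s, c in
              zip(matrix.sample_ids, expressed.sum(axis=0))}
    if cfg.scope == "any_sample":
        keep = expressed.any(axis=1)
        out = ExpressionMatrix(matrix.data.loc[keep].copy(),
                               dict(matrix.sample_roles))
    else:
        out = matrix
    return out, counts


def count_deg(matrix: ExpressionMatrix, query: str, comparator: str,
              fold: float = 2.0, pseudocount: float = 0.0,
              filter_cfg: FilterConfig | None = None) -> DEGCounts:
    """Count genes >fold-fold up/down in ``query`` versus ``comparator``.

    With pseudocount 0, q > 0 against c = 0 is an infinite ratio and counts
    as up (and symmetrically for down); a positive pseudocount regularises
    both ratios. Genes expressed in neither sample are excluded first.
    """
    if query == comparator:
        raise ValueError("query and comparator must differ")
    if fold <= 1:
        raise ValueError(f"fold threshold must be > 1, got {fold}")
    for s in (query, comparator):
        if s not in matrix.data.columns:
            raise KeyError(f"sample {s!r} not in matrix")
    cfg = filter_cfg or FilterConfig()
    q = matrix.data[query].to_numpy(dtype=float)
    c = matrix.data[comparator].to_numpy(dtype=float)
    considered = (q > cfg.rpkm_min) | (c > cfg.rpkm_min)
    q = q[considered] + pseudocount
    c = c[considered] + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        up = (q > fold * c) & (q > 0)
        down = (c > fold * q) & (c > 0)
    if pseudocount == 0:
        logger.debug("count_deg: pseudocount 0, zero denominators count as "
                     "infinite ratios")
    return DEGCounts(query, comparator, int(up.sum()), int(down.sum()),
                     fold, int(considered.sum()))


def cluster_genotypes(matrix: ExpressionMatrix,
                      metric: str = "correlation",
                      linkage_method: str = "average") -> GenotypeDendrogram:
    """Hierarchically cluster samples by expression profile.

    metric "correlation" is 1 - Pearson r on log2(RPKM+1) profiles;
    "euclidean_log" is Euclidean distance on the same transform. Default
    average linkage. Deterministic given metric and linkage.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    if metric not in ("correlation", "euclidean_log"):
        raise ValueError(f"unknown metric {metric!r}")
    if linkage_method not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    profiles = np.log2(matrix.data.to_numpy(dtype=float).T + 1.0)
    if metric == "correlation":
        dists = pdist(profiles, metric="correlation")
        # numerical noise can push identical profiles to ~1e-16 below zero
        dists = np.clip(dists, 0.0, None)
    else:
        dists = pdist(profiles, metric="euclidean")
    z = linkage(dists, method=linkage_method)
    return GenotypeDendrogram(tuple(matrix.sample_ids), z, metric,
                              linkage_method)
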