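"""Guilt-by-association screening of candidate genes against guide genes.

Each candidate is correlated against every guide role; candidates with at
least ``min_links`` positive correlations (r > r_min AND P < p_max) are
retained. Guide isoforms count separately (PAL1 and PAL2 are distinct
roles), so the maximum attainable link count equals the number of roles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CandidateList, ExpressionMatrix, GuideGeneSet
from .network import NetworkConfig, _maybe_transform, p_from_r, pearson_rows

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    min_links: int = 4
    network_cfg: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if self.min_links < 1:
            raise ValueError("min_links must be >= 1")


@dataclass(frozen=True)
class CandidateRecord:
    """One retained candidate: its link count, the linked roles with their
    coefficients, and the gene's RPKM range across all samples."""

    gene_id: str
    n_positive_links: int
    linked_roles: Mapping[str, float]
    rpkm_max: float
    rpkm_min: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.n_positive_links != len(self.linked_roles):
            raise ValueError("n_positive_links must equal |linked_roles|")
        if not (self.rpkm_max >= self.rpkm_min >= 0):
            raise ValueError("need rpkm_max >= rpkm_min >= 0")


def screen_candidates(matrix: ExpressionMatrix, guides: GuideGeneSet,
                      candidates: CandidateList,
                      cfg: ScreenConfig | None = None
                      ) -> tuple[list[CandidateRecord], pd.DataFrame]:
    """Screen every candidate against the guide set.

    Returns the retained records, sorted by descending link count then
    gene ID, plus the full candidate x role correlation table (all
    candidates, unfiltered) as a side artifact. Candidates absent from the
    matrix are skipped with a logged count; a candidate overlapping the
    guide set is an error.
    """
    cfg = cfg or ScreenConfig()
    if len(guides) == 0:
        raise ValueError("guide set is empty")
    if cfg.min_links > len(guides):
        raise ValueError(
            f"min_links={cfg.min_links} exceeds number of guide roles "
            f"({len(guides)})")
    candidates.check_disjoint(guides)
    missing_guides = [r for r, g in guides.entries.items()
                      if g not in matrix.data.index]
    if missing_guides:
        raise KeyError(f"guide genes missing from matrix: {missing_guides}")
    present = [g for g in candidates.gene_ids if g in matrix.data.index]
    n_skipped = len(candidates.gene_ids) - len(present)
    if n_skipped:
        logger.warning("screen: skipped %d candidates absent from matrix",
                       n_skipped)
    roles = guides.roles
    guide_ids = [guides.entries[r] for r in roles]
    ncfg = cfg.network_cfg
    if not present:
        empty = pd.DataFrame(columns=roles)
        return [], empty
    cand_vals = _maybe_transform(
        matrix.data.loc[present].to_numpy(float), ncfg.transform)
    guide_vals = _maybe_transform(
        matrix.data.loc[guide_ids].to_numpy(float), ncfg.transform)
    n = matrix.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples")
    df = ncfg.df_override if ncfg.df_override is not None else n - 2
    r = pearson_rows(cand_vals, guide_vals)
    p = p_from_r(r, df)
    positive = np.nan_to_num(r, nan=-2.0) > ncfg.r_min
    positive &= np.nan_to_num(p, nan=2.0) < ncfg.p_max
    link_table = pd.DataFrame(r, index=present, columns=roles)
    raw_rpkm = matrix.data.loc[present].to_numpy(float)
    records = []
    for i, gid in enumerate(present):
        n_links = int(positive[i].sum())
        if n_links < cfg.min_links:
            continue
        linked = {roles[j]: float(r[i, j])
                  for j in range(len(roles)) if positive[i, j]}
        records.append(CandidateRecord(
            gene_id=gid,
            n_positive_links=n_links,
            linked_roles=linked,
            rpkm_max=float(raw_rpkm[i].max()),
            rpkm_min=float(raw_rpkm[i].min()),
            description=candidates.descriptions.get(gid, ""),
        ))
    records.sort(key=lambda rec: (-rec.n_positive_links, rec.gene_id))
    return records, link_table


def count_positive_links(row: Mapping[str, float | None],
                         cfg: ScreenConfig | None = None) -> int:
    """Count positive links from a role -> coefficient map.

    Absent entries (None/NaN) do not count. Printed coefficient tables carry
    only entries that already passed the significance filter, so positivity
    here reduces to r > r_min (at 11 df the critical r for two-tailed
    P = 0.05 is ~0.553 < 0.65, making the r threshold binding).
    """
    cfg = cfg or ScreenConfig()
    r_min = cfg.network_cfg.r_min
    n = 0
    for role, value in row.items():
        if value is None:
            continue
        v = float(value)
        if np.isnan(v):
            continue
        if not -1.0 <= v <= 1.0:
            raise ValueError(
                f"correlation for role {role!r} outside [-1, 1]: {v}")
        if v > r_min:
            n += 1
    return n
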