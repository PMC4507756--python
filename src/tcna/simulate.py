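"""Synthetic inputs with the statistical structure the screen assumes.

Expression is generated on a latent log scale: each gene's log-RPKM is a
standard normal scaled by (mu, sigma) and exponentiated, so RPKM marginals
are log-normal and Pearson correlation on the latent scale is free of the
marginal skew. The guide module shares a single latent factor giving an
equicorrelated block; planted TF candidates mix the latent factors of their
linked guides; background genes are independent. The truth record carries
the latent-scale correlations; the RPKM-scale correlation they induce is
validated empirically in tests, not assumed equal.

Planted-TF construction: for a TF tracking guide subset S at target latent
correlation rho, let m be the mean of the linked guides' latents and
u = m / sd(m). The TF latent is w*u + sqrt(1-w^2)*eps with w chosen so the
mean correlation over S equals rho (exactly rho when the linked guides are
exchangeable). With mutually independent linked guides the attainable rho
is capped at 1/sqrt(|S|) (sum of squared correlations with orthogonal
variables cannot exceed 1); an unattainable target is rejected before
sampling as an infeasible correlation structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (CANONICAL_GUIDE_ROLES, CandidateList, ExpressionMatrix,
                 GuideGeneSet)
from .qpcr import CtTable

#: Roles outside the co-regulated ripening module: the tannin branch
#: (LAR, ANR), the flavonol branch (FLS) and F3pH behave independently.
DEFAULT_INDEPENDENT_ROLES = ("LAR", "ANR", "FLS", "F3pH")


@dataclass(frozen=True)
class PlantedTF:
    """A planted candidate: the guide roles it tracks and the target
    latent-scale correlation to each."""

    linked_roles: tuple[str, ...]
    rho: float = 0.9


def _default_planted() -> tuple[PlantedTF, ...]:
    return (
        PlantedTF(("PAL2", "4CL", "CHS1", "CHS2", "F3H"), 0.9),
        PlantedTF(("PAL1", "PAL2", "C4H", "4CL", "CHS1", "CHS2"), 0.9),
        PlantedTF(("PAL2", "CHI", "CHS1", "CHS2", "F3H"), 0.9),
    )


@dataclass(frozen=True)
class PopulationSimConfig:
    """Segregating-population RPKM simulation parameters.

    Defaults mirror a two-parent cross profiled at ripeness: 16 samples
    (2 parents + 14 progeny), 15 guide roles of which the non-tannin/
    non-flavonol ones form one correlated module, 3 planted TFs and enough
    background genes to total 1897 candidates.
    """

    n_samples: int = 16
    guide_module_rho: float = 0.8
    independent_roles: tuple[str, ...] = DEFAULT_INDEPENDENT_ROLES
    planted_tfs: tuple[PlantedTF, ...] = field(default_factory=_default_planted)
    n_background: int = 1894
    log_rpkm_mu: float = 3.0
    log_rpkm_sigma: float = 1.0
    dropout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need n_samples >= 4")
        if not -1 < self.guide_module_rho < 1:
            raise ValueError("guide_module_rho must be in (-1, 1)")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")
        unknown = set(self.independent_roles) - set(CANONICAL_GUIDE_ROLES)
        if unknown:
            raise ValueError(f"unknown roles: {sorted(unknown)}")
        for tf in self.planted_tfs:
            if not 0 < tf.rho < 1:
                raise ValueError("planted rho must be in (0, 1)")
            unknown = set(tf.linked_roles) - set(CANONICAL_GUIDE_ROLES)
            if unknown:
                raise ValueError(f"planted TF links unknown roles: "
                                 f"{sorted(unknown)}")


@dataclass(frozen=True)
class PopulationTruth:
    """Ground truth of a simulated population."""

    guides: GuideGeneSet
    module_roles: tuple[str, ...]
    planted_tf_ids: tuple[str, ...]
    planted_links: Mapping[str, tuple[str, ...]]
    planted_rho: Mapping[str, float]
    background_ids: tuple[str, ...]
    dropout_ids: tuple[str, ...]
    candidates: CandidateList


def _guide_latent_cov(roles: Sequence[str], module: set, rho: float
                      ) -> np.ndarray:
    k = len(roles)
    cov = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if roles[i] in module and roles[j] in module:
                cov[i, j] = cov[j, i] = rho
    return cov


def _mixing_weight(cov: np.ndarray, idx: Sequence[int], rho: float) -> float:
    """Weight w for tf = w*u_S + sqrt(1-w^2)*eps hitting mean corr rho on S."""
    sub = cov[np.ix_(idx, idx)]
    var_m = float(sub.mean())
    cov_m = sub.mean(axis=0)  # cov(mean latent, each linked guide)
    sd_m = math.sqrt(var_m)
    w = rho * sd_m / float(cov_m.mean())
    if not 0 < w <= 1:
        raise ValueError(
            f"infeasible planted correlation rho={rho} for links "
            f"{list(idx)}: required mixing weight {w:.3f} outside (0, 1]; "
            "the implied correlation matrix is not positive semi-definite")
    return w


def simulate_population(cfg: PopulationSimConfig | None = None
                        ) -> tuple[ExpressionMatrix, PopulationTruth]:
    """Draw one RPKM matrix plus its ground-truth planted structure.

    Fully deterministic given ``cfg.seed``; the same config yields
    bit-identical matrices.
    """
    cfg = cfg or PopulationSimConfig()
    rng = np.random.default_rng(cfg.seed)
    roles = list(CANONICAL_GUIDE_ROLES)
    module = set(roles) - set(cfg.independent_roles)
    n = cfg.n_samples
    rho = cfg.guide_module_rho

    # feasibility first: reject before drawing anything
    cov = _guide_latent_cov(roles, module, rho)
    weights = []
    for tf in cfg.planted_tfs:
        idx = [roles.index(r) for r in tf.linked_roles]
        weights.append(_mixing_weight(cov, idx, tf.rho))

    # guide latents via a shared module factor (equicorrelation rho)
    factor = rng.standard_normal(n)
    guide_z = np.empty((len(roles), n))
    srho = math.sqrt(max(rho, 0.0))
    for i, role in enumerate(roles):
        noise = rng.standard_normal(n)
        if role in module and rho > 0:
            guide_z[i] = srho * factor + math.sqrt(1 - rho) * noise
        else:
            guide_z[i] = noise

    # planted TFs mix their linked guides' latents
    tf_z = np.empty((len(cfg.planted_tfs), n))
    for t, tf in enumerate(cfg.planted_tfs):
        idx = [roles.index(r) for r in tf.linked_roles]
        m = guide_z[idx].mean(axis=0)
        sd_m = math.sqrt(float(cov[np.ix_(idx, idx)].mean()))
        u = m / sd_m
        w = weights[t]
        tf_z[t] = w * u + math.sqrt(1 - w * w) * rng.standard_normal(n)

    bg_z = rng.standard_normal((cfg.n_background, n))

    z = np.vstack([guide_z, tf_z, bg_z])
    rpkm = np.exp(cfg.log_rpkm_mu + cfg.log_rpkm_sigma * z)

    n_guides = len(roles)
    n_tf = len(cfg.planted_tfs)
    gene_ids = ([f"gene{i:05d}" for i in range(1, n_guides + 1)]
                + [f"gene{i:05d}" for i in range(10001, 10001 + n_tf)]
                + [f"gene{i:05d}" for i in range(20001, 20001 + cfg.n_background)])
    bg_ids = gene_ids[n_guides + n_tf:]

    # dropout: push a Bernoulli(dropout_fraction) subset of background genes
    # entirely below the 0.5 RPKM expressed threshold
    dropout_ids: list[str] = []
    if cfg.dropout_fraction > 0 and cfg.n_background:
        drop = rng.random(cfg.n_background) < cfg.dropout_fraction
        for k in np.flatnonzero(drop):
            row = n_guides + n_tf + k
            rpkm[row] *= 0.45 / rpkm[row].max()
            dropout_ids.append(bg_ids[k])

    sample_ids = (["parent_A", "parent_B"]
                  + [f"progeny_{i:02d}" for i in range(1, n - 1)])
    roles_map = {s: ("parent" if s.startswith("parent") else "progeny")
                 for s in sample_ids}
    matrix = ExpressionMatrix(
        pd.DataFrame(rpkm, index=gene_ids, columns=sample_ids), roles_map)

    guides = GuideGeneSet(dict(zip(roles, gene_ids[:n_guides])))
    tf_ids = tuple(gene_ids[n_guides:n_guides + n_tf])
    candidates = CandidateList(tf_ids + tuple(bg_ids))
    truth = PopulationTruth(
        guides=guides,
        module_roles=tuple(r for r in roles if r in module),
        planted_tf_ids=tf_ids,
        planted_links={gid: tf.linked_roles
                       for gid, tf in zip(tf_ids, cfg.planted_tfs)},
        planted_rho={gid: tf.rho
                     for gid, tf in zip(tf_ids, cfg.planted_tfs)},
        background_ids=tuple(bg_ids),
        dropout_ids=tuple(dropout_ids),
        candidates=candidates,
    )
    return matrix, truth


@dataclass(frozen=True)
class QpcrSimConfig:
    """Ct-table simulation under known fold changes.

    Ct = baseline - log2(relative abundance) + N(0, ct_noise_sd) per
    replicate; the reference gene sits at relative abundance 1 everywhere,
    so a perfect assay recovers the configured folds exactly at zero noise.
    """

    true_fold_changes: Mapping[str, float] = field(
        default_factory=lambda: {"target": 16.0})
    ct_noise_sd: float = 0.2
    n_replicates: int = 3
    n_treatment: int = 3
    n_control: int = 3
    reference_baseline_ct: float = 18.0
    target_baseline_ct: float = 24.0
    reference_gene: str = "reference"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.true_fold_changes.values()):
            raise ValueError("true fold changes must be > 0")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if min(self.n_replicates, self.n_treatment, self.n_control) < 1:
            raise ValueError("replicate and sample counts must be >= 1")
        if self.reference_gene in self.true_fold_changes:
            raise ValueError("reference gene cannot be a target")


def simulate_qpcr(cfg: QpcrSimConfig | None = None) -> CtTable:
    """Draw a replicate Ct table under the configured true fold changes."""
    cfg = cfg or QpcrSimConfig()
    rng = np.random.default_rng(cfg.seed)
    samples = ([f"treated_{i:02d}" for i in range(1, cfg.n_treatment + 1)]
               + [f"control_{i:02d}" for i in range(1, cfg.n_control + 1)])
    group = {s: ("treatment" if s.startswith("treated") else "control")
             for s in samples}
    rows = []
    for s in samples:
        treated = group[s] == "treatment"
        for gene, fold in cfg.true_fold_changes.items():
            abundance = fold if treated else 1.0
            base = cfg.target_baseline_ct - math.log2(abundance)
            for rep in range(1, cfg.n_replicates + 1):
                ct = base + rng.normal(0.0, cfg.ct_noise_sd)
                rows.append((s, gene, rep, ct))
        for rep in range(1, cfg.n_replicates + 1):
            ct = cfg.reference_baseline_ct + rng.normal(0.0, cfg.ct_noise_sd)
            rows.append((s, cfg.reference_gene, rep, ct))
    records = pd.DataFrame(rows,
                           columns=["sample_id", "gene_id", "replicate", "ct"])
    return CtTable(records, group, cfg.reference_gene)
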