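"""Relative quantification of qPCR Ct tables by the Livak 2^-ddCt method.

dCt = mean target Ct - mean reference Ct within a sample (replicates are
averaged on the Ct scale first); ddCt = dCt(treatment sample) - mean dCt
over all control samples; fold change = 2^(-ddCt). Replicate dispersion is
propagated to the dCt scale as sqrt(sd_target^2 + sd_ref^2). Primer
efficiency comes from the slope of Ct on log10 dilution of a template
serial dilution; efficiency estimates are reported but do not correct fold
changes unless the Pfaffl mode is requested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CtTable:
    """Long-format Ct records with group labels and a reference gene.

    ``records`` columns: sample_id, gene_id, replicate, ct. ``group`` maps
    sample_id -> "treatment" | "control". The reference gene must be
    measured in every sample.
    """

    records: pd.DataFrame
    group: Mapping[str, str]
    reference_gene: str

    def __post_init__(self) -> None:
        req = {"sample_id", "gene_id", "replicate", "ct"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.records["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("Ct values must be finite and > 0")
        samples = set(self.records["sample_id"])
        ref_samples = set(
            self.records.loc[self.records["gene_id"] == self.reference_gene,
                             "sample_id"])
        if samples - ref_samples:
            raise ValueError(
                f"reference gene {self.reference_gene!r} unmeasured in "
                f"samples: {sorted(samples - ref_samples)}")
        for s in samples:
            if s not in self.group:
                raise ValueError(f"sample {s!r} has no group label")

    def mean_ct(self, sample_id: str, gene_id: str) -> tuple[float, float, int]:
        """(mean, sd, n) of replicate Cts for one (sample, gene)."""
        mask = ((self.records["sample_id"] == sample_id)
                & (self.records["gene_id"] == gene_id))
        cts = self.records.loc[mask, "ct"].to_numpy(dtype=float)
        if cts.size == 0:
            raise KeyError(f"no Ct for sample {sample_id!r}, gene {gene_id!r}")
        sd = float(cts.std(ddof=1)) if cts.size > 1 else 0.0
        return float(cts.mean()), sd, int(cts.size)

    def samples_in(self, group: str) -> list[str]:
        ordered = list(dict.fromkeys(self.records["sample_id"]))
        return [s for s in ordered if self.group[s] == group]


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    sample_id: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    sd: float
    p_value: float | None = None


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Amplification efficiency from a standard-curve regression.

    efficiency = 10^(-1/slope) - 1; perfect per-cycle doubling gives slope
    -1/log10(2) ~ -3.32 and efficiency 1.0 (100%).
    """

    gene_id: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float


def read_ct_table(path: str | Path, group_path: str | Path,
                  reference_gene: str, sep: str = "\t") -> CtTable:
    """Read a (sample, gene, replicate, ct) TSV plus a (sample, group) TSV."""
    records = pd.read_csv(path, sep=sep,
                          names=["sample_id", "gene_id", "replicate", "ct"],
                          header=0)
    gm = pd.read_csv(group_path, sep=sep, header=None, dtype=str)
    group = dict(zip(gm[0], gm[1]))
    return CtTable(records, group, reference_gene)


def write_ct_table(table: CtTable, path: str | Path,
                   group_path: str | Path | None = None) -> None:
    table.records.to_csv(path, sep="\t", index=False, float_format="%.12g")
    if group_path is not None:
        with Path(group_path).open("w", encoding="utf-8") as fh:
            for s, g in table.group.items():
                fh.write(f"{s}\t{g}\n")


def delta_delta_ct(table: CtTable, target: str,
                   efficiency: EfficiencyEstimate | None = None
                   ) -> list[FoldChangeResult]:
    """2^-ddCt fold change of ``target`` for every treatment sample.

    The baseline is the mean dCt over all control samples. With an
    ``efficiency`` estimate given, the Pfaffl-style base (1 + E) replaces 2
    for the target ratio; by default quantification is pure 2^-ddCt.
    """
    controls = table.samples_in("control")
    treatments = table.samples_in("treatment")
    if not controls:
        raise ValueError("no control samples in group map")
    if not treatments:
        raise ValueError("no treatment samples in group map")
    if len(controls) == 1:
        logger.warning("single control sample; baseline dCt has no "
                       "between-sample dispersion")

    def dct(sample: str) -> tuple[float, float]:
        t_mean, t_sd, _ = table.mean_ct(sample, target)
        r_mean, r_sd, _ = table.mean_ct(sample, table.reference_gene)
        return t_mean - r_mean, math.sqrt(t_sd ** 2 + r_sd ** 2)

    control_dcts = [dct(s)[0] for s in controls]
    baseline = float(np.mean(control_dcts))
    base = 2.0 if efficiency is None else 1.0 + efficiency.efficiency
    out = []
    for s in treatments:
        d, sd = dct(s)
        ddct = d - baseline
        out.append(FoldChangeResult(
            gene_id=target, sample_id=s, delta_ct=d, delta_delta_ct=ddct,
            fold_change=float(base ** (-ddct)), sd=sd))
    return out


def control_fold_changes(table: CtTable, target: str) -> list[FoldChangeResult]:
    """Per-control-sample fold changes against the same pooled baseline
    (useful as the comparison group for significance tests)."""
    controls = table.samples_in("control")
    baseline = float(np.mean([
        table.mean_ct(s, target)[0] - table.mean_ct(s, table.reference_gene)[0]
        for s in controls]))
    out = []
    for s in controls:
        t_mean, t_sd, _ = table.mean_ct(s, target)
        r_mean, r_sd, _ = table.mean_ct(s, table.reference_gene)
        d = t_mean - r_mean
        out.append(FoldChangeResult(
            gene_id=target, sample_id=s, delta_ct=d,
            delta_delta_ct=d - baseline, fold_change=2.0 ** -(d - baseline),
            sd=math.sqrt(t_sd ** 2 + r_sd ** 2)))
    return out


def group_significance(groups: Sequence[Sequence[float]],
                       method: str = "t_test") -> tuple[float, bool]:
    """Significance of relative-abundance differences between groups.

    "t_test": two-sided Welch t-test between exactly two groups (treatment
    fruits versus controls). "anova": one-way ANOVA across >= 3 groups
    (e.g. developmental stages). Returns (p, degenerate); degenerate flags
    all-identical inputs, for which p is reported as the limiting value 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    flat = np.concatenate(arrays)
    if np.allclose(flat, flat[0]):
        return 1.0, True
    if method == "t_test":
        if len(arrays) != 2:
            raise ValueError("t_test compares exactly 2 groups")
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
    elif method == "anova":
        if len(arrays) < 3:
            raise ValueError("anova needs >= 3 groups")
        stat, p = stats.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown method {method!r}")
    if math.isnan(p):
        # zero within-group variance with differing means: perfect separation
        return 0.0, True
    return float(p), False


def primer_efficiency(dilution_series: Sequence[tuple[float, float]],
                      gene_id: str = "") -> EfficiencyEstimate:
    """Estimate amplification efficiency from (log10 dilution, Ct) points.

    Least-squares regression of Ct on log10 dilution; needs >= 3 points with
    non-degenerate dilutions.
    """
    pts = np.asarray(dilution_series, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (log10_dilution, ct) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("dilution series has zero variance")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("flat standard curve: slope is zero")
    eff = 10.0 ** (-1.0 / res.slope) - 1.0
    return EfficiencyEstimate(gene_id=gene_id, slope=float(res.slope),
                              intercept=float(res.intercept),
                              efficiency=float(eff),
                              r_squared=float(res.rvalue ** 2))
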