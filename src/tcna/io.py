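"""Readers and writers for the tabular formats every pipeline stage touches.

All files are plain text. The canonical dialect is tab-separated UTF-8 with
'.' decimal; comma-separated input is accepted behind ``sep=","``. Gene and
sample identifiers are opaque strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The fifteen flavonoid-pathway roles used as guide genes, in pathway order.
#: F3pH is flavonoid 3'-hydroxylase (the ' is not filesystem-safe).
CANONICAL_GUIDE_ROLES = (
    "PAL1", "PAL2", "C4H", "4CL", "CHS1", "CHS2", "CHI", "F3H",
    "F3pH", "FLS", "DFR", "LAR", "ANR", "ANS", "UFGT",
)

#: Pathway branch each role commits to. Upstream phenylpropanoid and core
#: flavonoid steps are shared ("general"); DFR/ANS/UFGT are anthocyanin-
#: specific, LAR/ANR tannin-specific and FLS flavonol-specific.
DEFAULT_BRANCHES: Mapping[str, str] = {
    "PAL1": "general", "PAL2": "general", "C4H": "general", "4CL": "general",
    "CHS1": "general", "CHS2": "general", "CHI": "general", "F3H": "general",
    "F3pH": "general",
    "DFR": "anthocyanin", "ANS": "anthocyanin", "UFGT": "anthocyanin",
    "LAR": "tannin", "ANR": "tannin",
    "FLS": "flavonol",
}

VALID_ROLES = frozenset(("parent", "progeny", "unspecified"))


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


@dataclass
class ExpressionMatrix:
    """A gene x sample RPKM table with per-sample population roles.

    ``data`` holds genes as rows and samples as columns; values are
    non-negative finite RPKM. ``sample_roles`` maps each sample to
    ``parent``, ``progeny`` or ``unspecified``.
    """

    data: pd.DataFrame
    sample_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        if arr.size and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative RPKM at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        for s, role in self.sample_roles.items():
            if role not in VALID_ROLES:
                raise FormatError(f"invalid role {role!r} for sample {s!r}")
        for s in df.columns:
            self.sample_roles.setdefault(str(s), "unspecified")
        df.index.name = "gene_id"
        df.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def profile(self, gene_id: str) -> np.ndarray:
        """RPKM vector of one gene across samples, in column order."""
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)].copy(),
                                dict(self.sample_roles))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (self.data.equals(other.data)
                and self.sample_roles == other.sample_roles)


@dataclass(frozen=True)
class GuideGeneSet:
    """Map from pathway role (PAL1 ... UFGT) to the gene ID filling it."""

    entries: Mapping[str, str]
    branch: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_BRANCHES))
    nonstandard_roles: frozenset = frozenset()

    def __post_init__(self) -> None:
        ids = list(self.entries.values())
        if len(set(ids)) != len(ids):
            raise FormatError("guide gene IDs must be unique across roles")

    @property
    def roles(self) -> list[str]:
        return list(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CandidateList:
    """Candidate gene IDs to screen (e.g. annotated TF homologues)."""

    gene_ids: tuple[str, ...]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("candidate gene IDs must be unique")

    def check_disjoint(self, guides: GuideGeneSet) -> None:
        overlap = set(self.gene_ids) & set(guides.gene_ids)
        if overlap:
            raise FormatError(
                f"candidates overlap guide genes: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_expression_matrix(
    path: str | Path,
    role_map: str | Path | None = None,
    sep: str = "\t",
    drop_missing: bool = False,
) -> ExpressionMatrix:
    """Load a gene x sample RPKM TSV (header = sample IDs, first column = genes).

    Missing cells ('' or NA) are a hard error unless ``drop_missing`` is set,
    in which case genes with any missing value are dropped and the count is
    logged — Pearson correlation downstream needs complete vectors.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str},
                     float_precision="round_trip")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            gene = df.index[newly_bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        if drop_missing:
            n_before = len(df)
            df = df.dropna(axis=0)
            logger.warning("%s: dropped %d genes with missing values",
                           path, n_before - len(df))
        else:
            gene = df.index[df.isna().any(axis=1).to_numpy().argmax()]
            raise FormatError(
                f"{path}: missing value in gene {gene!r} "
                "(pass drop_missing=True to discard incomplete genes)")
    roles: dict[str, str] = {}
    if role_map is not None:
        rm = pd.read_csv(role_map, sep=sep, header=None, dtype=str)
        roles = dict(zip(rm[0], rm[1]))
    return ExpressionMatrix(df.astype(float), roles)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            sep: str = "\t") -> None:
    """Write the matrix in the same dialect ``read_expression_matrix`` reads.

    Uses repr-precision floats so a round-trip preserves values exactly.
    """
    matrix.data.to_csv(path, sep=sep, index_label="gene_id",
                       float_format="%.17g")


def read_gene_list(
    path: str | Path,
    kind: str = "candidate",
    sep: str = "\t",
    matrix: ExpressionMatrix | None = None,
) -> GuideGeneSet | CandidateList:
    """Read a gene list TSV.

    For ``kind="guide"`` the file has two columns (role, gene_id); roles are
    validated against the 15 canonical pathway labels, extra roles are kept
    and flagged. For ``kind="candidate"`` the file has one or two columns
    (gene_id[, description]). With ``matrix`` given, IDs absent from the
    matrix are a hard error (cross-validation).
    """
    path = Path(path)
    if kind not in ("guide", "candidate"):
        raise ValueError(f"kind must be 'guide' or 'candidate', got {kind!r}")
    if path.stat().st_size == 0:
        if kind == "candidate":
            return CandidateList(())
        raise FormatError(f"{path}: empty guide file")
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if kind == "guide":
        if df.shape[1] < 2:
            raise FormatError(f"{path}: guide file needs (role, gene_id) columns")
        roles = df[0].tolist()
        dup_roles = {r for r in roles if roles.count(r) > 1}
        if dup_roles:
            raise FormatError(f"{path}: duplicate roles {sorted(dup_roles)}")
        entries = dict(zip(df[0], df[1]))
        extra = frozenset(entries) - frozenset(CANONICAL_GUIDE_ROLES)
        if extra:
            logger.warning("%s: non-canonical guide roles %s", path, sorted(extra))
        result: GuideGeneSet | CandidateList = GuideGeneSet(
            entries, nonstandard_roles=extra)
        ids: Iterable[str] = entries.values()
    else:
        ids = tuple(df[0])
        descriptions = (dict(zip(df[0], df[1].fillna("")))
                        if df.shape[1] > 1 else {})
        result = CandidateList(tuple(ids), descriptions)
    if matrix is not None:
        missing = sorted(set(ids) - set(matrix.gene_ids))
        if missing:
            raise FormatError(f"{path}: gene IDs absent from matrix: {missing}")
    return result


def write_gene_list(obj: GuideGeneSet | CandidateList, path: str | Path,
                    sep: str = "\t") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if isinstance(obj, GuideGeneSet):
            for role, gid in obj.entries.items():
                fh.write(f"{role}{sep}{gid}\n")
        else:
            for gid in obj.gene_ids:
                desc = obj.descriptions.get(gid, "")
                fh.write(f"{gid}{sep}{desc}\n" if desc else f"{gid}\n")


def write_edge_list(network, path: str | Path, format: str = "tsv") -> None:
    """Write a correlation network's positive edges.

    TSV columns: gene_a, gene_b, r, p, df. GraphML carries r as the edge
    ``weight`` attribute so renderers can scale line thickness by |r|.
    """
    path = Path(path)
    if format == "tsv":
        rows = [
            {"gene_a": e.gene_a, "gene_b": e.gene_b,
             "r": e.result.r, "p": e.result.p_two_tailed, "df": e.result.df}
            for e in sorted(network.edges, key=lambda e: (e.gene_a, e.gene_b))
        ]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "df"]).to_csv(
            path, sep="\t", index=False, float_format="%.12g")
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(network.nodes)
        for e in network.edges:
            g.add_edge(e.gene_a, e.gene_b, weight=float(e.result.r),
                       p=float(e.result.p_two_tailed), df=int(e.result.df))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown edge-list format {format!r}")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a TSV edge list back as a DataFrame (round-trip of write_edge_list)."""
    return pd.read_csv(path, sep="\t")


def write_candidate_table(records, path: str | Path) -> None:
    """Write screen results as a TSV mirroring the published report layout:
    n_positive_links, gene_id, rpkm_max, rpkm_min, description."""
    rows = [
        {"n_positive_links": r.n_positive_links, "gene_id": r.gene_id,
         "rpkm_max": r.rpkm_max, "rpkm_min": r.rpkm_min,
         "description": r.description}
        for r in records
    ]
    pd.DataFrame(rows, columns=["n_positive_links", "gene_id", "rpkm_max",
                                "rpkm_min", "description"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g")
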