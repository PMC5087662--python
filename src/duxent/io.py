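"""Readers, writers and shared domain types.

Expression matrices travel as genes x samples tables (first column gene
identifiers, header row sample identifiers), interaction networks as
two-column edge lists or SIF, and gene sets as GMT.  Gene identifiers are
opaque, case-sensitive strings throughout; cross-species use goes through an
explicit user-supplied ortholog map (:func:`rename_genes`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("duxent")

#: The six experimental conditions of the retroviral construct panel.
CONDITIONS = (
    "control",
    "DUX4",
    "tMALDUX4",
    "tMALDUX4-VP16",
    "tMALDUX4-ERD",
    "DUX4c",
)

#: Non-control perturbations, each contrasted against control.
CONSTRUCTS = CONDITIONS[1:]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when an in-memory object violates a contract."""


@dataclass
class ExpressionMatrix:
    """Log-normalised expression, one row per gene, one column per sample.

    Values are treated as opaque positive quantities on a log scale; no log
    base is assumed.  Strict positivity is only enforced where it matters
    (signalling entropy), not at construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.shape[0] == 0:
            raise ValidationError("expression matrix contains no genes")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        if self.data.isna().any().any():
            na = self.data.isna()
            gene = na.any(axis=1).idxmax()
            raise ValidationError(f"missing values in expression matrix (e.g. gene {gene!r})")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def as_frame(matrix) -> pd.DataFrame:
    """Accept an :class:`ExpressionMatrix` or a bare DataFrame."""
    return matrix.data if isinstance(matrix, ExpressionMatrix) else matrix


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            seen, dupes = set(), set()
            for n in names:
                (dupes if n in seen else seen).add(n)
            raise ValidationError(f"duplicate gene-set names: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class SignatureSet:
    """A regulator's target signature: disjoint up- and down-regulated gene lists."""

    regulator: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.up_genes = tuple(self.up_genes)
        self.down_genes = tuple(self.down_genes)
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValidationError(
                f"up/down lists of {self.regulator} overlap: {sorted(overlap)[:5]}"
            )

    def to_collection(self) -> GeneSetCollection:
        sets = []
        if self.up_genes:
            sets.append(GeneSet(f"{self.regulator}_up", f"{self.regulator} upregulated targets", self.up_genes))
        if self.down_genes:
            sets.append(GeneSet(f"{self.regulator}_down", f"{self.regulator} downregulated targets", self.down_genes))
        return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# expression matrices

def read_expression(
    path,
    delimiter: str | None = None,
    duplicate_policy: str = "max_mean",
    missing_policy: str = "error",
) -> ExpressionMatrix:
    """Read a genes x samples table.

    duplicate_policy: how to treat repeated gene ids (probe-level data) —
    ``"max_mean"`` keeps the row with the highest mean expression, ``"mean"``
    averages rows, ``"error"`` refuses.
    missing_policy: ``"error"`` or ``"drop"`` (drop rows with any NA).
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else ("," if path.suffix == ".csv" else "\t")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no genes (header-only file)")
    # locate non-numeric cells before coercion so the error can name them
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ParseError(f"{path}: malformed numeric cell at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        if missing_policy == "drop":
            before = df.shape[0]
            df = df.dropna(axis=0)
            logger.info("read_expression: dropped %d rows with missing values", before - df.shape[0])
        else:
            na = df.isna()
            gene = na.any(axis=1).idxmax()
            raise ParseError(f"{path}: missing value at gene {gene!r}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        if duplicate_policy == "error":
            raise ParseError(f"{path}: duplicate gene id(s) {dupes}")
        if duplicate_policy == "mean":
            df = df.groupby(level=0, sort=False).mean()
        elif duplicate_policy == "max_mean":
            first_seen = list(dict.fromkeys(df.index))
            means = df.mean(axis=1).to_numpy()
            df = df.iloc[np.argsort(-means, kind="stable")]
            df = df[~df.index.duplicated(keep="first")]
            df = df.loc[first_seen]
        else:
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
        logger.info("read_expression: collapsed duplicate gene ids %s by %s", dupes, duplicate_policy)
    return ExpressionMatrix(df)


def write_expression(matrix, path, delimiter: str = "\t") -> None:
    df = as_frame(matrix)
    df.to_csv(path, sep=delimiter, index_label="gene")


def read_metadata(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a sample metadata table with columns sample_id, condition, replicate."""
    meta = pd.read_csv(path, sep=delimiter)
    required = {"sample_id", "condition"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"{path}: metadata lacks columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id in metadata")
    if "replicate" not in meta.columns:
        meta["replicate"] = meta.groupby("condition").cumcount() + 1
    return meta


def write_metadata(meta: pd.DataFrame, path, delimiter: str = "\t") -> None:
    meta.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# interaction networks

def read_network(path, format: str = "edge_list") -> nx.Graph:
    """Read an undirected simple interaction network.

    Self-loops are dropped and parallel edges collapsed; both are counted and
    logged.  SIF lines are ``node relation node``; edge-list lines are two
    whitespace/tab-separated node ids.
    """
    if format not in ("edge_list", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    graph = nx.Graph()
    n_loops = 0
    n_dupes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if format == "sif":
                if len(tokens) < 3:
                    raise ParseError(f"{path}:{lineno}: SIF line needs >=3 tokens")
                pairs = [(tokens[0], t) for t in tokens[2:]]
            else:
                if len(tokens) < 2:
                    raise ParseError(f"{path}:{lineno}: edge line needs >=2 tokens")
                pairs = [(tokens[0], tokens[1])]
            for u, v in pairs:
                if u == v:
                    n_loops += 1
                    continue
                if graph.has_edge(u, v):
                    n_dupes += 1
                    continue
                graph.add_edge(u, v)
    if n_loops or n_dupes:
        logger.info("read_network: dropped %d self-loops, collapsed %d duplicate edges", n_loops, n_dupes)
    graph.graph["n_self_loops_dropped"] = n_loops
    graph.graph["n_duplicate_edges_collapsed"] = n_dupes
    return graph


def write_network(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format: name TAB description TAB member..."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, description = fields[0], fields[1]
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            names.add(name)
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            sets.append(GeneSet(name, description, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# utilities

def rename_genes(matrix, mapping: Mapping[str, str] | pd.DataFrame) -> ExpressionMatrix:
    """Apply a user-supplied ortholog/identifier map (two-column table or dict).

    Unmapped genes are dropped with a logged count; collisions after mapping
    are collapsed by keeping the row with highest mean expression.
    """
    df = as_frame(matrix)
    if isinstance(mapping, pd.DataFrame):
        mapping = dict(zip(mapping.iloc[:, 0], mapping.iloc[:, 1]))
    keep = [g for g in df.index if g in mapping]
    dropped = df.shape[0] - len(keep)
    if dropped:
        logger.info("rename_genes: dropped %d unmapped genes", dropped)
    out = df.loc[keep].rename(index=mapping)
    if out.index.duplicated().any():
        order = out.mean(axis=1).to_numpy()
        out = out.iloc[np.argsort(-order, kind="stable")]
        out = out[~out.index.duplicated(keep="first")]
    return ExpressionMatrix(out)


def samples_for(meta: pd.DataFrame, condition: str) -> list[str]:
    """Sample ids belonging to one condition."""
    hits = meta.loc[meta["condition"] == condition, "sample_id"].tolist()
    if not hits:
        raise KeyError(f"condition {condition!r} absent from metadata")
    return hits
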