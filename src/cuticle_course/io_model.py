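"""Shared data model and file I/O for the wing cuticle time-course pipeline.

All tabular artifacts travel as tab-delimited UTF-8 text with a header row;
protein sequences as FASTA; dendrograms as Newick (written by the clustering
module through helpers here).  The central object is :class:`ExpressionMatrix`,
a genes x ordered-time-points table of non-negative FPKM values.

Readers validate and never coerce: a negative, missing or non-numeric FPKM is
an error, not a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TimeGrid",
    "ExpressionMatrix",
    "IsoformMatrix",
    "AnnotationSet",
    "DEResult",
    "ProteinSet",
    "ParseError",
    "DEFAULT_GRID",
    "read_expression_table",
    "write_expression_table",
    "read_isoform_table",
    "write_isoform_table",
    "read_annotation_lists",
    "read_de_table",
    "write_de_table",
    "read_protein_fasta",
    "write_protein_fasta",
]

#: the twenty standard amino acids, one-letter code
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class ParseError(ValueError):
    """Raised when an input file violates the data model."""


@dataclass(frozen=True)
class TimeGrid:
    """Ordered developmental sampling times in hours after white prepupa (awp).

    Adjacency ("neighboring time points") is defined by sort order; the grid
    need not be evenly spaced.
    """

    labels: tuple[float, ...]

    def __init__(self, labels: Iterable[float]):
        labels = tuple(float(x) for x in labels)
        if len(labels) < 2:
            raise ValueError("a TimeGrid needs at least 2 time points")
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise ValueError(f"time labels must be strictly increasing: {labels}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    @property
    def neighbor_pairs(self) -> tuple[tuple[float, float], ...]:
        """Adjacent (earlier, later) time pairs, e.g. (42, 52), (52, 62), ..."""
        return tuple(zip(self.labels, self.labels[1:]))

    def index(self, t: float) -> int:
        return self.labels.index(float(t))


#: the study's pupal-wing sampling design: 42-96 hr awp, 7 time points
DEFAULT_GRID = TimeGrid((42, 52, 62, 72, 80, 88, 96))


def _validate_fpkm(values: np.ndarray, what: str) -> None:
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError(f"{what}: non-numeric FPKM values")
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(f"{what}: non-finite FPKM at row {bad[0]}, column {bad[1]}")
    if (values < 0).any():
        bad = np.argwhere(values < 0)[0]
        raise ParseError(f"{what}: negative FPKM at row {bad[0]}, column {bad[1]}")


@dataclass
class ExpressionMatrix:
    """Genes x time points of merged (per-condition) FPKM.

    ``replicate_fpkm``, when present, is a 3-d array (gene, time, replicate)
    accepted solely for dispersion diagnostics; every analysis operates on the
    merged per-condition values.
    """

    gene_ids: tuple[str, ...]
    grid: TimeGrid
    fpkm: np.ndarray  # shape (n_genes, n_times)
    replicate_fpkm: np.ndarray | None = None

    def __post_init__(self):
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            raise ParseError(
                "duplicate gene ids: "
                + ", ".join(sorted(set(dupes[dupes.duplicated()])))
            )
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.gene_ids), len(self.grid)):
            raise ParseError(
                f"FPKM shape {self.fpkm.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.grid)} time points"
            )
        _validate_fpkm(self.fpkm, "expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fpkm, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.grid.labels),
        )

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene}") from None
        return self.fpkm[i]

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        missing = keep - set(self.gene_ids)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            tuple(self.gene_ids[i] for i in idx), self.grid, self.fpkm[idx]
        )


@dataclass
class IsoformMatrix:
    """Isoforms x time points with an isoform -> parent gene grouping."""

    isoform_ids: tuple[str, ...]
    parent_gene: dict[str, str]
    grid: TimeGrid
    fpkm: np.ndarray

    def __post_init__(self):
        self.isoform_ids = tuple(str(i) for i in self.isoform_ids)
        if len(set(self.isoform_ids)) != len(self.isoform_ids):
            raise ParseError("duplicate isoform ids")
        missing = [i for i in self.isoform_ids if i not in self.parent_gene]
        if missing:
            raise ParseError(f"isoforms without a parent gene: {missing[:5]}")
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.isoform_ids), len(self.grid)):
            raise ParseError("isoform FPKM shape mismatch")
        _validate_fpkm(self.fpkm, "isoform matrix")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for iso in self.isoform_ids:
            seen.setdefault(self.parent_gene[iso], None)
        return tuple(seen)

    def isoforms_of(self, gene: str) -> tuple[str, ...]:
        return tuple(i for i in self.isoform_ids if self.parent_gene[i] == gene)

    def row(self, isoform: str) -> np.ndarray:
        try:
            i = self.isoform_ids.index(isoform)
        except ValueError:
            raise KeyError(f"unknown isoform id: {isoform}") from None
        return self.fpkm[i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fpkm, index=pd.Index(self.isoform_ids, name="isoform_id"),
            columns=list(self.grid.labels),
        )
        df.insert(0, "gene_id", [self.parent_gene[i] for i in self.isoform_ids])
        return df


@dataclass
class AnnotationSet:
    """Named binary gene-label sets plus an optional gene -> category multimap.

    Typical labels: ``cuticle_protein``, ``arthropod_restricted``,
    ``tf_dna_binding``, ``wing_phenotype``.
    """

    label_maps: dict[str, frozenset[str]] = field(default_factory=dict)
    categories: dict[str, frozenset[str]] = field(default_factory=dict)

    def labeled(self, name: str) -> frozenset[str]:
        return self.label_maps.get(name, frozenset())


@dataclass
class DEResult:
    """Pairwise differential-expression records from the upstream run.

    ``records`` columns: gene, t1, t2, fold, q.  Significance filtering is
    downstream; all records are kept here.
    """

    records: pd.DataFrame

    def __post_init__(self):
        need = {"gene", "t1", "t2", "fold", "q"}
        if not need <= set(self.records.columns):
            raise ParseError(f"DE table needs columns {sorted(need)}")
        q = self.records["q"].to_numpy(float)
        if ((q < 0) | (q > 1)).any() or not np.isfinite(q).all():
            raise ParseError("q values must lie in [0, 1]")
        fold = self.records["fold"].to_numpy(float)
        if (fold[np.isfinite(fold)] <= 0).any():
            raise ParseError("fold changes must be positive")

    def for_pair(self, t1: float, t2: float) -> pd.DataFrame:
        r = self.records
        return r[(r["t1"] == float(t1)) & (r["t2"] == float(t2))]


@dataclass
class ProteinSet:
    """Protein sequences keyed by id; non-standard letters are flagged."""

    records: dict[str, str]

    def __post_init__(self):
        for pid, seq in self.records.items():
            if not seq:
                raise ParseError(f"empty sequence for {pid}")

    def nonstandard_letters(self, pid: str) -> set[str]:
        return {c for c in self.records[pid].upper() if c not in STANDARD_AA}

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_table(path: str | Path, dialect: str = "wide") -> ExpressionMatrix:
    """Read a gene FPKM table.

    ``wide``: first column ``gene_id``, remaining columns numeric time labels.
    ``long``: columns ``gene``, ``time``, ``fpkm``; every gene must cover the
    full grid.
    """
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if df.columns[0] != "gene_id":
            raise ParseError(f"{path}: first column header must be 'gene_id', got "
                             f"{df.columns[0]!r}")
        try:
            times = [float(c) for c in df.columns[1:]]
        except ValueError as e:
            raise ParseError(f"{path}: non-numeric time label in header: {e}")
        if df.iloc[:, 1:].isna().any().any():
            raise ParseError(f"{path}: missing FPKM cells")
        values = df.iloc[:, 1:].to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError(f"{path}: non-numeric FPKM values")
        return ExpressionMatrix(tuple(df.iloc[:, 0]), TimeGrid(times), values)
    if dialect == "long":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        need = {"gene", "time", "fpkm"}
        if not need <= set(df.columns):
            raise ParseError(f"{path}: long dialect needs columns {sorted(need)}")
        if df["fpkm"].isna().any():
            raise ParseError(f"{path}: missing FPKM cells")
        wide = df.pivot(index="gene", columns="time", values="fpkm")
        if wide.isna().any().any():
            raise ParseError(f"{path}: incomplete gene/time coverage")
        wide = wide[sorted(wide.columns)]
        # preserve first-appearance gene order from the file
        order = df["gene"].drop_duplicates().tolist()
        wide = wide.loc[order]
        return ExpressionMatrix(tuple(wide.index), TimeGrid(wide.columns),
                                wide.to_numpy())
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.columns = [format(c, "g") for c in df.columns]
    df.to_csv(path, sep="\t")


def read_isoform_table(path: str | Path) -> IsoformMatrix:
    """Read an isoform FPKM table: isoform_id, gene_id, then time columns."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns[:2]) != ["isoform_id", "gene_id"]:
        raise ParseError(f"{path}: first columns must be isoform_id, gene_id")
    if df["isoform_id"].duplicated().any():
        dupes = df.loc[df["isoform_id"].duplicated(), "isoform_id"]
        raise ParseError(f"{path}: isoform listed more than once: {list(dupes)[:5]}")
    times = [float(c) for c in df.columns[2:]]
    if df.iloc[:, 2:].isna().any().any():
        raise ParseError(f"{path}: missing FPKM cells")
    parent = dict(zip(df["isoform_id"], df["gene_id"]))
    return IsoformMatrix(tuple(df["isoform_id"]), parent, TimeGrid(times),
                         df.iloc[:, 2:].to_numpy())


def write_isoform_table(iso: IsoformMatrix, path: str | Path) -> None:
    df = iso.to_frame()
    df.columns = ["gene_id"] + [format(c, "g") for c in df.columns[1:]]
    df.to_csv(path, sep="\t")


def read_annotation_lists(paths: Mapping[str, str | Path]) -> AnnotationSet:
    """Read named annotation files into an :class:`AnnotationSet`.

    One-column files contribute a binary label set under their name;
    two-column (gene<TAB>category) files feed the category multimap.
    Duplicated ids deduplicate; an empty file yields an empty set with a
    warning.
    """
    labels: dict[str, frozenset[str]] = {}
    categories: dict[str, set[str]] = {}
    for name, p in paths.items():
        p = Path(p)
        lines = [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]
        if not lines:
            warnings.warn(f"annotation file {p} is empty; label {name!r} empty")
            labels[name] = frozenset()
            continue
        if any("\t" in ln for ln in lines):
            for ln in lines:
                gene, cat = ln.split("\t")[:2]
                categories.setdefault(gene, set()).add(cat)
            labels[name] = frozenset(ln.split("\t")[0] for ln in lines)
        else:
            labels[name] = frozenset(lines)
    return AnnotationSet(labels, {g: frozenset(c) for g, c in categories.items()})


def read_de_table(path: str | Path, grid: TimeGrid | None = None) -> DEResult:
    """Read pairwise DE records (gene, t1, t2, fold, q).

    With a grid, records whose time pair falls outside it are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    res = DEResult(df)
    if grid is not None:
        ok = df["t1"].isin(grid.labels) & df["t2"].isin(grid.labels)
        res = DEResult(df[ok].reset_index(drop=True))
    return res


def write_de_table(de: DEResult, path: str | Path) -> None:
    de.records.to_csv(path, sep="\t", index=False)


def read_protein_fasta(path: str | Path) -> ProteinSet:
    """Read a protein FASTA; the header token before whitespace is the id."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not len(rec.seq):
            raise ParseError(f"{path}: empty sequence record {rec.id!r}")
        if rec.id in records:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return ProteinSet(records)


def write_protein_fasta(proteins: ProteinSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.records.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
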