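"""Readers and writers for the flat-file formats the pipeline touches.

All tabular exchange is TSV.  Interaction networks use the STRING flat edge-list
convention (``protein1 protein2 combined_score`` with integer scores in 0-999),
annotations are either two-column ``(term_id, gene_id)`` tables or GAF 2.x, and
gene sets are one-id-per-line text files.  Missing values are accepted as empty
cells or ``NA`` on read and always written back as ``NA``; parsing never
silently coerces a missing cell to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("sample_id", "age", "drug", "induction", "replicate", "batch", "dataset_id")

__all__ = [
    "SampleDesign",
    "PeptideTable",
    "ProteinTable",
    "GeneSet",
    "AnnotationSet",
    "read_intensity_table",
    "read_design",
    "read_network_edges",
    "read_annotations",
    "read_parent_map",
    "read_gene_set",
    "read_protein_table",
    "read_de_table",
    "read_enrichment_table",
    "write_table",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SampleDesign:
    """Sample annotation table for a factorial TMT-style experiment.

    The condition factors are ``age``, ``drug`` and ``induction``; ``batch``
    records the labeling/dissection batch and enters models as a covariate,
    never as a condition.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table is missing required column(s): {missing}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicated sample_id(s) in design: {sorted(set(dup))}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        self.table = self.table.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def cells(self) -> pd.Series:
        """(age, drug, induction) condition cell of every sample."""
        return pd.Series(
            list(zip(self.table["age"], self.table["drug"], self.table["induction"])),
            index=self.table.index,
        )

    def cell_counts(self) -> dict[tuple, int]:
        return self.cells().value_counts().to_dict()

    def batches(self) -> pd.Series:
        return self.table["batch"]

    def subset(self, sample_ids: Iterable[str]) -> "SampleDesign":
        keep = [s for s in self.table.index if s in set(sample_ids)]
        return SampleDesign(self.table.loc[keep].reset_index(drop=True))


@dataclass
class PeptideTable:
    """Peptide-level intensities: rows are peptides, columns are samples.

    ``values`` holds intensities with NaN marking missing measurements;
    ``proteins`` maps each peptide to its parent protein; ``scale`` is either
    ``"raw"`` (nonnegative intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    proteins: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if not self.values.index.equals(self.proteins.index):
            raise ValueError("peptide index of values and protein map differ")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "protein_id", self.proteins)
        out.index.name = "peptide_id"
        return out.reset_index()


@dataclass
class ProteinTable:
    """Protein-level log2 values with NaN missingness mask."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValueError(f"duplicated protein id(s): {dups}")

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.isna()

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.index.name = "protein_id"
        return out.reset_index()


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class AnnotationSet:
    """Term -> gene multimap with optional metadata and is_a parent links."""

    terms: dict[str, set]
    meta: dict[str, dict] = field(default_factory=dict)
    parents: dict[str, set] | None = None

    def restrict(self, background: set) -> dict[str, set]:
        """Term memberships intersected with a background universe."""
        return {t: g & background for t, g in self.terms.items()}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_intensity_table(path: str | Path, scale: str = "raw") -> PeptideTable:
    """Read a peptide x sample TSV (columns: peptide_id, protein_id, samples...).

    Empty cells and ``NA`` are recorded as missing.  Peptides mapping to a
    protein group (ids joined by ``;``) are excluded with a logged count, so
    group ambiguity cannot leak into protein quantification.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns[:2]) != ["peptide_id", "protein_id"]:
        raise ValueError(
            f"first two columns must be 'peptide_id', 'protein_id'; got {list(df.columns[:2])}"
        )
    dup = df["peptide_id"][df["peptide_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated peptide id(s): {sorted(set(dup))}")
    shared = df["protein_id"].str.contains(";", na=False)
    if shared.any():
        logger.info("excluding %d shared peptide(s) mapping to protein groups", int(shared.sum()))
        df = df.loc[~shared]
    sample_cols = list(df.columns[2:])
    values = df[sample_cols].apply(pd.to_numeric, errors="raise").astype(float)
    values.index = pd.Index(df["peptide_id"], name="peptide_id")
    proteins = pd.Series(df["protein_id"].to_numpy(), index=values.index, name="protein_id")
    if scale == "raw" and (values.to_numpy() < 0).any():
        raise ValueError("negative raw intensity encountered")
    table = PeptideTable(values=values, proteins=proteins, scale=scale)
    logger.info(
        "read %d peptides x %d samples (%d missing cells)",
        values.shape[0], values.shape[1], table.n_missing,
    )
    return table


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    design = SampleDesign(df)
    logger.info("design: %d samples, cells %s", len(df), design.cell_counts())
    return design


def read_network_edges(path: str | Path, score_threshold: int = 899) -> nx.Graph:
    """Read a STRING-style flat edge list keeping edges with score > threshold.

    The threshold is strict: with integer scores, ``> 899`` keeps 900 and up.
    Self-loops are dropped; duplicate/reciprocal rows are merged keeping the
    maximum score.
    """
    graph = nx.Graph()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            a, b, raw_score = parts[0], parts[1], parts[2]
            if lineno == 1 and not _is_int(raw_score):
                continue  # header row
            if not _is_int(raw_score):
                raise ValueError(f"{path}:{lineno}: non-integer combined_score {raw_score!r}")
            score = int(raw_score)
            n_rows += 1
            if a == b:
                continue
            if score <= score_threshold:
                continue
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], score)
            else:
                graph.add_edge(a, b, score=score)
    if graph.number_of_edges() == 0:
        raise ValueError(
            f"no edges with combined_score > {score_threshold} among {n_rows} rows in {path}"
        )
    logger.info(
        "network: %d nodes, %d edges (score > %d)",
        graph.number_of_nodes(), graph.number_of_edges(), score_threshold,
    )
    return graph


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_annotations(path: str | Path, format: str = "two_column") -> AnnotationSet:
    """Read term->gene annotations from a two-column TSV or a GAF 2.x file.

    GAF convention: gene id is column 2, term id is column 5, NOT-qualified
    lines are excluded; malformed lines are skipped with a logged count.
    """
    terms: dict[str, set] = {}
    meta: dict[str, dict] = {}
    if format == "two_column":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                term, gene = parts[0], parts[1]
                terms.setdefault(term, set()).add(gene)
                if len(parts) >= 3 and parts[2]:
                    meta.setdefault(term, {})["name"] = parts[2]
    elif format == "gaf":
        n_skipped = 0
        aspects = {"P": "biological_process", "F": "molecular_function", "C": "cellular_component"}
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5 or not parts[1] or not parts[4]:
                    n_skipped += 1
                    continue
                qualifier = parts[3] if len(parts) > 3 else ""
                if "NOT" in qualifier.split("|"):
                    continue
                gene, term = parts[1], parts[4]
                terms.setdefault(term, set()).add(gene)
                if len(parts) > 8 and parts[8] in aspects:
                    meta.setdefault(term, {})["namespace"] = aspects[parts[8]]
        if n_skipped:
            logger.info("skipped %d malformed GAF line(s)", n_skipped)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not terms:
        raise ValueError(f"annotation file {path} yielded no term-gene pairs")
    return AnnotationSet(terms=terms, meta=meta)


def read_parent_map(path: str | Path) -> dict[str, set]:
    """Optional two-column (child_term, parent_term) is_a table."""
    parents: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            parents.setdefault(parts[0], set()).add(parts[1])
    return parents


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene/protein id per line."""
    with open(path) as fh:
        members = frozenset(line.strip() for line in fh if line.strip())
    return GeneSet(name=name or Path(path).stem, members=members)


def read_protein_table(path: str | Path) -> ProteinTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "protein_id":
        raise ValueError(f"first column must be 'protein_id', got {df.columns[0]!r}")
    values = df.set_index("protein_id").apply(pd.to_numeric, errors="raise").astype(float)
    return ProteinTable(values=values)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return df.set_index("protein_id")


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"term_id": str, "direction": str})


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------


def _format_cell(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    if isinstance(x, (np.floating,)):
        return _format_cell(float(x))
    return str(x)


def write_table(result, path: str | Path) -> None:
    """Write any tabular pipeline result as a deterministic TSV.

    Columns keep their defined order, rows are sorted by the leading id
    column(s), missing values are written as ``NA`` and floats at 6
    significant digits, so identical results yield bit-identical files.
    """
    if hasattr(result, "to_frame") and not isinstance(result, (pd.Series, pd.DataFrame)):
        df = result.to_frame()
    elif isinstance(result, pd.Series):
        df = result.rename_axis("id").reset_index()
    elif isinstance(result, pd.DataFrame):
        df = result.reset_index() if result.index.name is not None else result.copy()
    else:
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    sort_cols = [c for c in df.columns if df[c].dtype == object][:2]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_format_cell(x) for x in row) + "\n")
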