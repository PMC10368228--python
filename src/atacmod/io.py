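"""Readers and writers for the on-disk formats the pipeline consumes.

Fragments are (gzipped) TSV in the 10x convention: chrom, start, end,
barcode[, count], 0-based half-open coordinates. Matrices travel as
MatrixMarket files with one-name-per-line row/column sidecars; gene sets as
GMT; protein-protein interactions as 3-column TSV (node1, node2, score).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ConfigurationError(ValueError):
    """Invalid configuration or parameters."""


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally parseable input that violates an invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


@dataclass
class FragmentSet:
    """Per-barcode Tn5 fragment intervals plus a barcode -> sample map.

    ``data`` has columns chrom, start, end, barcode, count; coordinates are
    0-based half-open so each fragment contributes two Tn5 insertions, at
    ``start`` and ``end - 1``.
    """

    data: pd.DataFrame
    sample_of_barcode: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"fragment table missing columns {missing}")
        if len(self.data):
            if (self.data["start"] >= self.data["end"]).any():
                raise ValidationError("fragment with start >= end")
            if (self.data["start"] < 0).any():
                raise ValidationError("negative fragment coordinate")
            if (self.data["count"] < 1).any():
                raise ValidationError("fragment count < 1")
            if (self.data["barcode"].astype(str) == "").any():
                raise ValidationError("empty barcode")

    @property
    def barcodes(self) -> np.ndarray:
        return self.data["barcode"].unique()

    def sample_labels(self) -> pd.Series:
        """Sample label per fragment row (default sample 's1' if unmapped)."""
        return self.data["barcode"].map(
            lambda b: self.sample_of_barcode.get(b, "s1")
        )

    def insertion_positions(self) -> pd.DataFrame:
        """Long table of Tn5 insertion sites: two per fragment."""
        d = self.data
        left = d[["chrom", "start", "barcode"]].rename(columns={"start": "pos"})
        right = d[["chrom", "end", "barcode"]].copy()
        right["end"] -= 1
        right = right.rename(columns={"end": "pos"})
        return pd.concat([left, right], ignore_index=True)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass
class PPINetwork:
    """Undirected weighted protein-protein interaction edges, scores in [0,1]."""

    edges: pd.DataFrame  # columns: node1, node2, score

    def __post_init__(self) -> None:
        need = ["node1", "node2", "score"]
        if list(self.edges.columns[:3]) != need:
            self.edges = self.edges.rename(
                columns=dict(zip(self.edges.columns[:3], need))
            )
        s = self.edges["score"]
        if len(s) and ((s < 0).any() or (s > 1).any()):
            raise ValidationError("PPI scores must lie in [0, 1]")


@dataclass
class NamedMatrix:
    """Matrix with row/column names; values may be dense or scipy sparse."""

    values: np.ndarray | scipy.sparse.spmatrix
    row_names: list[str]
    col_names: list[str]

    def __post_init__(self) -> None:
        r, c = self.values.shape
        if len(self.row_names) != r or len(self.col_names) != c:
            raise ValidationError(
                f"name sidecars ({len(self.row_names)}, {len(self.col_names)}) "
                f"do not match matrix shape {self.values.shape}"
            )

    def toarray(self) -> np.ndarray:
        v = self.values
        return v.toarray() if scipy.sparse.issparse(v) else np.asarray(v)


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path, sample_map: Mapping[str, str] | None = None) -> FragmentSet:
    """Read a (gzipped) fragments TSV; 4 or 5 columns, '#' comments allowed."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 or 5 fields, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            count = 1
            if len(parts) == 5:
                try:
                    count = int(parts[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: non-integer count") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            rows.append((parts[0], start, end, parts[3], count))
    data = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    return FragmentSet(data, dict(sample_map or {}))


def write_fragments(frags: FragmentSet, path) -> None:
    with _open_text(path, "wt") as fh:
        for row in frags.data.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.barcode}\t{row.count}\n")


def read_barcode_samples(path) -> dict[str, str]:
    """Two-column TSV barcode -> sample."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs >=3 fields, got {len(parts)}"
                )
            sets.append(
                GeneSet(parts[0], frozenset(p for p in parts[2:] if p), parts[1])
            )
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    with _open_text(path, "wt") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.source}\t{members}\n")


# ---------------------------------------------------------------------------
# Named matrices (MatrixMarket + sidecars)
# ---------------------------------------------------------------------------

def _read_names(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n")]


def read_matrix(path_mtx, path_rows, path_cols) -> NamedMatrix:
    values = scipy.io.mmread(str(path_mtx))
    if scipy.sparse.issparse(values):
        values = values.tocsr()
    return NamedMatrix(values, _read_names(path_rows), _read_names(path_cols))


def write_matrix(matrix: NamedMatrix, path_mtx, path_rows, path_cols) -> None:
    values = matrix.values
    if not scipy.sparse.issparse(values):
        values = scipy.sparse.coo_matrix(np.asarray(values))
    scipy.io.mmwrite(str(path_mtx), values)
    for names, path in ((matrix.row_names, path_rows), (matrix.col_names, path_cols)):
        with _open_text(path, "wt") as fh:
            for name in names:
                fh.write(f"{name}\n")


# ---------------------------------------------------------------------------
# PPI and truth JSON
# ---------------------------------------------------------------------------

def read_ppi(path) -> PPINetwork:
    edges = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["node1", "node2", "score"]
    )
    return PPINetwork(edges)


def write_ppi(ppi: PPINetwork, path) -> None:
    ppi.edges.to_csv(path, sep="\t", header=False, index=False)


def write_truth(truth_dict: Mapping, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth_dict, indent=1, default=_default))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
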