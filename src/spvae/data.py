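"""Reading, validation and assembly of grouped count data.

A *group* is one unpaired scRNA-seq dataset (cells x genes raw UMI counts)
with its own gene set; the model never aligns features across groups, so
gene names only need to be unique within a group.  Counts can be read from
Matrix Market triplet files with one-name-per-line sidecars, or from dense
delimited tables (header row of gene names, index column of cell names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ValidationError(ValueError):
    """Raised when input data violates the count-matrix contract."""


@dataclass
class GroupRecord:
    """One group's raw counts with per-cell metadata.

    counts : (cells, genes) nonnegative integer matrix
    batch_codes : integer codes into ``batch_categories``
    labels : optional per-cell class names over a shared vocabulary
    """

    counts: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    batch_codes: np.ndarray = None
    batch_categories: list[str] = None
    labels: np.ndarray | None = None
    name: str = "group"

    def __post_init__(self):
        self.counts = _validate_counts(np.asarray(self.counts))
        n_cells, n_genes = self.counts.shape
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_names = [str(c) for c in self.cell_names]
        if len(self.gene_names) != n_genes:
            raise ValidationError(
                f"{len(self.gene_names)} gene names for {n_genes} matrix columns"
            )
        if len(self.cell_names) != n_cells:
            raise ValidationError(
                f"{len(self.cell_names)} cell names for {n_cells} matrix rows"
            )
        if len(set(self.gene_names)) != n_genes:
            raise ValidationError("duplicate gene names within the group")
        if len(set(self.cell_names)) != n_cells:
            raise ValidationError("duplicate cell names within the group")
        if self.batch_codes is None:
            self.batch_codes = np.zeros(n_cells, dtype=np.int64)
            self.batch_categories = ["batch0"]
        else:
            self.batch_codes = np.asarray(self.batch_codes)
            if self.batch_codes.dtype.kind not in "iu":
                cat = pd.Categorical(self.batch_codes)
                self.batch_categories = [str(c) for c in cat.categories]
                self.batch_codes = np.asarray(cat.codes, dtype=np.int64)
            elif self.batch_categories is None:
                self.batch_categories = [str(b) for b in np.unique(self.batch_codes)]
                remap = {b: i for i, b in enumerate(np.unique(self.batch_codes))}
                self.batch_codes = np.array([remap[b] for b in self.batch_codes])
        if len(self.batch_codes) != n_cells:
            raise ValidationError("batch vector length does not match cell count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != n_cells:
                raise ValidationError("label vector length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_batches(self) -> int:
        return len(self.batch_categories)

    def batch_onehot(self) -> np.ndarray:
        out = np.zeros((self.n_cells, self.n_batches), dtype=np.float32)
        out[np.arange(self.n_cells), self.batch_codes] = 1.0
        return out


@dataclass
class GroupedExpressionBundle:
    """Two or more validated groups plus the shared label vocabulary."""

    groups: list[GroupRecord]
    label_vocabulary: list[str] | None
    library_sizes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def label_codes(self, group_index: int) -> np.ndarray:
        """Integer codes of a group's labels into the shared vocabulary."""
        if self.label_vocabulary is None:
            raise ValueError("bundle carries no label vocabulary")
        labels = self.groups[group_index].labels
        lookup = {name: i for i, name in enumerate(self.label_vocabulary)}
        return np.array([lookup[l] for l in labels], dtype=np.int64)


def _validate_counts(counts: np.ndarray) -> np.ndarray:
    if counts.ndim != 2:
        raise ValidationError(f"counts must be 2-D, got shape {counts.shape}")
    if counts.dtype.kind == "f":
        frac = counts != np.floor(counts)
        if frac.any():
            i, j = np.argwhere(frac)[0]
            raise ValidationError(
                f"non-integer count {counts[i, j]} at cell {i}, gene {j}"
            )
    neg = counts < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(f"negative count {counts[i, j]} at cell {i}, gene {j}")
    return counts.astype(np.int64)


def _read_names(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_group(
    counts_path: str | Path,
    format: Literal["mtx", "dense_delimited"],
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    batch: Sequence | str | Path | None = None,
    labels: Sequence | str | Path | None = None,
    name: str = "group",
) -> GroupRecord:
    """Read one group from disk and validate it.

    MTX matrices are transposed to cells x genes when the header dimensions
    match the sidecar lengths the other way around.  ``batch`` and
    ``labels`` may be in-memory sequences or paths to one-value-per-line
    files.
    """
    counts_path = Path(counts_path)
    if not counts_path.exists():
        raise FileNotFoundError(counts_path)
    if format == "mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("mtx format requires gene and cell sidecar files")
        genes = _read_names(Path(genes_path))
        cells = _read_names(Path(cells_path))
        mat = spio.mmread(counts_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        if mat.shape == (len(cells), len(genes)):
            pass
        elif mat.shape == (len(genes), len(cells)):
            mat = mat.T
        else:
            raise ValidationError(
                f"matrix shape {mat.shape} matches neither "
                f"(cells={len(cells)}, genes={len(genes)}) nor its transpose"
            )
    elif format == "dense_delimited":
        sep = "\t" if counts_path.suffix in {".tsv", ".tab", ".txt"} else ","
        df = pd.read_csv(counts_path, sep=sep, index_col=0)
        genes = [str(g) for g in df.columns]
        cells = [str(c) for c in df.index]
        mat = df.to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}")

    def _column(spec):
        if spec is None:
            return None
        if isinstance(spec, (str, Path)) and Path(spec).exists():
            return np.array(_read_names(Path(spec)), dtype=object)
        return np.asarray(spec, dtype=object)

    return GroupRecord(
        counts=mat,
        gene_names=genes,
        cell_names=cells,
        batch_codes=_column(batch),
        labels=_column(labels),
        name=name,
    )


def write_group(record: GroupRecord, out_dir: str | Path) -> None:
    """Write a group as MTX + sidecars (+ optional batch/label columns)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out_dir / "counts.mtx", sparse.coo_matrix(record.counts))
    (out_dir / "genes.txt").write_text("\n".join(record.gene_names) + "\n")
    (out_dir / "cells.txt").write_text("\n".join(record.cell_names) + "\n")
    batches = [record.batch_categories[c] for c in record.batch_codes]
    (out_dir / "batches.txt").write_text("\n".join(batches) + "\n")
    if record.labels is not None:
        (out_dir / "labels.txt").write_text("\n".join(map(str, record.labels)) + "\n")


def compute_library_sizes(record: GroupRecord) -> np.ndarray:
    """Per-cell total UMI count; zero-count cells are rejected because the
    library size scales the negative-binomial rate and must be positive."""
    tau = record.counts.sum(axis=1)
    if (tau == 0).any():
        idx = int(np.argwhere(tau == 0)[0, 0])
        raise ValidationError(
            f"cell {record.cell_names[idx]!r} has zero total counts; "
            "filter empty cells before model fitting"
        )
    return tau


def assemble_bundle(groups: list[GroupRecord], supervised: bool) -> GroupedExpressionBundle:
    """Validate group compatibility and build the shared label vocabulary."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    vocabulary: list[str] | None = None
    if supervised:
        for i, g in enumerate(groups):
            if g.labels is None:
                raise ValidationError(
                    f"group {i} ({g.name!r}) has no labels; supervised mode requires "
                    "labels for every group - use unsupervised (OT) mode instead"
                )
    observed: set[str] = set()
    any_labels = False
    for g in groups:
        if g.labels is not None:
            any_labels = True
            observed.update(str(l) for l in g.labels)
    if any_labels:
        vocabulary = sorted(observed)
    lib_sizes = [compute_library_sizes(g) for g in groups]
    return GroupedExpressionBundle(
        groups=list(groups), label_vocabulary=vocabulary, library_sizes=lib_sizes
    )
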