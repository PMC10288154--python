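"""Count-matrix containers and I/O.

A :class:`CountMatrix` holds one modality's features × cells matrix together
with its identifiers; a :class:`MultiModalDataset` is an ordered collection of
modalities measured on the same cells.  Matrices are stored as
``scipy.sparse.csr_matrix`` throughout — single-cell count data is sparse and
every downstream operation (normalization, graph construction, factorization)
preserves the sparsity pattern.

Two on-disk layouts are supported: the CellRanger-style Matrix Market triplet
directory (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) and a dense
delimited table with a header row of cell ids and a first column of feature
ids.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "MultiModalDataset",
    "load_counts",
    "write_counts",
    "filter_features",
    "median_library_normalize",
]

Flavor = Literal["raw", "normalized"]


def _as_csr(values) -> sp.csr_matrix:
    if sp.issparse(values):
        return values.tocsr().astype(np.float64)
    return sp.csr_matrix(np.asarray(values, dtype=np.float64))


@dataclass
class CountMatrix:
    """One modality's features × cells count matrix.

    Parameters
    ----------
    values : (M, N) sparse matrix
        Non-negative entries; integers when ``flavor="raw"``.
    feature_ids, cell_ids : sequences of str
        Unique identifiers matching the matrix dimensions.
    modality_name : str
        E.g. ``"rna"`` or ``"atac"``.
    flavor : {"raw", "normalized"}
    """

    values: sp.csr_matrix
    feature_ids: list[str]
    cell_ids: list[str]
    modality_name: str = "modality"
    flavor: Flavor = "raw"

    def __post_init__(self) -> None:
        self.values = _as_csr(self.values)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        m, n = self.values.shape
        if len(self.feature_ids) != m:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {m} matrix rows"
            )
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix columns")
        if len(set(self.feature_ids)) != m:
            raise ValueError("feature_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        data = self.values.data
        if data.size and data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if self.flavor == "raw" and data.size and np.any(data != np.floor(data)):
            raise ValueError("raw count matrix contains non-integer entries")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


@dataclass
class MultiModalDataset:
    """Aligned modalities sharing one ordered cell set, plus optional labels."""

    modalities: list[CountMatrix]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.modalities) < 1:
            raise ValueError("dataset needs at least one modality")
        ref = self.modalities[0].cell_ids
        for cm in self.modalities[1:]:
            if cm.cell_ids != ref:
                raise ValueError(
                    f"modality {cm.modality_name!r} cell ids differ from "
                    f"{self.modalities[0].modality_name!r}"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(ref):
                raise ValueError("labels length does not match the cell count")

    @property
    def n_cells(self) -> int:
        return self.modalities[0].n_cells

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def cell_ids(self) -> list[str]:
        return self.modalities[0].cell_ids

    def map(self, fn) -> "MultiModalDataset":
        """Apply ``fn`` to every modality, keeping labels."""
        return MultiModalDataset([fn(cm) for cm in self.modalities], self.labels)


def _read_id_list(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            # CellRanger features.tsv may carry extra tab-separated columns
            ids.append(line.split("\t")[0])
    return ids


def _find_one(directory: Path, candidates: Sequence[str], what: str) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {what} file in {directory} (tried {candidates})")


def load_counts(path, format: str = "mtx_dir", modality_name: str = "modality") -> CountMatrix:
    """Read a raw count matrix from disk.

    ``mtx_dir`` expects a directory holding a Matrix Market file plus feature
    and barcode id lists; ``delimited`` expects a dense table whose header row
    lists cell ids and whose first column lists feature ids.  Orientation on
    disk is resolved by matching the id-list lengths; the returned matrix is
    always features × cells.
    """
    path = Path(path)
    if format == "mtx_dir":
        if not path.is_dir():
            raise FileNotFoundError(f"{path} is not a directory")
        mtx = _find_one(path, ["matrix.mtx", "counts.mtx"], "matrix (.mtx)")
        feats = _find_one(
            path, ["features.tsv", "features.txt", "genes.tsv"], "feature list"
        )
        bars = _find_one(path, ["barcodes.tsv", "barcodes.txt"], "barcode list")
        values = sp.csr_matrix(scipy.io.mmread(mtx))
        feature_ids = _read_id_list(feats)
        cell_ids = _read_id_list(bars)
    elif format == "delimited":
        if not path.is_file():
            raise FileNotFoundError(f"{path} does not exist")
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            sep = "\t" if "\t" in header else ","
            header_fields = header.split(sep)
            rows = []
            feature_ids = []
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split(sep)
                # each data row carries the feature id plus one value per cell
                feature_ids.append(fields[0])
                rows.append(fields[1:])
        if not rows:
            raise ValueError(f"{path}: no data rows")
        # header = id-column label (may be empty) followed by the cell ids
        cell_ids = header_fields[1:]
        n_values = {len(r) for r in rows}
        if len(n_values) != 1:
            raise ValueError(f"{path}: ragged rows with varying field counts")
        if n_values.pop() != len(cell_ids):
            raise ValueError(
                f"{path}: rows carry {len(rows[0])} values but the header "
                f"lists {len(cell_ids)} cell ids"
            )
        values = sp.csr_matrix(np.array(rows, dtype=np.float64))
    else:
        raise ValueError(f"unknown format {format!r}")

    m, n = values.shape
    if (m, n) == (len(feature_ids), len(cell_ids)):
        pass
    elif (m, n) == (len(cell_ids), len(feature_ids)):
        values = values.T.tocsr()
    else:
        raise ValueError(
            f"matrix shape {(m, n)} matches neither (features={len(feature_ids)}, "
            f"cells={len(cell_ids)}) nor its transpose"
        )
    return CountMatrix(values, feature_ids, cell_ids, modality_name, flavor="raw")


def write_counts(x: CountMatrix, path, format: str = "mtx_dir") -> None:
    """Write a count matrix in a layout :func:`load_counts` reads back."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(x.values))
        (path / "features.tsv").write_text("\n".join(x.feature_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(x.cell_ids) + "\n")
    elif format == "delimited":
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(x.toarray(), index=x.feature_ids, columns=x.cell_ids)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def filter_features(x: CountMatrix, min_cells: int = 10) -> CountMatrix:
    """Keep features with a nonzero count in at least ``min_cells`` cells.

    The default of 10 matches the common minimum-prevalence filter applied to
    single-cell count matrices before factorization.  Feature order is
    preserved.  Idempotent for a fixed ``min_cells``.
    """
    if x.flavor != "raw":
        raise ValueError("filter_features expects raw counts")
    if min_cells < 1:
        raise ValueError("min_cells must be a positive integer")
    n_nonzero_cells = np.asarray((x.values > 0).sum(axis=1)).ravel()
    keep = n_nonzero_cells >= min_cells
    if not keep.any():
        raise ValueError(
            f"min_cells={min_cells} removes every feature of modality "
            f"{x.modality_name!r}"
        )
    if keep.all():
        return x
    kept_ids = [f for f, k in zip(x.feature_ids, keep) if k]
    return CountMatrix(
        x.values[keep], kept_ids, list(x.cell_ids), x.modality_name, x.flavor
    )


def median_library_normalize(x: CountMatrix) -> CountMatrix:
    """Median library size normalization.

    Each cell's counts are divided by that cell's library size and multiplied
    by the median library size across cells, so every column of the result
    sums to the median library size.  Count-like magnitudes are preserved,
    which keeps the Poisson/KL reading of the data meaningful.
    """
    if x.flavor != "raw":
        raise ValueError("median_library_normalize expects raw counts")
    lib = x.library_sizes()
    zero = lib <= 0
    if zero.any():
        bad = [c for c, z in zip(x.cell_ids, zero) if z]
        raise ValueError(f"cells with zero library size: {bad}")
    med = float(np.median(lib))
    scale = med / lib
    normalized = (x.values @ sp.diags(scale)).tocsr()
    return CountMatrix(
        normalized, list(x.feature_ids), list(x.cell_ids), x.modality_name,
        flavor="normalized",
    )


def read_labels(path) -> pd.Series:
    """Read a ``cell_id,cluster`` CSV into a Series indexed by cell id."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns cell_id,cluster")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def write_labels(cell_ids: Sequence[str], labels, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "cluster"])
        for c, l in zip(cell_ids, labels):
            w.writerow([c, l])
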