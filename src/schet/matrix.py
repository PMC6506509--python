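"""Count-matrix container and text-format I/O.

The universal input of the pipeline is a genes x cells matrix of raw,
non-negative integer read counts with gene/cell identifiers and a per-gene
spike-in flag.  Two plain-text formats are supported:

* Matrix Market coordinate format (``matrix.mtx``) with co-located
  ``genes.tsv`` / ``barcodes.tsv`` sidecar files (one id per line);
* dense TSV with gene ids in the first column and cell ids in the header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, ValidationError

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "flag_spikeins",
    "split_spikeins",
]


@dataclass
class CountMatrix:
    """Raw genes x cells integer counts with identifiers and spike-in flags.

    Parameters
    ----------
    counts
        Non-negative integer array, genes as rows, cells as columns.
    gene_ids, cell_ids
        Ordered unique identifiers matching the matrix dimensions.
    is_spikein
        Boolean flag per gene; all ``False`` until :func:`flag_spikeins` runs.
    dataset_id
        Free-text label (e.g. ``"huc2_p0"``) carried into reports.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    is_spikein: np.ndarray = field(default=None)  # type: ignore[assignment]
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x cells array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)):
                raise ValidationError("counts contain non-finite entries")
            rounded = np.rint(self.counts)
            if not np.array_equal(rounded, self.counts):
                raise ValidationError("counts contain non-integer entries")
            self.counts = rounded.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts contain negative entries")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell_ids")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene_ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell_ids for {n_cells} matrix columns"
            )
        if self.is_spikein is None:
            self.is_spikein = np.zeros(n_genes, dtype=bool)
        self.is_spikein = np.asarray(self.is_spikein, dtype=bool)
        if self.is_spikein.shape != (n_genes,):
            raise ValidationError("is_spikein length must equal gene count")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            is_spikein=self.is_spikein[idx],
            dataset_id=self.dataset_id,
        )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "mtx" if path.suffix == ".mtx" else "tsv"


def read_counts(path: str | Path, fmt: str | None = None, dataset_id: str = "") -> CountMatrix:
    """Read a count matrix from ``mtx`` (+ sidecars) or dense ``tsv``.

    Identifier order is preserved from the files; negative or non-integer
    entries are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        genes_file = path.parent / "genes.tsv"
        barcodes_file = path.parent / "barcodes.tsv"
        if not genes_file.exists() or not barcodes_file.exists():
            raise FormatError(
                f"mtx sidecars genes.tsv/barcodes.tsv not found next to {path}"
            )
        mat = scipy.io.mmread(path)
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_ids = genes_file.read_text().splitlines()
        cell_ids = barcodes_file.read_text().splitlines()
        gene_ids = [g.split("\t")[0] for g in gene_ids if g]
        cell_ids = [c.split("\t")[0] for c in cell_ids if c]
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise FormatError(f"unknown format {fmt!r}; expected 'mtx' or 'tsv'")
    if len(gene_ids) != counts.shape[0] or len(cell_ids) != counts.shape[1]:
        raise ValidationError(
            f"matrix shape {counts.shape} does not match "
            f"{len(gene_ids)} genes / {len(cell_ids)} cells"
        )
    if not gene_ids or any(not g for g in gene_ids):
        raise FormatError("empty gene identifiers")
    return CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
                       dataset_id=dataset_id or path.stem)


def write_counts(cm: CountMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a count matrix in ``mtx`` (+ sidecars) or dense ``tsv`` format."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        sparse = scipy.sparse.coo_matrix(cm.counts)
        scipy.io.mmwrite(str(path), sparse, field="integer")
        (path.parent / "genes.tsv").write_text("\n".join(cm.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(cm.cell_ids) + "\n")
    elif fmt == "tsv":
        cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    else:
        raise FormatError(f"unknown format {fmt!r}; expected 'mtx' or 'tsv'")


def flag_spikeins(
    cm: CountMatrix,
    prefixes: Sequence[str] = ("ERCC-",),
    explicit_ids: Iterable[str] | None = None,
) -> CountMatrix:
    """Return a copy with ``is_spikein`` set by id prefix and/or explicit list.

    A gene is flagged iff its id starts with any prefix or appears in
    ``explicit_ids``.  Counts are unchanged.  Flagging nothing raises a
    warning because spike-in-calibrated variability detection will then fail.
    """
    if not prefixes and not explicit_ids:
        raise ValidationError("at least one prefix or explicit id required")
    explicit = set(explicit_ids or ())
    flags = np.array(
        [
            any(g.startswith(p) for p in prefixes) or g in explicit
            for g in cm.gene_ids
        ],
        dtype=bool,
    )
    if not flags.any():
        warnings.warn(
            "no genes matched the spike-in prefixes; spike-in-based "
            "variability calibration will not be possible",
            stacklevel=2,
        )
    return replace(cm, counts=cm.counts.copy(), is_spikein=flags)


def split_spikeins(cm: CountMatrix) -> tuple[CountMatrix, CountMatrix]:
    """Partition into (endogenous, spikes); gene order preserved, cells shared."""
    return cm.subset_genes(~cm.is_spikein), cm.subset_genes(cm.is_spikein)
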