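"""Median-of-ratios size factors, normalization, and the low-expression filter.

Sequencing depth is corrected with the classic median-of-ratios estimator:
the reference for gene g is its geometric mean across cells, and a cell's
size factor is the median over reference genes of the count/reference ratio.
Reference genes must be strictly positive in every cell; spike-ins are
excluded by default because they track technical capture, not depth.
Normalized values are counts / size factor, and all downstream correlation
work is on log2(value + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, ValidationError
from .matrix import CountMatrix

__all__ = [
    "SizeFactors",
    "NormalizedMatrix",
    "size_factors",
    "normalize",
    "low_expression_filter",
]


@dataclass
class SizeFactors:
    s: np.ndarray  # per-cell positive reals
    reference_gene_count: int

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s <= 0) or not np.all(np.isfinite(self.s)):
            raise ValidationError("size factors must be finite and > 0")


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized expression with its log2(x+1) transform."""

    values: np.ndarray  # genes x cells, counts / size factor
    log_values: np.ndarray  # log2(values + 1)
    gene_ids: list[str]
    cell_ids: list[str]
    is_spikein: np.ndarray
    filter_mask: np.ndarray  # True where the gene passed the low-expression filter
    dataset_id: str = ""

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def size_factors(
    cm: CountMatrix,
    exclude_spikeins: bool = True,
    rescale: bool = True,
) -> SizeFactors:
    """Median-of-ratios size factors.

    Parameters
    ----------
    exclude_spikeins
        Drop spike-in rows from the reference gene set (default).
    rescale
        Rescale the factors to geometric mean 1 for cross-run comparability.
        Factors are identified up to a global constant (scaling one cell's
        counts by c scales its factor relative to the others by exactly c
        when the reference gene set is unchanged).
    """
    if cm.n_cells < 2:
        raise EstimationError("size-factor estimation needs at least 2 cells")
    counts = cm.counts
    if exclude_spikeins and cm.is_spikein.any():
        counts = counts[~cm.is_spikein]
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise EstimationError(
            "no gene has strictly positive counts in every cell; "
            "median-of-ratios reference is empty"
        )
    ref = counts[positive].astype(float)
    log_geo_mean = np.mean(np.log(ref), axis=1)
    ratios = np.exp(np.log(ref) - log_geo_mean[:, None])
    s = np.median(ratios, axis=0)
    if rescale:
        s = s / np.exp(np.mean(np.log(s)))
    return SizeFactors(s=s, reference_gene_count=int(positive.sum()))


def normalize(cm: CountMatrix, sf: SizeFactors) -> NormalizedMatrix:
    """Divide counts by size factors; attach log2(x+1) values."""
    if len(sf.s) != cm.n_cells:
        raise ValidationError("size-factor length does not match cell count")
    values = cm.counts / sf.s[None, :]
    return NormalizedMatrix(
        values=values,
        log_values=np.log2(values + 1.0),
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
        is_spikein=cm.is_spikein.copy(),
        filter_mask=np.ones(cm.n_genes, dtype=bool),
        dataset_id=cm.dataset_id,
    )


def low_expression_filter(cm: CountMatrix) -> np.ndarray:
    """Keep genes detected (count > 0) in >= ceil(n_cells/10) cells with a
    mean raw count across cells >= 1."""
    if cm.n_cells < 10:
        warnings.warn(
            f"low-expression filter on {cm.n_cells} cells; the 1/10-cells "
            "detection rule is intended for >= 10 cells",
            stacklevel=2,
        )
    min_cells = int(np.ceil(cm.n_cells / 10))
    detected = (cm.counts > 0).sum(axis=1) >= min_cells
    abundant = cm.counts.mean(axis=1) >= 1.0
    return detected & abundant
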