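"""Cell-cycle signature scoring and phase classification.

Each cell is scored for a G1/S and a G2/M signature by the expression-bin
control-pool method: genes are binned by mean log expression, and a
signature gene's relative expression in a cell is its log value minus the
mean log value of the non-signature genes in its bin.  A cell's score for a
set is the mean relative expression over the set's resolvable genes,
centered to mean 0 across cells.  Cells with both scores at or below the
threshold are noncycling; otherwise the phase is the argmax of the two
scores (ties toward G1/S).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GeneSetError, ValidationError
from .normalize import NormalizedMatrix

__all__ = [
    "GeneSet",
    "read_gene_sets",
    "default_cycle_gene_sets",
    "phase_scores",
    "classify_cells",
    "gene_phase_association",
]

MIN_RESOLVABLE = 5


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Two-column TSV (set_name, gene_id) -> {name: GeneSet}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"],
                     comment="#", dtype=str)
    return {
        name: GeneSet(name=name, genes=frozenset(sub["gene"]))
        for name, sub in df.groupby("set", sort=True)
    }


def default_cycle_gene_sets() -> tuple[GeneSet, GeneSet]:
    """The editable G1/S and G2/M signature lists shipped with the package
    (human gene symbols)."""
    path = Path(__file__).parent / "data" / "cell_cycle_genesets.tsv"
    sets = read_gene_sets(path)
    return sets["G1S"], sets["G2M"]


def phase_scores(
    nm: NormalizedMatrix,
    gs_g1s: GeneSet,
    gs_g2m: GeneSet,
    n_bins: int = 25,
) -> pd.DataFrame:
    """Per-cell G1/S and G2/M relative-expression scores (cells x 2)."""
    gene_pos = {g: i for i, g in enumerate(nm.gene_ids)}
    sig_idx = {}
    for gs in (gs_g1s, gs_g2m):
        idx = [gene_pos[g] for g in sorted(gs.genes) if g in gene_pos]
        if len(idx) < MIN_RESOLVABLE:
            raise GeneSetError(
                f"gene set {gs.name!r}: only {len(idx)} of {len(gs.genes)} "
                f"genes resolvable (need >= {MIN_RESOLVABLE})"
            )
        sig_idx[gs.name] = np.array(idx)
    all_sig = set(sig_idx[gs_g1s.name]) | set(sig_idx[gs_g2m.name])

    L = nm.log_values
    mean_expr = L.mean(axis=1)
    n_genes = len(mean_expr)
    bins = min(n_bins, n_genes)
    # equal-occupancy bins on the rank of mean expression
    order = np.argsort(mean_expr, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = (np.arange(n_genes) * bins) // n_genes

    scores = {}
    for gs in (gs_g1s, gs_g2m):
        idx = sig_idx[gs.name]
        rel = np.zeros((len(idx), nm.n_cells))
        for row, gi in enumerate(idx):
            pool = np.flatnonzero((bin_of == bin_of[gi]))
            pool = np.array([p for p in pool if p not in all_sig])
            if pool.size == 0:  # fall back to the full bin
                pool = np.flatnonzero(bin_of == bin_of[gi])
            rel[row] = L[gi] - L[pool].mean(axis=0)
        s = rel.mean(axis=0)
        scores[gs.name] = s - s.mean()  # center across cells
    return pd.DataFrame(
        {"score_g1s": scores[gs_g1s.name], "score_g2m": scores[gs_g2m.name]},
        index=pd.Index(nm.cell_ids, name="cell_id"),
    )


def classify_cells(scores: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Append a phase_call column: noncycling if both scores <= threshold,
    else the argmax phase (ties toward G1/S)."""
    g1s = scores["score_g1s"].to_numpy()
    g2m = scores["score_g2m"].to_numpy()
    call = np.where(
        np.maximum(g1s, g2m) <= threshold,
        "noncycling",
        np.where(g2m > g1s, "G2/M", "G1/S"),
    )
    out = scores.copy()
    out["phase_call"] = call
    out.attrs["threshold"] = threshold
    return out


def gene_phase_association(
    nm: NormalizedMatrix, gene: str, classified: pd.DataFrame
) -> dict:
    """Enrichment of a gene's high-expressing cells (upper quartile) in G2/M.

    Returns odds ratio and two-sided Fisher exact p for the 2x2 table
    (high vs rest) x (G2/M vs rest); degenerate margins give NaN odds ratio.
    """
    if gene not in nm.gene_ids:
        raise GeneSetError(f"gene {gene!r} not in the matrix")
    if classified["phase_call"].nunique() < 2:
        raise ValidationError("need at least 2 distinct phase calls")
    x = nm.values[nm.gene_ids.index(gene)]
    q75 = np.quantile(x, 0.75)
    high = x > q75
    g2m = classified["phase_call"].to_numpy() == "G2/M"
    table = np.array([
        [int(np.sum(high & g2m)), int(np.sum(high & ~g2m))],
        [int(np.sum(~high & g2m)), int(np.sum(~high & ~g2m))],
    ])
    degenerate = bool((table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any())
    if degenerate:
        return {"odds_ratio": np.nan, "p": 1.0, "table": table, "flag": "degenerate"}
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"odds_ratio": float(odds), "p": float(p), "table": table, "flag": ""}
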