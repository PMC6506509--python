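"""Signed weighted co-expression network and module detection.

The signed adjacency between genes i and j is a_ij = ((1 + cor_ij)/2)^beta
(Pearson correlation of log values over cells; soft power beta, default 12),
which suppresses negative correlation.  Pairwise similarity is the
topological overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

and modules are branches of the average-linkage dendrogram of 1 - TOM cut
by a dynamic-hybrid-style procedure: a static cut at a fraction of the
merge-height range yields candidate branches of at least ``min_module_size``
genes, after which unassigned genes whose eigengene correlation exceeds 0.3
are pulled into the closest module.  Modules get deterministic size-ordered
display names (largest = "turquoise", second = "blue", ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .normalize import NormalizedMatrix

__all__ = [
    "NetworkMatrices",
    "ModuleSet",
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "module_trait_significance",
    "eigengene_correlation",
    "node_centrality",
    "top_edges",
]

UNASSIGNED = "unassigned"

# WGCNA-style display palette, assigned by decreasing module size
PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


@dataclass
class NetworkMatrices:
    adjacency: np.ndarray  # genes x genes in [0, 1], unit diagonal
    connectivity: np.ndarray  # k_i = sum_{j != i} a_ij
    beta: float
    gene_ids: list[str]
    tom: np.ndarray | None = None


@dataclass
class ModuleSet:
    labels: np.ndarray  # per-gene display name or "unassigned"
    gene_ids: list[str]

    @property
    def module_names(self) -> list[str]:
        """Module display names ordered by decreasing size."""
        names = [n for n in PALETTE if n in self.labels]
        extra = sorted(set(self.labels) - set(names) - {UNASSIGNED})
        return names + extra

    def sizes(self) -> dict[str, int]:
        return {m: int(np.sum(self.labels == m)) for m in self.module_names}

    def members(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.labels == name)


def signed_adjacency(
    nm: NormalizedMatrix, gene_set: np.ndarray, beta: float = 12.0
) -> NetworkMatrices:
    """a_ij = ((1 + cor(x_i, x_j))/2)^beta on log values over cells."""
    gene_set = np.asarray(gene_set)
    if gene_set.dtype == bool:
        gene_set = np.flatnonzero(gene_set)
    if len(gene_set) < 3:
        raise ValidationError("need at least 3 genes for a network")
    if beta < 1:
        raise ValidationError(f"soft power must be >= 1, got {beta}")
    X = nm.log_values[gene_set]
    sd = X.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance genes; their correlations "
            "are set to 0",
            stacklevel=2,
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    C = (Xc / norm[:, None]) @ (Xc / norm[:, None]).T
    C = np.clip(C, -1.0, 1.0)
    C[zero_var, :] = 0.0
    C[:, zero_var] = 0.0
    A = ((1.0 + C) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    k = A.sum(axis=1) - 1.0  # exclude the unit diagonal
    return NetworkMatrices(
        adjacency=A, connectivity=k, beta=beta,
        gene_ids=[nm.gene_ids[i] for i in gene_set],
    )


def topological_overlap(net: NetworkMatrices) -> np.ndarray:
    """TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    A = net.adjacency.copy()
    np.fill_diagonal(A, 0.0)
    shared = A @ A  # entry ij sums over all u; u = i,j contribute 0 off-diagonal
    k = net.connectivity
    kmin = np.minimum.outer(k, k)
    tom = (shared + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    net.tom = tom
    return tom


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    deep_split: int = 2,
    log_values: np.ndarray | None = None,
    reassign_threshold: float = 0.3,
) -> ModuleSet:
    """Cut the 1 - TOM dendrogram into modules (dynamic-hybrid style).

    ``log_values`` (rows aligned with ``gene_ids``) enables the second,
    PAM-like stage that reassigns unassigned genes to the module whose
    eigengene they correlate with beyond ``reassign_threshold``.
    """
    n = tom.shape[0]
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    heights = Z[:, 2]
    frac = 0.98 - 0.03 * deep_split
    cut = float(heights.min() + (heights.max() - heights.min()) * frac)
    branches = hierarchy.fcluster(Z, t=cut, criterion="distance")
    uniq, counts = np.unique(branches, return_counts=True)
    keep = uniq[counts >= min_module_size]
    labels = np.full(n, UNASSIGNED, dtype=object)
    # size-ordered provisional ids; display names assigned after reassignment
    keep = keep[np.argsort(-counts[np.isin(uniq, keep)], kind="stable")]
    for rank, b in enumerate(keep):
        labels[branches == b] = f"M{rank}"
    if not keep.size:
        warnings.warn("no branch reached min_module_size; all genes unassigned",
                      stacklevel=2)
        return ModuleSet(labels=labels, gene_ids=list(gene_ids))
    if log_values is not None:
        provisional = ModuleSet(labels=labels.copy(), gene_ids=list(gene_ids))
        eig = _eigengenes_from_values(log_values, provisional)
        un = np.flatnonzero(labels == UNASSIGNED)
        if un.size and not eig.empty:
            X = log_values[un]
            cors = np.column_stack(
                [_row_cor(X, eig[m].to_numpy()) for m in eig.columns]
            )
            best = np.argmax(cors, axis=1)
            ok = cors[np.arange(len(un)), best] > reassign_threshold
            labels[un[ok]] = eig.columns.to_numpy()[best[ok]]
    # final display names by decreasing size
    mods = [m for m in np.unique(labels) if m != UNASSIGNED]
    sizes = {m: int(np.sum(labels == m)) for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], m))
    rename = {m: PALETTE[i] if i < len(PALETTE) else f"module{i}"
              for i, m in enumerate(order)}
    labels = np.array([rename.get(v, v) for v in labels], dtype=object)
    return ModuleSet(labels=labels, gene_ids=list(gene_ids))


def _row_cor(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with vector y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    denom[denom == 0] = np.inf
    return (Xc @ yc) / denom


def _eigengenes_from_values(log_values: np.ndarray, ms: ModuleSet) -> pd.DataFrame:
    cols = {}
    for m in ms.module_names:
        idx = ms.members(m)
        if len(idx) < 1:
            continue
        X = log_values[idx]
        sd = X.std(axis=1)
        sd[sd == 0] = 1.0
        Xz = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        # first right singular vector over cells
        _, _, vt = np.linalg.svd(Xz, full_matrices=False)
        e = vt[0]
        mean_cor = float(np.mean(_row_cor(X, e)))
        if mean_cor < 0:
            e = -e
        cols[m] = e
    return pd.DataFrame(cols)


def module_eigengenes(nm: NormalizedMatrix, ms: ModuleSet) -> pd.DataFrame:
    """First principal component per module over standardized gene profiles.

    Returns a cells x modules table; each eigengene has unit norm and is
    oriented so its mean correlation with the module's genes is positive.
    """
    order = {g: i for i, g in enumerate(nm.gene_ids)}
    idx = np.array([order[g] for g in ms.gene_ids])
    eig = _eigengenes_from_values(nm.log_values[idx], ms)
    eig.index = pd.Index(nm.cell_ids, name="cell_id")
    return eig


def module_trait_significance(
    eigengenes: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Pearson r (and Student-t p) of each eigengene vs one-hot subcluster
    indicators; rows = modules, columns = MultiIndex (group, {r, p})."""
    labels = np.asarray(labels)
    n = len(labels)
    if n != len(eigengenes):
        raise ValidationError("label length does not match eigengene cells")
    out = {}
    for g in np.unique(labels):
        ind = (labels == g).astype(float)
        rs, ps = [], []
        for m in eigengenes.columns:
            e = eigengenes[m].to_numpy()
            if ind.sum() < 2 or n - ind.sum() < 1 or ind.std() == 0:
                rs.append(np.nan)
                ps.append(np.nan)
                continue
            r, p = stats.pearsonr(e, ind)
            rs.append(r)
            ps.append(p)
        out[(str(g), "r")] = rs
        out[(str(g), "p")] = ps
    return pd.DataFrame(out, index=pd.Index(eigengenes.columns, name="module"))


def eigengene_correlation(eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Module x module Pearson correlation of eigengenes."""
    if eigengenes.shape[1] < 2:
        raise ValidationError("need at least 2 modules")
    return eigengenes.corr(method="pearson")


def node_centrality(net: NetworkMatrices, ms: ModuleSet) -> pd.DataFrame:
    """Within-module connectivity kWithin_i = sum_{j in module(i), j != i} a_ij,
    ranked descending within each module."""
    A = net.adjacency
    kwithin = np.zeros(len(ms.labels))
    for m in ms.module_names:
        idx = ms.members(m)
        sub = A[np.ix_(idx, idx)]
        kwithin[idx] = sub.sum(axis=1) - 1.0  # remove unit diagonal
    df = pd.DataFrame(
        {"module": ms.labels, "kwithin": kwithin},
        index=pd.Index(ms.gene_ids, name="gene_id"),
    )
    df["rank"] = (
        df.groupby("module")["kwithin"].rank(ascending=False, method="first").astype(int)
    )
    df.loc[df["module"] == UNASSIGNED, "rank"] = 0
    return df


def top_edges(net: NetworkMatrices, n: int = 150) -> pd.DataFrame:
    """The n largest off-diagonal TOM entries as (gene_i, gene_j, weight).

    Sorted non-increasing by weight; ties broken by lexicographic gene ids.
    If fewer than n edges exist, all are returned.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    tom = net.tom if net.tom is not None else topological_overlap(net)
    iu, ju = np.triu_indices(tom.shape[0], k=1)
    rows = sorted(
        zip(tom[iu, ju], (net.gene_ids[i] for i in iu), (net.gene_ids[j] for j in ju)),
        key=lambda t: (-t[0], t[1], t[2]),
    )[:n]
    return pd.DataFrame(
        [(a, b, w) for w, a, b in rows], columns=["source", "target", "weight"]
    )
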