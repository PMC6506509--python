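"""Permutation Z-statistics for cross-dataset module preservation.

For each reference module the test dataset yields two density statistics
(mean off-diagonal correlation among module genes; mean signed adjacency)
and two connectivity statistics (correlation of intramodular connectivity
between the datasets; correlation of the vectorized module gene-gene
correlation matrices).  Each is standardized against a permutation null of
random same-size gene sets drawn (without replacement, excluding the module
itself) from the shared expressed gene universe:

    Z = (observed - null mean) / null SD
    Zdensity      = median of the density Zs
    Zconnectivity = median of the connectivity Zs
    Zsummary      = mean(Zdensity, Zconnectivity)

Zsummary >= 10 is the conventional strong-preservation bound.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import ModuleSet
from .normalize import NormalizedMatrix

__all__ = ["module_preservation"]


def _corr(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    C = (Xc / norm[:, None]) @ (Xc / norm[:, None]).T
    return np.clip(C, -1.0, 1.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _module_stats(Xr: np.ndarray, Xt: np.ndarray, beta: float) -> np.ndarray:
    """(meanCor, meanAdj, cor.kIM, cor.cor) for one gene set."""
    Cr, Ct = _corr(Xr), _corr(Xt)
    m = Cr.shape[0]
    off = ~np.eye(m, dtype=bool)
    mean_cor = float(Ct[off].mean())
    At = ((1.0 + Ct) / 2.0) ** beta
    mean_adj = float(At[off].mean())
    Ar = ((1.0 + Cr) / 2.0) ** beta
    kim_r = Ar.sum(axis=1) - 1.0
    kim_t = At.sum(axis=1) - 1.0
    iu = np.triu_indices(m, k=1)
    return np.array([
        mean_cor,
        mean_adj,
        _pearson(kim_r, kim_t),
        _pearson(Cr[iu], Ct[iu]),
    ])


def module_preservation(
    reference: NormalizedMatrix,
    modules: ModuleSet,
    test: NormalizedMatrix,
    beta: float = 12.0,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Z-summary preservation of reference modules in a test dataset.

    Gene universes are intersected; modules smaller than 3 genes after
    intersection are reported with NaN statistics rather than raising.
    """
    if n_perm < 50:
        raise ValidationError(f"n_perm must be >= 50, got {n_perm}")
    shared = sorted(set(reference.gene_ids) & set(test.gene_ids))
    if len(shared) < 10:
        raise ValidationError("shared gene universe too small")
    ref_idx = {g: i for i, g in enumerate(reference.gene_ids)}
    test_idx = {g: i for i, g in enumerate(test.gene_ids)}
    mod_of = dict(zip(modules.gene_ids, modules.labels))
    Xr = reference.log_values[[ref_idx[g] for g in shared]]
    Xt = test.log_values[[test_idx[g] for g in shared]]
    pos = {g: i for i, g in enumerate(shared)}

    rng = np.random.default_rng(seed)
    stat_names = ["Z.meanCor", "Z.meanAdj", "Z.cor.kIM", "Z.cor.cor"]
    rows = []
    for name in modules.module_names:
        members = [g for g in modules.gene_ids
                   if mod_of[g] == name and g in pos]
        size = len(members)
        row: dict = {"module": name, "size": size,
                     "n_permutations": n_perm, "seed": seed}
        if size < 3:
            rows.append({**row, "Zsummary": np.nan, "Zdensity": np.nan,
                         "Zconnectivity": np.nan,
                         **{s: np.nan for s in stat_names}})
            continue
        idx = np.array([pos[g] for g in members])
        obs = _module_stats(Xr[idx], Xt[idx], beta)
        pool = np.array([i for i in range(len(shared)) if i not in set(idx)])
        null = np.empty((n_perm, 4))
        for b in range(n_perm):
            rand = rng.choice(pool, size=size, replace=False)
            null[b] = _module_stats(Xr[rand], Xt[rand], beta)
        mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (obs - mu) / sd, np.nan)
        zdensity = float(np.nanmedian(z[:2]))
        zconn = float(np.nanmedian(z[2:]))
        rows.append({
            **row,
            "Zsummary": (zdensity + zconn) / 2.0,
            "Zdensity": zdensity,
            "Zconnectivity": zconn,
            **dict(zip(stat_names, z)),
        })
    df = pd.DataFrame(rows).set_index("module")
    return df[[c for c in ["size", "Zsummary", "Zdensity", "Zconnectivity",
                           *stat_names, "n_permutations", "seed"]]]
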