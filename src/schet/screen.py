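"""Featured-gene screen and gene-set over-representation.

The screen looks for subpopulation markers inside the two dominant
co-expression modules: a candidate passes iff it (1) is specifically
overexpressed in exactly one subcluster of a dataset (one-vs-rest q below
threshold, positive fold change), (2) shows that subcluster-specific
expression in at least ``min_datasets`` datasets, and (3) is on the
user-supplied cell-surface list.  Over-representation of gene sets uses the
upper-tail hypergeometric test with Benjamini-Hochberg control and a
corrected-p < 0.05 significance rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cellcycle import GeneSet
from .errors import ValidationError
from .network import ModuleSet

__all__ = ["featured_gene_screen", "hypergeometric_enrichment"]


def _candidate_pool(modules_by_dataset: dict[str, ModuleSet]) -> set[str]:
    """Genes in the two largest (turquoise/blue) modules of any dataset."""
    pool: set[str] = set()
    for ms in modules_by_dataset.values():
        for name in ms.module_names[:2]:
            pool.update(np.array(ms.gene_ids)[ms.members(name)])
    return pool


def _specific_subcluster(de_by_group: dict, gene: str, q_threshold: float):
    """The single subcluster where the gene is up (q < thr, log2fc > 0), or None."""
    hits = []
    for group, df in de_by_group.items():
        if gene not in df.index:
            continue
        row = df.loc[gene]
        if row["q"] < q_threshold and row["log2fc"] > 0:
            hits.append((group, float(row["log2fc"]), float(row["q"])))
    return hits[0] if len(hits) == 1 else None


def featured_gene_screen(
    de_by_dataset: dict[str, dict],
    modules_by_dataset: dict[str, ModuleSet],
    surface_genes: GeneSet,
    min_datasets: int = 2,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Three-criterion featured-gene screen across datasets.

    Parameters
    ----------
    de_by_dataset
        ``{dataset: {subcluster: DE table}}`` with one-vs-rest DE tables
        (gene-indexed, columns log2fc/p/q) per subcluster.
    modules_by_dataset
        ``{dataset: ModuleSet}``; the two largest modules form the pool.
    surface_genes
        Cell-surface gene list (criterion 3); user input, never hard-coded.

    Returns a per-candidate report retaining near-misses with the failed
    criterion named.
    """
    if len(de_by_dataset) < 2:
        raise ValidationError("screen needs >= 2 datasets with DE results")
    datasets = sorted(de_by_dataset)
    surface = set(surface_genes.genes)
    if not surface:
        warnings.warn("empty surface list: criterion 3 fails for every gene",
                      stacklevel=2)
    rows = []
    for gene in sorted(_candidate_pool(modules_by_dataset)):
        evidence = {}
        for ds in datasets:
            hit = _specific_subcluster(de_by_dataset[ds], gene, q_threshold)
            if hit is not None:
                evidence[ds] = hit
        n_support = len(evidence)
        c1 = n_support >= 1
        c2 = n_support >= min_datasets
        c3 = gene in surface
        if not c1:
            reason = "criterion 1"
        elif not c2:
            reason = "criterion 2"
        elif not c3:
            reason = "criterion 3"
        else:
            reason = ""
        row = {
            "gene_id": gene,
            "n_datasets_supporting": n_support,
            "surface_flag": c3,
            "passed": c1 and c2 and c3,
            "failure_reason": reason,
        }
        for ds in datasets:
            if ds in evidence:
                grp, lfc, q = evidence[ds]
                row[f"{ds}_subcluster"] = str(grp)
                row[f"{ds}_log2fc"] = lfc
                row[f"{ds}_q"] = q
            else:
                row[f"{ds}_subcluster"] = ""
                row[f"{ds}_log2fc"] = np.nan
                row[f"{ds}_q"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def hypergeometric_enrichment(
    query: set[str],
    background: set[str],
    terms: dict[str, GeneSet],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each term in the query.

    Terms are intersected with the background first; terms that become empty
    are recorded with ``tested = False``.  p = P(X >= k) for overlap k, term
    size K, query size n, background size N; BH across tested terms.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValidationError("query must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for name in sorted(terms):
        term_genes = terms[name].genes & background
        K = len(term_genes)
        k = len(term_genes & query)
        if K == 0:
            rows.append((name, 0, 0, n, N, np.nan, False))
            continue
        p = 1.0 if (n == 0 or k == 0) else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p, True))
    df = pd.DataFrame(
        rows,
        columns=["term", "overlap", "set_size", "query_size",
                 "background_size", "p", "tested"],
    ).set_index("term")
    df["q"] = np.nan
    tested = df["tested"].to_numpy()
    if tested.any():
        df.loc[tested, "q"] = multipletests(
            df.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    df["significant"] = df["q"] < alpha
    return df
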