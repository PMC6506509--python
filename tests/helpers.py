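"""Shared test utilities: standard synthetic conditions and preprocessing."""

from __future__ import annotations

import numpy as np

from schet import (
    SyntheticConfig,
    generate_dataset,
    generate_dataset_pair,
    low_expression_filter,
    normalize,
    size_factors,
)
from schet.cellcycle import GeneSet

# the standard parameter-recovery condition: two cell-cycle phases,
# 200 cells x 2,000 genes with 60 spike-ins
RECOVERY_KW = dict(
    n_cells=200,
    n_genes=2000,
    n_spikeins=60,
    cycle_module_size=100,
    immune_module_size=80,
    cell_depth_sd=0.3,
    phase_proportions=(0.7, 0.0, 0.3),
)


def recovery_config(seed: int, **overrides) -> SyntheticConfig:
    kw = {**RECOVERY_KW, **overrides}
    return SyntheticConfig(seed=seed, **kw)


def prep(cm):
    """Normalize a count matrix and attach the low-expression filter mask."""
    sf = size_factors(cm)
    nm = normalize(cm, sf)
    nm.filter_mask = low_expression_filter(cm) & ~cm.is_spikein
    return sf, nm


def recovery_dataset(seed: int, **overrides):
    cm, truth = generate_dataset(recovery_config(seed, **overrides))
    return cm, truth


def recovery_pair(seed: int, shared_modules=True, **overrides):
    return generate_dataset_pair(
        recovery_config(seed, **overrides), shared_modules=shared_modules
    )


def planted_gene_sets(cm, truth) -> tuple[GeneSet, GeneSet]:
    """(G1/S, G2/M) gene sets from the planted immune / cycle modules."""
    cyc = frozenset(
        g for g, m in zip(cm.gene_ids, truth.module_membership) if m == "cycle"
    )
    imm = frozenset(
        g for g, m in zip(cm.gene_ids, truth.module_membership) if m == "immune"
    )
    return GeneSet("G1S", imm), GeneSet("G2M", cyc)


def phase_call_accuracy(pred: np.ndarray, truth_phases: np.ndarray) -> float:
    """Accuracy collapsing S into G1/S and noncycling into the G1/S side."""
    pred_g2m = pred == "G2/M"
    true_g2m = truth_phases == "G2/M"
    return float(np.mean(pred_g2m == true_g2m))


def two_block_expression(seed: int, n_cells=100, block=50, background=600,
                         within_cor=0.7):
    """Planted two-block log-expression matrix + truth labels (1, 2, 0)."""
    rng = np.random.default_rng(seed)
    lam = np.sqrt(within_cor)
    eps = np.sqrt(1 - within_cor)
    f1 = rng.normal(size=n_cells)
    f2 = rng.normal(size=n_cells)
    rows, labels = [], []
    for f, lab in ((f1, 1), (f2, 2)):
        for _ in range(block):
            rows.append(lam * f + eps * rng.normal(size=n_cells))
            labels.append(lab)
    for _ in range(background):
        rows.append(rng.normal(size=n_cells))
        labels.append(0)
    return np.array(rows), np.array(labels)
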