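"""Synthetic single-cell count data with planted cell-cycle structure.

The generator emulates a microfluidics-scale single-cell RNA-seq experiment
on a culture of mesenchymal stromal cells: ~50 cells per dataset, a few
thousand genes, ERCC-style spike-in controls, cell-cycle phases driving one
gene module (up in G2/M), and an immune-regulation module moving in the
opposite direction — the inverse-correlation structure the downstream
network analysis is meant to recover.

Per gene g and cell c the expected count before dropout is

    m_gc = baseline_g * s_c * 2**(effect_g * phase_weight_c)

where s_c is the cell's true depth factor, effect_g is +cycle_log2fc for
cycle-module genes, -immune_log2fc for immune-module genes and 0 otherwise,
and phase_weight_c is 1 for G2/M cells, 0.5 for S cells (cycle genes only,
so the G1/S vs G2/M score plane is a continuum) and 0 otherwise.  Counts are
negative binomial with variance m + phi*m**2, except that with a
logistic, magnitude-decreasing probability the observation is a dropout
drawn from a low-mean Poisson.  Spike-ins have fixed concentrations scaled
by the cell's capture efficiency and no phase effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError
from .matrix import CountMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_dataset_pair",
    "write_truth",
]

PHASES = ("G0/G1", "S", "G2/M")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror the study scale (50 cells,
    5,000 genes, 92 spike-ins) and a strong G2/M signature."""

    n_cells: int = 50
    n_genes: int = 5000
    n_spikeins: int = 92
    phase_proportions: tuple[float, float, float] = (0.60, 0.15, 0.25)
    cycle_module_size: int = 100
    immune_module_size: int = 80
    cycle_log2fc: float = 1.5
    immune_log2fc: float = 1.0
    baseline_logmean_distribution: tuple[float, float] = (4.0, 2.0)
    nb_dispersion: float = 0.1
    cell_depth_sd: float = 0.3
    dropout_midpoint: float = 0.0
    dropout_slope: float = 1.0
    dropout_lambda: float = 0.1
    n_variable_genes: int = 0
    variable_lognormal_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_cells < 1 or self.n_genes < 1:
            raise ConfigError("n_cells and n_genes must be positive")
        if abs(sum(self.phase_proportions) - 1.0) > 1e-8:
            raise ConfigError("phase_proportions must sum to 1")
        if any(p < 0 for p in self.phase_proportions):
            raise ConfigError("phase_proportions must be non-negative")
        if (
            self.cycle_module_size
            + self.immune_module_size
            + self.n_variable_genes
            + self.n_spikeins
            > self.n_genes
        ):
            raise ConfigError("module sizes + spike-ins exceed n_genes")
        if self.nb_dispersion <= 0 or self.dropout_lambda <= 0:
            raise ConfigError("dispersion parameters must be > 0")
        if self.cell_depth_sd < 0 or self.variable_lognormal_sd < 0:
            raise ConfigError("spread parameters must be >= 0")
        return self


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery testing."""

    phase_labels: np.ndarray  # per cell, in PHASES
    module_membership: np.ndarray  # per gene, {cycle, immune, background, spikein}
    true_size_factors: np.ndarray  # per cell, > 0
    true_gene_means: np.ndarray  # genes x cells, expected values before dropout
    dropout_mask: np.ndarray  # boolean genes x cells
    is_variable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.is_variable is None:
            self.is_variable = np.zeros(len(self.module_membership), dtype=bool)


def _draw_membership(cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Assign module/variable/spike-in roles over the gene panel."""
    n_endo = cfg.n_genes - cfg.n_spikeins
    membership = np.full(cfg.n_genes, "background", dtype=object)
    membership[n_endo:] = "spikein"
    special = rng.choice(
        n_endo,
        size=cfg.cycle_module_size + cfg.immune_module_size + cfg.n_variable_genes,
        replace=False,
    )
    cyc = special[: cfg.cycle_module_size]
    imm = special[cfg.cycle_module_size : cfg.cycle_module_size + cfg.immune_module_size]
    var = special[cfg.cycle_module_size + cfg.immune_module_size :]
    membership[cyc] = "cycle"
    membership[imm] = "immune"
    is_variable = np.zeros(cfg.n_genes, dtype=bool)
    is_variable[var] = True
    return {"membership": membership, "is_variable": is_variable}


def _generate(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    membership: np.ndarray,
    is_variable: np.ndarray,
    baselines: np.ndarray,
    dataset_id: str,
) -> tuple[CountMatrix, SyntheticTruth]:
    n_genes, n_cells = cfg.n_genes, cfg.n_cells
    phases = rng.choice(len(PHASES), size=n_cells, p=list(cfg.phase_proportions))
    phase_labels = np.array([PHASES[i] for i in phases], dtype=object)

    size_factors = 2.0 ** rng.normal(0.0, cfg.cell_depth_sd, size=n_cells)

    effect = np.zeros(n_genes)
    effect[membership == "cycle"] = cfg.cycle_log2fc
    effect[membership == "immune"] = -cfg.immune_log2fc
    # phase weight: G2/M gets the full effect; S gets half of it on cycle genes
    weight = np.zeros((n_genes, n_cells))
    weight[:, phases == 2] = 1.0
    s_cols = phases == 1
    if s_cols.any():
        weight[np.ix_(membership == "cycle", s_cols)] = 0.5

    log2_means = (
        np.log2(baselines)[:, None]
        + np.log2(size_factors)[None, :]
        + effect[:, None] * weight
    )
    spike = membership == "spikein"
    # spike-ins: fixed concentration scaled by capture efficiency, no phase effect
    log2_means[spike] = (
        np.log2(baselines[spike])[:, None] + np.log2(size_factors)[None, :]
    )
    if is_variable.any():
        extra = rng.normal(
            0.0, cfg.variable_lognormal_sd, size=(int(is_variable.sum()), n_cells)
        )
        log2_means[is_variable] += extra

    means = 2.0 ** log2_means
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + means))

    p_drop = expit(-cfg.dropout_slope * (log2_means - cfg.dropout_midpoint))
    dropout = rng.random(size=means.shape) < p_drop
    counts[dropout] = rng.poisson(cfg.dropout_lambda, size=int(dropout.sum()))

    n_endo = n_genes - cfg.n_spikeins
    gene_ids = [f"G{i:05d}" for i in range(n_endo)] + [
        f"ERCC-{i:05d}" for i in range(cfg.n_spikeins)
    ]
    cell_ids = [f"{dataset_id}_C{j:03d}" for j in range(n_cells)]
    cm = CountMatrix(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        is_spikein=spike.copy(),
        dataset_id=dataset_id,
    )
    truth = SyntheticTruth(
        phase_labels=phase_labels,
        module_membership=membership.copy(),
        true_size_factors=size_factors,
        true_gene_means=means,
        dropout_mask=dropout,
        is_variable=is_variable.copy(),
    )
    return cm, truth


def generate_dataset(
    cfg: SyntheticConfig, dataset_id: str = "sim"
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate one dataset with planted phases, modules and dropout."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    roles = _draw_membership(cfg, rng)
    loc, scale = cfg.baseline_logmean_distribution
    baselines = 2.0 ** rng.normal(loc, scale, size=cfg.n_genes)
    return _generate(
        cfg, rng, roles["membership"], roles["is_variable"], baselines, dataset_id
    )


def generate_dataset_pair(
    cfg: SyntheticConfig,
    shared_modules: bool = True,
    dataset_ids: tuple[str, str] = ("simA", "simB"),
) -> list[tuple[CountMatrix, SyntheticTruth]]:
    """Two independent datasets over an identical gene panel.

    With ``shared_modules`` the planted module memberships are identical in
    both datasets (the preserved-module setting); otherwise the second
    dataset's module gene sets are re-drawn at random.
    """
    cfg.validate()
    master = np.random.default_rng(cfg.seed)
    roles = _draw_membership(cfg, master)
    out = []
    for i, ds in enumerate(dataset_ids):
        rng = np.random.default_rng([cfg.seed, i + 1])
        if i == 1 and not shared_modules:
            roles_i = _draw_membership(cfg, rng)
        else:
            roles_i = roles
        loc, scale = cfg.baseline_logmean_distribution
        baselines = 2.0 ** rng.normal(loc, scale, size=cfg.n_genes)
        out.append(
            _generate(
                cfg, rng, roles_i["membership"], roles_i["is_variable"], baselines, ds
            )
        )
    return out


def write_truth(truth: SyntheticTruth, cm: CountMatrix, outdir: str | Path) -> None:
    """Write ground-truth tables (cell phase, gene module) as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"cell_id": cm.cell_ids, "phase": truth.phase_labels}
    ).to_csv(outdir / "truth_phases.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "module": truth.module_membership,
            "is_variable": truth.is_variable.astype(int),
        }
    ).to_csv(outdir / "truth_modules.tsv", sep="\t", index=False)
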