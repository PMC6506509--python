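"""End-to-end pipeline: normalize -> HVG -> subgroups -> markers -> network
-> preservation -> cell cycle -> screen -> enrichment.

Every stage writes its tables under ``outdir`` (per-dataset subdirectories
for dataset-level stages) and a machine-readable ``run_log.json`` records
the seed, all parameters and the config hash, so any reported number is
traceable.  A stage failure raises :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellcycle as cc
from . import error_model, network, preservation
from . import screen as screen_mod
from . import subgroups as sg
from . import variability
from .normalize import low_expression_filter, normalize as normalize_counts, size_factors
from .config import PipelineConfig
from .errors import PipelineError
from .matrix import CountMatrix, flag_spikeins
from .normalize import NormalizedMatrix

__all__ = ["run_pipeline"]

FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


class _Stage:
    """Context manager that renames any error with the failing stage."""

    def __init__(self, name: str, log: dict):
        self.name = name
        self.log = log

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        self.log.setdefault("stages_completed", []).append(self.name)
        return False


def _dataset_stages(
    cm: CountMatrix, config: PipelineConfig, ds_dir: Path, log: dict
) -> dict:
    """Run all single-dataset stages; returns intermediate state."""
    state: dict = {}
    with _Stage(f"normalize[{cm.dataset_id}]", log):
        cm = flag_spikeins(cm, config.spikein_prefixes, config.spikein_ids or None)
        mask = low_expression_filter(cm)
        sf = size_factors(
            cm,
            exclude_spikeins=config.exclude_spikeins_from_size_factors,
            rescale=config.rescale_size_factors,
        )
        nm = normalize_counts(cm, sf)
        nm.filter_mask = mask & ~cm.is_spikein
        state.update(cm=cm, sf=sf, nm=nm)
        pd.DataFrame({"cell_id": cm.cell_ids, "size_factor": sf.s}).to_csv(
            ds_dir / "size_factors.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT,
        )
        pd.DataFrame(
            {"gene_id": cm.gene_ids, "passed_filter": mask.astype(int)}
        ).to_csv(ds_dir / "filter_mask.tsv", sep="\t", index=False)
        _write(
            pd.DataFrame(nm.values, index=pd.Index(cm.gene_ids, name="gene_id"),
                         columns=cm.cell_ids),
            ds_dir / "normalized.tsv",
        )
    with _Stage(f"hvg[{cm.dataset_id}]", log):
        fit = variability.fit_spikein_trend(nm)
        hvg = variability.call_hvgs(nm, fit, fdr=config.hvg_fdr)
        state.update(trend=fit, hvg=hvg)
        _write(hvg, ds_dir / "hvg_table.tsv")
        log.setdefault("trend_fits", {})[cm.dataset_id] = {
            "a1": fit.a1, "a0": fit.a0, "n_spikeins_used": fit.n_spikeins_used,
        }
    hvg_idx = np.flatnonzero(hvg["is_hvg"].to_numpy())
    if len(hvg_idx) < max(3, config.min_module_size):
        # fall back to the most deviant filter-passing genes so downstream
        # stages remain runnable on weakly structured data
        eligible = np.flatnonzero(nm.filter_mask)
        order = np.argsort(hvg["p"].to_numpy()[eligible], kind="stable")
        hvg_idx = eligible[order[: max(50, 2 * config.min_module_size)]]
    state["hvg_idx"] = hvg_idx
    with _Stage(f"cluster[{cm.dataset_id}]", log):
        assign = sg.cluster_cells(
            nm, hvg_idx, K=config.n_clusters, max_clusters=config.max_clusters
        )
        emb = sg.pca_embed(
            nm, hvg_idx,
            n_components=min(config.n_pca_components, len(hvg_idx), nm.n_cells),
        )
        state.update(assign=assign, embedding=emb)
        pd.DataFrame({"cell_id": cm.cell_ids, "group": assign.labels}).to_csv(
            ds_dir / "clusters.tsv", sep="\t", index=False
        )
        emb_df = pd.DataFrame(
            emb.coordinates,
            index=pd.Index(cm.cell_ids, name="cell_id"),
            columns=[f"PC{i + 1}" for i in range(emb.coordinates.shape[1])],
        )
        _write(emb_df, ds_dir / "embedding.tsv")
        _write(
            pd.DataFrame(assign.linkage_tree,
                         columns=["child_a", "child_b", "height", "size"]),
            ds_dir / "linkage.tsv",
        )
    with _Stage(f"de[{cm.dataset_id}]", log):
        de_by_group: dict[str, pd.DataFrame] = {}
        gene_ids = [nm.gene_ids[i] for i in hvg_idx]
        counts_hvg = cm.counts[hvg_idx]
        for g in range(1, assign.K + 1):
            in_g = assign.labels == g
            if in_g.sum() < 5 or (~in_g).sum() < 5:
                continue
            df = error_model.de_table(
                counts_hvg[:, in_g], counts_hvg[:, ~in_g], gene_ids,
                sf_a=state["sf"].s[in_g], sf_b=state["sf"].s[~in_g],
                lam0=config.dropout_lambda,
            )
            de_by_group[str(g)] = df
            _write(df, ds_dir / f"de_group{g}_vs_rest.tsv")
        state["de"] = de_by_group
    with _Stage(f"network[{cm.dataset_id}]", log):
        net = network.signed_adjacency(nm, hvg_idx, beta=config.soft_power)
        tom = network.topological_overlap(net)
        ms = network.detect_modules(
            tom, net.gene_ids,
            min_module_size=min(config.min_module_size, max(3, len(hvg_idx) // 3)),
            deep_split=config.deep_split,
            log_values=nm.log_values[hvg_idx],
        )
        eig = network.module_eigengenes(nm, ms)
        centrality = network.node_centrality(net, ms)
        state.update(net=net, modules=ms, eigengenes=eig)
        _write(centrality, ds_dir / "modules.tsv")
        _write(eig, ds_dir / "eigengenes.tsv")
        if not eig.empty:
            mt = network.module_trait_significance(eig, assign.labels)
            mt.columns = [f"group{g}_{s}" for g, s in mt.columns]
            _write(mt, ds_dir / "module_trait.tsv")
        if eig.shape[1] >= 2:
            _write(network.eigengene_correlation(eig),
                   ds_dir / "eigengene_correlation.tsv")
        edges = network.top_edges(net, n=config.n_top_edges)
        edges.to_csv(ds_dir / "edges.tsv", sep="\t", index=False,
                     float_format=FLOAT_FMT)
    return state


def run_pipeline(
    config: PipelineConfig,
    counts_by_dataset: dict[str, CountMatrix],
    outdir: str | Path,
    genesets_path: str | Path | None = None,
    surface_path: str | Path | None = None,
    terms_path: str | Path | None = None,
    reference_dataset: str | None = None,
) -> dict:
    """Execute every stage on the given datasets; returns the run log."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "datasets": sorted(counts_by_dataset),
    }
    states: dict[str, dict] = {}
    for ds in sorted(counts_by_dataset):
        ds_dir = outdir / ds
        ds_dir.mkdir(parents=True, exist_ok=True)
        cm = counts_by_dataset[ds]
        if cm.dataset_id != ds:
            cm.dataset_id = ds
        states[ds] = _dataset_stages(cm, config, ds_dir, log)

    datasets = sorted(states)
    ref = reference_dataset or datasets[0]
    if ref not in states:
        raise PipelineError(f"stage 'preserve' failed: unknown reference {ref!r}")
    log["reference_dataset"] = ref
    if len(datasets) > 1:
        with _Stage("preserve", log):
            ref_state = states[ref]
            ref_nm = _filtered(ref_state["nm"])
            for ds in datasets:
                if ds == ref:
                    continue
                res = preservation.module_preservation(
                    ref_nm, ref_state["modules"], _filtered(states[ds]["nm"]),
                    beta=config.soft_power, n_perm=config.n_permutations,
                    seed=config.seed,
                )
                _write(res, outdir / f"preservation_{ref}_vs_{ds}.tsv")

    with _Stage("cellcycle", log):
        if genesets_path is not None:
            sets = cc.read_gene_sets(genesets_path)
            gs_g1s, gs_g2m = sets["G1S"], sets["G2M"]
        else:
            gs_g1s, gs_g2m = cc.default_cycle_gene_sets()
        for ds in datasets:
            scores = cc.phase_scores(
                states[ds]["nm"], gs_g1s, gs_g2m, n_bins=config.n_expression_bins
            )
            classified = cc.classify_cells(
                scores, threshold=config.phase_score_threshold
            )
            states[ds]["cellcycle"] = classified
            _write(classified, outdir / ds / "cellcycle.tsv")

    if len(datasets) > 1 and surface_path is not None:
        with _Stage("screen", log):
            surface = cc.GeneSet(
                "surface",
                frozenset(Path(surface_path).read_text().split()),
            )
            report = screen_mod.featured_gene_screen(
                {ds: states[ds]["de"] for ds in datasets},
                {ds: states[ds]["modules"] for ds in datasets},
                surface,
                min_datasets=config.screen_min_datasets,
                q_threshold=config.screen_q_threshold,
            )
            _write(report, outdir / "featured_genes.tsv")

    if terms_path is not None:
        with _Stage("enrich", log):
            terms = cc.read_gene_sets(terms_path)
            background: set[str] = set()
            query: set[str] = set()
            for ds in datasets:
                nm = states[ds]["nm"]
                background |= {
                    g for g, ok in zip(nm.gene_ids, nm.filter_mask) if ok
                }
                for df in states[ds]["de"].values():
                    query |= set(
                        df.index[(df["q"] < config.de_alpha) & (df["log2fc"] > 0)]
                    )
            query &= background
            enr = screen_mod.hypergeometric_enrichment(
                query, background, terms, alpha=config.enrichment_alpha
            )
            _write(enr, outdir / "enrichment.tsv")

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return log


def _filtered(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Restrict a normalized matrix to its filter-passing endogenous genes."""
    keep = np.flatnonzero(nm.filter_mask)
    return NormalizedMatrix(
        values=nm.values[keep],
        log_values=nm.log_values[keep],
        gene_ids=[nm.gene_ids[i] for i in keep],
        cell_ids=list(nm.cell_ids),
        is_spikein=nm.is_spikein[keep],
        filter_mask=np.ones(len(keep), dtype=bool),
        dataset_id=nm.dataset_id,
    )
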