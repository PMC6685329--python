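"""Top-level pipeline: simulate -> analyze -> report.

A :class:`RunConfig` is a plain mapping (usually loaded from YAML) with a
mandatory ``seed``; every run writes its fully resolved configuration next to
its outputs, and re-running a saved configuration reproduces the outputs
byte-identically for the deterministic stages.  Any stage failure aborts with
a stage-tagged diagnostic.
"""

from __future__ import annotations

import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np

from . import io as caio
from .atlas import (
    composition_test,
    cluster_markers,
    embed_and_cluster,
    gene_query,
    qc_filter,
    remove_contaminant_cluster,
)
from .clones import call_clones, clonal_stats, compare_groups, estimate_recombination_efficiency, merger_test
from .params import QCParams
from .presets import counts_preset, tissue_preset
from .signature import load_panel, score_signature
from .tissue import simulate_tissue

log = logging.getLogger("cloneatlas")

DEFAULT_CONFIG = dict(
    tissue=dict(presets=["healthy", "mi"], n_sections=6),
    merger=dict(n_resamples=1000),
    counts=dict(n_cells=[400, 400], n_genes=800),
    scrna=dict(n_pcs=30, n_clusters_hint=11, min_genes=400, max_mito=0.20, tsne=False),
    signature=dict(panel="endmt"),
    gene_queries=["Plvap"],
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


def _resolve_config(config: dict) -> dict:
    if "seed" not in config or config["seed"] is None:
        raise ValueError("config must set an integer 'seed' (seed is mandatory)")
    resolved = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict) and k in resolved:
            resolved[k].update(v)
        else:
            resolved[k] = v
    resolved["package_version"] = _pkg_version("cloneatlas")
    return resolved


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged and re-raised
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


@_stage("tissue")
def _run_tissue(cfg, seeds, outdir):
    out = {}
    per_section = {}
    for i, preset in enumerate(cfg["presets"]):
        params = tissue_preset(preset, seed=int(seeds[i]), n_sections=cfg["n_sections"])
        tissue = simulate_tissue(params)
        clones = call_clones(tissue)
        stats = clonal_stats(clones, tissue)
        caio.write_tissue_csv(tissue, outdir / f"tissue_{preset}.csv")
        stats.per_section.to_csv(outdir / f"clonal_per_section_{preset}.csv", index=False)
        out[preset] = stats.to_dict()
        out[preset]["recombination_efficiency_recovered"] = estimate_recombination_efficiency(tissue)
        per_section[preset] = stats.per_section
        out[f"_clones_{preset}"] = clones
    if len(cfg["presets"]) == 2:
        a, b = cfg["presets"]
        out["group_comparisons"] = {
            metric: compare_groups(per_section[a], per_section[b], metric)
            for metric in ("mean_clone_size", "singleton_fraction", "edu_confetti_fraction",
                           "founder_events")
        }
    return out


@_stage("merger")
def _run_merger(cfg, clones, seed):
    res = merger_test(clones, n_resamples=cfg["n_resamples"], seed=int(seed))
    return dict(
        statistic=res.statistic, p_value=res.p_value, kw_statistic=res.kw_statistic,
        kw_pvalue=res.kw_pvalue, n_clones=res.n_clones, n_resamples=res.n_resamples,
    )


@_stage("scrna")
def _run_scrna(counts_cfg, scrna_cfg, sig_cfg, queries, seed, outdir):
    params = counts_preset(
        seed=int(seed),
        n_cells=tuple(counts_cfg["n_cells"]),
        n_genes=counts_cfg["n_genes"],
    )
    from .counts import simulate_counts

    adata = simulate_counts(params)
    caio.write_counts_mtx(adata, outdir / "counts")
    qc = QCParams(min_genes_per_cell=scrna_cfg["min_genes"], max_mito_fraction=scrna_cfg["max_mito"])
    filtered, qc_report = qc_filter(adata, qc)
    result = embed_and_cluster(
        filtered, n_pcs=min(scrna_cfg["n_pcs"], filtered.n_obs - 1),
        n_clusters_hint=scrna_cfg.get("n_clusters_hint"), seed=int(seed),
        tsne=scrna_cfg.get("tsne", False),
    )
    result = remove_contaminant_cluster(result)
    markers = cluster_markers(result, n_top=10)
    comp = composition_test(result)
    result.labels.rename("cluster").to_csv(outdir / "clusters.tsv", sep="\t")
    markers.to_csv(outdir / "markers.csv", index=False)
    caio.save_json(qc_report.to_dict(), outdir / "qc_report.json")

    panel = load_panel(sig_cfg["panel"])
    sig = score_signature(result.adata, panel, seed=int(seed))
    sig.scores.to_frame().assign(group=result.adata.obs["group"].values).to_csv(
        outdir / "signature_scores.csv"
    )
    out = dict(
        qc=qc_report.to_dict(),
        n_clusters=result.n_clusters,
        resolution=result.resolution,
        contaminant_removed=result.contaminant_removed,
        removed_clusters=list(result.removed_clusters),
        double_positive_fraction=result.double_positive_fraction,
        composition=comp.to_dict(orient="records"),
        top_markers={
            cl: grp["gene"].head(5).tolist() for cl, grp in markers.groupby("cluster")
        },
        signature=dict(panel=sig.panel_name, group_summary=sig.group_summary),
        gene_queries={},
    )
    for gene in queries:
        out["gene_queries"][gene] = gene_query(result, gene).to_dict(orient="records")
    return out


def run_pipeline(config: dict | str, outdir) -> dict:
    """Execute the configured simulate -> analyze chain and write a JSON report."""
    if isinstance(config, (str, Path)):
        config = caio.load_config(config)
    cfg = _resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    seeds = np.random.SeedSequence(seed).generate_state(8) % (2**31)
    log.info("cloneatlas %s run: seed=%d outdir=%s", cfg["package_version"], seed, outdir)
    caio.save_config(cfg, outdir / "resolved_config.yaml")

    report = dict(config=cfg)
    tissue_out = _run_tissue(cfg["tissue"], seeds, outdir)
    clones_for_merger = tissue_out.pop(f"_clones_{cfg['tissue']['presets'][0]}", None)
    for p in cfg["tissue"]["presets"]:
        tissue_out.pop(f"_clones_{p}", None)
    report["tissue"] = tissue_out
    if clones_for_merger is not None and clones_for_merger.n_clones >= 2:
        report["merger"] = _run_merger(cfg["merger"], clones_for_merger, seeds[4])
    report["scrna"] = _run_scrna(
        cfg["counts"], cfg["scrna"], cfg["signature"], cfg.get("gene_queries", []),
        seeds[5], outdir,
    )
    caio.save_json(report, outdir / "report.json")
    return report
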