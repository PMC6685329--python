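"""Single-cell endothelial state pipeline: QC, clustering, contaminants, markers.

The pipeline mirrors standard droplet scRNA-seq practice: remove cells with a
low detected-gene count (< 400) or a high mitochondrial transcript ratio
(> 20%), depth-normalize and log-transform, PCA, graph-based community
clustering (Leiden) in PCA space, with a 3D t-SNE computed for display only --
cluster assignment never depends on the t-SNE.  Downstream operations detect
per-cluster marker genes (one-vs-rest rank-sum with Benjamini-Hochberg
correction within cluster), remove haematopoietic contaminant clusters by the
Ptprc+ / Pecam1- / Kdr- rule, test per-cluster group enrichment against the
global healthy:MI ratio, and answer per-gene queries.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .params import QCParams, resolve_mito_genes


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed: pd.DataFrame  # index: removed cell ids; columns: reason, n_genes, mito_fraction
    mito_genes: list
    mito_filter_applied: bool
    params: QCParams

    def to_dict(self) -> dict:
        reasons = self.removed["reason"].value_counts().to_dict() if len(self.removed) else {}
        return dict(
            n_input=self.n_input,
            n_retained=self.n_retained,
            n_removed=self.n_input - self.n_retained,
            removal_reasons=reasons,
            mito_genes=list(self.mito_genes),
            mito_filter_applied=self.mito_filter_applied,
            min_genes_per_cell=self.params.min_genes_per_cell,
            max_mito_fraction=self.params.max_mito_fraction,
        )


def _raw_counts(adata: ad.AnnData):
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    return sparse.csr_matrix(X) if not sparse.issparse(X) else X.tocsr()


def qc_filter(adata: ad.AnnData, qc: QCParams | None = None) -> tuple[ad.AnnData, QCReport]:
    """Remove low-gene-count and high-mitochondrial cells.

    A cell is removed when its detected-gene count is strictly below
    ``qc.min_genes_per_cell`` or its mitochondrial count fraction is strictly
    above ``qc.max_mito_fraction`` (cells exactly at either threshold are
    retained).  Removal reasons partition the removed cells
    (``low_genes`` / ``high_mito`` / ``both``).  If no mitochondrial genes are
    identifiable under the rule, the mito filter is skipped with a warning and
    flagged in the report.  Idempotent: re-filtering a filtered matrix removes
    nothing.
    """
    qc = qc or QCParams()
    X = _raw_counts(adata)
    n_genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()

    mito_genes = resolve_mito_genes(adata.var_names, qc.mito_gene_rule)
    mito_applied = len(mito_genes) > 0
    if mito_applied:
        mito_idx = adata.var_names.get_indexer(mito_genes)
        mito_counts = np.asarray(X[:, mito_idx].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    else:
        warnings.warn(
            f"no mitochondrial genes identifiable under rule {qc.mito_gene_rule!r}; "
            "mito filter skipped",
            stacklevel=2,
        )
        mito_frac = np.zeros(adata.n_obs)

    low = n_genes_detected < qc.min_genes_per_cell
    high = mito_applied & (mito_frac > qc.max_mito_fraction)
    drop = low | high
    reason = np.where(low & high, "both", np.where(low, "low_genes", "high_mito"))

    removed = pd.DataFrame(
        dict(reason=reason[drop], n_genes=n_genes_detected[drop], mito_fraction=mito_frac[drop]),
        index=adata.obs_names[drop],
    )
    out = adata[~drop].copy()
    out.obs["n_genes_detected"] = n_genes_detected[~drop]
    out.obs["mito_fraction"] = mito_frac[~drop]
    report = QCReport(
        n_input=adata.n_obs, n_retained=out.n_obs, removed=removed,
        mito_genes=mito_genes, mito_filter_applied=mito_applied, params=qc,
    )
    return out, report


# ---------------------------------------------------------------------------
# embedding + clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    adata: ad.AnnData = field(repr=False)
    labels: pd.Series  # per-cell cluster id (string)
    n_clusters: int
    resolution: float
    composition: pd.DataFrame  # cluster x group counts
    contaminant_removed: bool = False
    removed_clusters: list = field(default_factory=list)
    double_positive_fraction: float | None = None


def _composition(labels: pd.Series, groups: pd.Series) -> pd.DataFrame:
    return pd.crosstab(labels, groups)


def _leiden(adata, resolution, seed) -> pd.Series:
    sc.tl.leiden(
        adata, resolution=resolution, random_state=seed, key_added="cluster",
        flavor="leidenalg",
    )
    return adata.obs["cluster"]


def embed_and_cluster(
    adata: ad.AnnData,
    n_pcs: int = 30,
    resolution: float = 0.5,
    n_clusters_hint: int | None = None,
    hvg: bool = True,
    n_hvg: int = 2000,
    seed: int = 0,
    tsne: bool = False,
    group_key: str = "group",
) -> ClusterResult:
    """Normalize, embed and cluster a QC-filtered count matrix.

    Per-cell depth scaling to the median depth plus log1p, optional
    highly-variable-gene selection (disable with ``hvg=False`` to use the
    whole transcriptome), PCA with ``n_pcs`` components, a k-NN graph and
    Leiden community detection.  If ``n_clusters_hint`` is given, the
    resolution is searched (bisection on log-resolution) to return that many
    clusters.  A 3D t-SNE is computed for visualization only when
    ``tsne=True``.  Deterministic given ``seed``.
    """
    if adata.n_obs < n_pcs:
        raise ValueError(f"fewer cells ({adata.n_obs}) than principal components ({n_pcs})")
    adata = adata.copy()
    if "counts" not in adata.layers:
        adata.layers["counts"] = sparse.csr_matrix(adata.X).copy()
    sc.pp.normalize_total(adata)  # median depth
    sc.pp.log1p(adata)
    if hvg and adata.n_vars > n_hvg:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
    n_comps = min(n_pcs, adata.n_obs - 1, adata.n_vars - 1)
    sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=15, n_pcs=n_comps, random_state=seed)

    if n_clusters_hint is None:
        labels = _leiden(adata, resolution, seed)
        used_res = resolution
    else:
        lo, hi = 0.01, 10.0
        used_res = resolution
        labels = _leiden(adata, used_res, seed)
        best = (abs(labels.nunique() - n_clusters_hint), used_res, labels)
        for _ in range(25):
            k = labels.nunique()
            if k == n_clusters_hint:
                break
            if k < n_clusters_hint:
                lo = used_res
            else:
                hi = used_res
            used_res = float(np.sqrt(lo * hi))
            labels = _leiden(adata, used_res, seed)
            cand = (abs(labels.nunique() - n_clusters_hint), used_res, labels)
            if cand[0] < best[0]:
                best = cand
        if labels.nunique() != n_clusters_hint:
            _, used_res, labels = best
            adata.obs["cluster"] = labels
            warnings.warn(
                f"resolution search reached {labels.nunique()} clusters "
                f"(hint was {n_clusters_hint})",
                stacklevel=2,
            )

    if tsne:
        from sklearn.manifold import TSNE

        emb = TSNE(n_components=3, random_state=seed, init="pca",
                   perplexity=min(30.0, max(5.0, adata.n_obs / 100))).fit_transform(
            adata.obsm["X_pca"]
        )
        adata.obsm["X_tsne3d"] = emb

    labels = adata.obs["cluster"].astype(str)
    adata.obs["cluster"] = labels
    groups = (
        adata.obs[group_key]
        if group_key in adata.obs
        else pd.Series("all", index=adata.obs_names)
    )
    return ClusterResult(
        adata=adata,
        labels=labels,
        n_clusters=int(labels.nunique()),
        resolution=float(used_res),
        composition=_composition(labels, groups),
    )


# ---------------------------------------------------------------------------
# contaminant removal
# ---------------------------------------------------------------------------

DEFAULT_CONTAMINANT_MARKERS = dict(positive=("Ptprc",), negative=("Pecam1", "Kdr"))


def remove_contaminant_cluster(
    result: ClusterResult,
    markers: dict | None = None,
    positive_quantile: float = 0.90,
    negative_quantile: float = 0.25,
) -> ClusterResult:
    """Flag and remove haematopoietic contaminant clusters.

    A cluster is flagged when its mean expression of every positive marker
    exceeds the global per-cell upper decile of that marker while its mean of
    every negative (endothelial) marker falls below the global lower quartile.
    Rare double-positive cells (positive marker co-expressed with the first
    negative marker) inside retained clusters are kept and reported as a
    fraction of retained cells.
    """
    markers = markers or DEFAULT_CONTAMINANT_MARKERS
    adata = result.adata
    for g in tuple(markers["positive"]) + tuple(markers["negative"]):
        if g not in adata.var_names:
            raise KeyError(f"marker gene {g!r} absent from the matrix")

    def expr(gene):
        col = adata[:, gene].X
        return np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()

    labels = result.labels
    flagged = []
    for cl in labels.unique():
        mask = (labels == cl).to_numpy()
        pos_ok = all(
            expr(g)[mask].mean() > np.quantile(expr(g), positive_quantile)
            for g in markers["positive"]
        )
        neg_ok = all(
            expr(g)[mask].mean() < np.quantile(expr(g), negative_quantile)
            for g in markers["negative"]
        )
        if pos_ok and neg_ok:
            flagged.append(cl)

    keep = ~labels.isin(flagged).to_numpy()
    sub = adata[keep].copy()
    sub_labels = labels[keep]

    counts = _raw_counts(sub)
    pos_gene = markers["positive"][0]
    neg_gene = markers["negative"][0]
    pos_counts = np.asarray(counts[:, sub.var_names.get_loc(pos_gene)].todense()).ravel()
    neg_counts = np.asarray(counts[:, sub.var_names.get_loc(neg_gene)].todense()).ravel()
    dp = float(((pos_counts >= 2) & (neg_counts >= 1)).mean()) if sub.n_obs else None

    groups = (
        sub.obs["group"] if "group" in sub.obs else pd.Series("all", index=sub.obs_names)
    )
    return ClusterResult(
        adata=sub,
        labels=sub_labels,
        n_clusters=int(sub_labels.nunique()),
        resolution=result.resolution,
        composition=_composition(sub_labels, groups),
        contaminant_removed=bool(flagged),
        removed_clusters=list(flagged),
        double_positive_fraction=dp,
    )


# ---------------------------------------------------------------------------
# markers, composition, gene queries
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def cluster_markers(
    result: ClusterResult,
    method: str = "wilcoxon",
    alpha: float = 0.05,
    min_lfc: float = 1.0,
    n_top: int | None = None,
) -> pd.DataFrame:
    """One-vs-rest marker detection per cluster.

    Rank-sum (Wilcoxon) test per gene per cluster on the normalized
    log-expression, BH adjustment across genes within each cluster, sorted by
    effect size (log2 fold-change).  A gene is flagged ``specific`` when it
    qualifies as a marker (adjusted p < alpha and lfc > min_lfc) in exactly
    one cluster.  Clusters with fewer than 3 cells are skipped and flagged in
    the ``skipped_clusters`` attribute of the returned frame.
    """
    adata = result.adata
    sizes = result.labels.value_counts()
    usable = sizes[sizes >= 3].index.astype(str).tolist()
    skipped = sizes[sizes < 3].index.astype(str).tolist()
    if len(usable) < 2:
        raise ValueError("marker detection needs >= 2 clusters with >= 3 cells")
    ad_use = adata[result.labels.isin(usable)].copy()
    ad_use.obs["cluster"] = ad_use.obs["cluster"].astype("category")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(
            ad_use, "cluster", method=method, pts=True, use_raw=False
        )
    frames = []
    for cl in usable:
        df = sc.get.rank_genes_groups_df(ad_use, group=cl)
        df = df.rename(
            columns=dict(
                names="gene", logfoldchanges="lfc", scores="statistic",
                pvals="pval", pvals_adj="padj", pct_nz_group="pct_in",
                pct_nz_reference="pct_out",
            )
        )
        df.insert(0, "cluster", cl)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    is_marker = (table["padj"] < alpha) & (table["lfc"] > min_lfc)
    n_clusters_marking = table.loc[is_marker].groupby("gene")["cluster"].nunique()
    table["specific"] = is_marker & (
        table["gene"].map(n_clusters_marking).fillna(0).astype(int) == 1
    )
    table = table.sort_values(["cluster", "lfc"], ascending=[True, False]).reset_index(drop=True)
    if n_top is not None:
        table = table.groupby("cluster", group_keys=False).head(n_top).reset_index(drop=True)
    table.attrs["skipped_clusters"] = skipped
    return table


def composition_test(
    result: ClusterResult, group_key: str = "group", min_cells: int = 10
) -> pd.DataFrame:
    """Per-cluster test of group enrichment against the global group ratio.

    Exact two-sided binomial test of each cluster's MI count against the
    global MI fraction; clusters composed exclusively of one group are
    flagged, as are clusters too small to be informative.
    """
    adata = result.adata
    if group_key not in adata.obs:
        raise KeyError(f"missing group labels: obs[{group_key!r}]")
    groups = adata.obs[group_key].astype(str)
    levels = list(groups.unique())
    ref = "MI" if "MI" in levels else levels[-1]
    other = next((l for l in ("healthy",) if l in levels and l != ref), None)
    if other is None:
        other = next((l for l in levels if l != ref), "(none)")
    global_frac = float((groups == ref).mean())
    rows = []
    for cl in sorted(result.labels.unique(), key=str):
        mask = result.labels == cl
        n = int(mask.sum())
        k = int((groups[mask.to_numpy()] == ref).sum())
        p = stats.binomtest(k, n, global_frac, alternative="two-sided").pvalue if n else 1.0
        rows.append(
            dict(
                cluster=cl,
                n_cells=n,
                **{f"{other}_fraction": 1.0 - k / n if n else np.nan,
                   f"{ref}_fraction": k / n if n else np.nan},
                p=float(p),
                exclusive=(k == 0 or k == n),
                underpowered=n < min_cells,
            )
        )
    return pd.DataFrame(rows)


def gene_query(result: ClusterResult, gene: str, group_key: str = "group") -> pd.DataFrame:
    """Per-cluster, per-group expression summary for one gene.

    Returns mean normalized expression, detection fraction and the per-group
    split for each cluster, ranked by cluster mean; raises with nearest-name
    suggestions when the gene is absent.
    """
    adata = result.adata
    if gene not in adata.var_names:
        hint = difflib.get_close_matches(gene, list(adata.var_names), n=3)
        raise KeyError(f"gene {gene!r} not in matrix; closest matches: {hint}")
    col = adata[:, gene].X
    x = np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()
    groups = (
        adata.obs[group_key].astype(str)
        if group_key in adata.obs
        else pd.Series("all", index=adata.obs_names)
    )
    rows = []
    for cl in sorted(result.labels.unique(), key=str):
        mask = (result.labels == cl).to_numpy()
        row = dict(
            cluster=cl,
            n_cells=int(mask.sum()),
            mean=float(x[mask].mean()),
            detection_fraction=float((x[mask] > 0).mean()),
        )
        for g in sorted(groups.unique()):
            gm = mask & (groups == g).to_numpy()
            row[f"mean_{g}"] = float(x[gm].mean()) if gm.any() else np.nan
            row[f"detection_{g}"] = float((x[gm] > 0).mean()) if gm.any() else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("mean", ascending=False).reset_index(drop=True)
    out.attrs["gene"] = gene
    return out
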