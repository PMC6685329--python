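"""Gene-signature (module) scoring with expression-matched control genes.

A signature score for a cell is the mean normalized expression of the panel
genes minus the mean of a control set sampled to match the panel's expression
distribution: genes are binned by their average expression across cells and,
for every panel gene, ``ctrl_size`` control genes are drawn from the same bin,
excluding the panel itself.  This removes the depth/abundance component of the
raw mean, so a score near zero means the panel behaves like background.

The shipped endothelial-to-mesenchymal transition (EndMT) panel is a
reconstruction: the markers named in the primary report (Icam1, Vcam1, Vim,
Fn1, Smtn) plus canonical early (transcription factors, intermediate-state
markers) and late (mesenchymal/ECM) EndMT genes; see ``data/panels/endmt.yaml``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import sparse, stats

from .atlas import benjamini_hochberg


@dataclass(frozen=True)
class SignaturePanel:
    name: str
    genes: tuple  # gene symbols
    tags: dict = field(default_factory=dict)  # gene -> early/late (optional)

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError("signature panel has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature panel has duplicate genes")


def load_panel(path_or_name) -> SignaturePanel:
    """Load a signature panel from a YAML file, or a bundled panel by name."""
    try:
        text = open(path_or_name).read()
    except (FileNotFoundError, IsADirectoryError):
        ref = resources.files("cloneatlas").joinpath(f"data/panels/{path_or_name}.yaml")
        text = ref.read_text()
    raw = yaml.safe_load(text)
    genes, tags = [], {}
    for item in raw["genes"]:
        if isinstance(item, str):
            genes.append(item)
        else:
            (g, tag), = item.items()
            genes.append(g)
            tags[g] = tag
    return SignaturePanel(name=raw["name"], genes=tuple(genes), tags=tags)


@dataclass
class SignatureScore:
    panel_name: str
    scores: pd.Series  # per-cell score
    genes_used: tuple
    genes_missing: tuple
    control_genes: tuple
    group_summary: dict | None  # means, effect size, p
    per_gene: pd.DataFrame | None  # per-gene group breakdown


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    s = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((b.mean() - a.mean()) / s) if s > 0 else 0.0


def score_signature(
    adata: ad.AnnData,
    panel: SignaturePanel,
    n_control_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
    group_key: str = "group",
) -> SignatureScore:
    """Score a gene signature per cell against expression-matched controls.

    ``adata.X`` must hold normalized (log) expression.  Panel genes missing
    from the matrix are dropped with a warning; an empty panel after dropping
    is an error.  Control genes are sampled per expression bin and are always
    disjoint from the panel.  When group labels are available the score is
    compared between groups (Mann-Whitney, Cohen's d) and a per-gene breakdown
    is reported so that "signature flat but individual genes up" is visible.
    """
    present = [g for g in panel.genes if g in adata.var_names]
    missing = [g for g in panel.genes if g not in adata.var_names]
    if missing:
        warnings.warn(
            f"{len(missing)} panel gene(s) absent from matrix and dropped: {missing}",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"panel {panel.name!r} is empty after dropping missing genes")

    rng = np.random.default_rng(seed)
    gene_means = np.asarray(_dense(adata.X).mean(axis=0)).ravel()
    order = pd.Series(gene_means, index=adata.var_names)
    ranks = order.rank(method="first")
    n_bins = min(n_control_bins, adata.n_vars)
    bins = pd.cut(ranks, bins=n_bins, labels=False)

    panel_set = set(present)
    control: set = set()
    for g in present:
        pool = bins.index[(bins == bins[g]) & ~bins.index.isin(panel_set)]
        if len(pool) == 0:
            continue
        take = min(ctrl_size, len(pool))
        control.update(rng.choice(pool, size=take, replace=False))
    control -= panel_set
    if not control:
        raise ValueError("no control genes available outside the panel")
    control = sorted(control)

    panel_x = _dense(adata[:, present].X)
    ctrl_x = _dense(adata[:, control].X)
    scores = pd.Series(
        panel_x.mean(axis=1) - ctrl_x.mean(axis=1), index=adata.obs_names, name="score"
    )

    group_summary = None
    per_gene = None
    if group_key in adata.obs and adata.obs[group_key].nunique() == 2:
        groups = adata.obs[group_key].astype(str)
        lv = sorted(groups.unique())
        g0, g1 = ("healthy", "MI") if set(lv) == {"healthy", "MI"} else lv
        a = scores[groups == g0].to_numpy()
        b = scores[groups == g1].to_numpy()
        mw = stats.mannwhitneyu(a, b, alternative="two-sided")
        group_summary = {
            f"mean_{g0}": float(a.mean()),
            f"mean_{g1}": float(b.mean()),
            "difference": float(b.mean() - a.mean()),
            "cohens_d": _cohens_d(a, b),
            "p_value": float(mw.pvalue),
            "groups": (g0, g1),
        }
        rows = []
        mask1 = (groups == g1).to_numpy()
        for j, g in enumerate(present):
            xa, xb = panel_x[~mask1, j], panel_x[mask1, j]
            if np.ptp(np.concatenate([xa, xb])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            rows.append(
                dict(
                    gene=g,
                    tag=panel.tags.get(g, ""),
                    **{f"mean_{g0}": float(xa.mean()), f"mean_{g1}": float(xb.mean())},
                    difference=float(xb.mean() - xa.mean()),
                    p=p,
                )
            )
        per_gene = pd.DataFrame(rows)
        per_gene["padj"] = benjamini_hochberg(per_gene["p"])

    return SignatureScore(
        panel_name=panel.name,
        scores=scores,
        genes_used=tuple(present),
        genes_missing=tuple(missing),
        control_genes=tuple(control),
        group_summary=group_summary,
        per_gene=per_gene,
    )
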