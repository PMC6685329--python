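"""Negative-binomial UMI count simulator for the endothelial state atlas.

Generates a sparse gene x cell UMI matrix with the statistical structure the
downstream pipeline assumes: ten endothelial (EC) transcriptional archetypes
with planted marker programs, group (healthy vs infarct) composition per
archetype including an infarct-exclusive state, a haematopoietic contaminant
population (Ptprc+ Pecam1- Kdr-), rare Ptprc+Pecam1+ double-positive EC,
per-cell mitochondrial fractions with a tail beyond the QC threshold, and a
low-depth cell fraction that fails the detected-gene filter.

Counts are Gamma-Poisson (negative binomial): a gene with mean ``mu`` and
dispersion ``theta`` has variance ``mu + mu**2/theta``.  Per-cell means are a
normalized product of a lognormal gene weight vector, archetype fold-changes
and group shifts, scaled to the cell's target depth, with the mitochondrial
block scaled to the cell's mitochondrial fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

ENDOTHELIAL_GENES = ("Pecam1", "Kdr", "Cdh5")
CONTAMINANT_POSITIVE = "Ptprc"

#: The ten EC-state archetypes.  Marker sets are the published per-cluster
#: top differentially expressed genes; ``healthy_share`` encodes the group
#: composition of each state (archetype 7 is infarct-exclusive).
DEFAULT_ARCHETYPES: tuple[dict, ...] = (
    dict(name="1", markers=("Arhgap18", "Adm", "Hspb1", "Cd36"), healthy_share=0.50),
    dict(name="2", markers=("Ifit1", "Ifit2", "Ifit3", "Ifit3b", "Usp18", "Cxcl10"),
         healthy_share=0.38),
    dict(name="3", markers=("Myl2", "Mb", "Myl3", "Tnnt2", "Tnni3", "Actc1"),
         healthy_share=0.30),
    dict(name="4", markers=("Klra3", "Klra9", "Klra10"), healthy_share=0.50),
    dict(name="5", markers=("Dll4", "Notch1", "Hey1", "Jag1", "Gja4"), healthy_share=0.50),
    dict(name="6", markers=("Plvap", "Lrg1", "Rbp1", "Bgn", "Vwf"), healthy_share=0.35),
    dict(name="7", markers=("Ackr1", "Ehd4", "Tmem176a", "Tmem252", "Tmem176b", "Selp"),
         healthy_share=0.0),
    dict(name="8", markers=("Fbln2", "Anxa2", "Col5a2", "Emilin1", "Hmcn1", "Bgn", "Mgp"),
         healthy_share=0.42),
    dict(name="9", markers=("Serpina1b", "Serpina1d", "Serpina1e"), healthy_share=0.50),
    dict(name="10", markers=("Mki67", "Top2a", "Cenpf", "Cks2", "Birc5", "Cenpa",
                             "Ube2c", "Cdc20"), healthy_share=0.38),
)

#: Genes elevated beyond their home archetype (capillary/venous Plvap rises in
#: the three infarct-enriched states).
SECONDARY_MARKERS: dict[str, dict[str, float]] = {"Plvap": {"7": 8.0, "8": 8.0}}


def _bundled_panel_genes(name: str = "endmt") -> tuple:
    """Gene symbols of a bundled signature panel (kept in the gene universe so
    signature scoring has its panel present by default)."""
    from importlib import resources

    import yaml

    raw = yaml.safe_load(
        resources.files("cloneatlas").joinpath(f"data/panels/{name}.yaml").read_text()
    )
    out = []
    for item in raw["genes"]:
        out.append(item if isinstance(item, str) else next(iter(item)))
    return tuple(out)


@dataclass(frozen=True)
class Archetype:
    name: str
    markers: dict  # gene -> fold change
    healthy_share: float
    weight: float = 1.0  # relative abundance of the state
    n_program_genes: int = 10
    program_fold: float = 3.0

    def __post_init__(self):
        if not (0.0 <= self.healthy_share <= 1.0):
            raise ValueError(f"healthy_share of archetype {self.name} not in [0,1]")
        if self.weight <= 0:
            raise ValueError(f"weight of archetype {self.name} must be positive")
        for g, f in self.markers.items():
            if f <= 0:
                raise ValueError(f"fold change for {g} must be positive")


def build_archetypes(
    specs=DEFAULT_ARCHETYPES,
    marker_fold: float = 8.0,
    secondary: dict | None = None,
    n_program_genes: int = 10,
    program_fold: float = 3.0,
) -> tuple[Archetype, ...]:
    """Expand archetype specs into marker->fold maps, checking for conflicts."""
    secondary = SECONDARY_MARKERS if secondary is None else secondary
    arks = []
    for entry in specs:
        markers = {g: marker_fold for g in entry["markers"]}
        for gene, by_ark in secondary.items():
            if entry["name"] in by_ark:
                if gene in markers and markers[gene] != by_ark[entry["name"]]:
                    raise ValueError(
                        f"marker {gene} configured twice for archetype {entry['name']} "
                        "with conflicting fold-changes"
                    )
                markers[gene] = by_ark[entry["name"]]
        arks.append(
            Archetype(
                name=entry["name"], markers=markers, healthy_share=entry["healthy_share"],
                n_program_genes=n_program_genes, program_fold=program_fold,
            )
        )
    return tuple(arks)


@dataclass(frozen=True)
class SimCountsParams:
    """Parameters of the count-matrix simulator (validated on construction)."""

    n_cells: tuple = (1500, 1500)  # (healthy, MI)
    n_genes: int = 2000
    archetypes: tuple = field(default_factory=build_archetypes)
    dispersion: float = 10.0  # NB theta; var = mu + mu**2/theta
    group_depth: tuple = (2232.0, 5041.0)  # mean UMI per cell (healthy, MI)
    depth_sigma: float = 0.3  # lognormal spread of per-cell depth
    mito_law: tuple = ("beta_mixture", dict(a=2.0, b=31.0, cap=0.15, tail_mass=0.04,
                                            tail_lo=0.22, tail_hi=0.5))
    lowdepth_cell_fraction: float = 0.02
    lowdepth_depth: float = 300.0  # < min-genes threshold by construction
    contaminant_fraction: float = 0.03
    contaminant_fold: float = 300.0
    rare_double_positive_fraction: float = 0.0029  # of MI EC cells
    group_gene_shifts: tuple = ()  # ((gene, healthy_mult, mi_mult), ...)
    extra_genes: tuple = field(default_factory=_bundled_panel_genes)
    seed: int | None = None

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if len(self.archetypes) == 0:
            raise ValueError("at least one archetype required")
        folds: dict[str, float] = {}
        for a in self.archetypes:
            for g, f in a.markers.items():
                if g in folds and folds[g] != f:
                    raise ValueError(
                        f"marker gene {g!r} named in two archetypes with conflicting "
                        f"fold-changes ({folds[g]} vs {f})"
                    )
                folds[g] = f
        for frac, name in (
            (self.lowdepth_cell_fraction, "lowdepth_cell_fraction"),
            (self.contaminant_fraction, "contaminant_fraction"),
            (self.rare_double_positive_fraction, "rare_double_positive_fraction"),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")


def _gene_names(params: SimCountsParams) -> tuple[list, dict]:
    """Assemble the gene universe: planted markers, special genes, programs,
    mitochondrial genes and anonymous filler."""
    names: list[str] = []
    marker_of: dict[str, str] = {}
    for a in params.archetypes:
        for g in a.markers:
            if g not in names:
                names.append(g)
                marker_of[g] = a.name
        for j in range(a.n_program_genes):
            g = f"Prog{a.name}.{j + 1}"
            names.append(g)
            marker_of[g] = a.name
    for g in ENDOTHELIAL_GENES + (CONTAMINANT_POSITIVE, "Pdpn") + tuple(params.extra_genes):
        if g not in names:
            names.append(g)
    shifted = [g for g, _, _ in params.group_gene_shifts if g not in names]
    names.extend(shifted)
    names.extend(MITO_GENES)
    n_filler = params.n_genes - len(names)
    if n_filler < 0:
        raise ValueError(
            f"n_genes={params.n_genes} too small for {len(names)} structured genes"
        )
    names.extend(f"Gene{j:04d}" for j in range(1, n_filler + 1))
    return names, marker_of


def _mito_fractions(rng, law, n) -> np.ndarray:
    kind, kw = law
    if kind == "fixed":
        return np.full(n, float(kw))
    if kind != "beta_mixture":
        raise ValueError(f"unknown mito law {kind!r}")
    f = rng.beta(kw["a"], kw["b"], size=n)
    f = np.minimum(f, kw["cap"])
    tail = rng.random(n) < kw["tail_mass"]
    f[tail] = rng.uniform(kw["tail_lo"], kw["tail_hi"], size=int(tail.sum()))
    return f


def simulate_counts(params: SimCountsParams) -> ad.AnnData:
    """Simulate a UMI count matrix as an :class:`anndata.AnnData` (cells x genes).

    ``adata.X`` holds raw counts (CSR); per-cell metadata records group, true
    archetype, target mitochondrial fraction and the planted low-depth /
    double-positive flags.  Deterministic given ``params.seed``.
    """
    if params.seed is None:
        raise ValueError("params.seed is required (reproducibility is mandatory)")
    rng = np.random.default_rng(params.seed)

    gene_names, marker_of = _gene_names(params)
    n_genes = len(gene_names)
    gidx = {g: i for i, g in enumerate(gene_names)}
    is_mito = np.array([g in MITO_GENES for g in gene_names])

    # Baseline relative expression; special genes pinned so that endothelial
    # identity and contaminant contrast do not depend on a lucky lognormal draw.
    w = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    w[gidx["Pecam1"]] = 20.0
    w[gidx["Kdr"]] = 15.0
    w[gidx["Cdh5"]] = 10.0
    w[gidx["Ptprc"]] = 0.05
    w[gidx["Pdpn"]] = 0.05
    # Signature-panel genes share a common moderate baseline so that panel
    # scores are comparable across genes and group-shift scenarios compose
    # additively on the mean scale.
    for g in params.extra_genes:
        w[gidx[g]] = 1.0

    # archetype fold-change matrix (n_arch x n_genes)
    arks = params.archetypes
    fold = np.ones((len(arks), n_genes))
    for ai, a in enumerate(arks):
        for g, f in a.markers.items():
            fold[ai, gidx[g]] = f
        for j in range(a.n_program_genes):
            fold[ai, gidx[f"Prog{a.name}.{j + 1}"]] = a.program_fold

    contam_mult = np.ones(n_genes)
    contam_mult[gidx["Ptprc"]] = params.contaminant_fold
    for g in ENDOTHELIAL_GENES:
        contam_mult[gidx[g]] = 0.01

    group_mult = np.ones((2, n_genes))  # rows: healthy, MI
    for g, hm, mm in params.group_gene_shifts:
        group_mult[0, gidx[g]] = hm
        group_mult[1, gidx[g]] = mm

    # ---- per-cell assignments ------------------------------------------
    n_h, n_m = params.n_cells
    n_total = n_h + n_m
    group = np.array([0] * n_h + [1] * n_m)

    shares = np.array([a.healthy_share for a in arks])
    abundance = np.array([a.weight for a in arks])
    weights_by_group = np.stack([shares, 1.0 - shares]) * abundance  # healthy, MI rows
    archetype_idx = np.full(n_total, -1)
    is_contaminant = rng.random(n_total) < params.contaminant_fraction
    for g in (0, 1):
        mask = (group == g) & ~is_contaminant
        wts = weights_by_group[g]
        if wts.sum() == 0:
            raise ValueError("archetype mixture for a group sums to zero")
        archetype_idx[mask] = rng.choice(len(arks), size=int(mask.sum()), p=wts / wts.sum())

    is_dp = (group == 1) & ~is_contaminant & (
        rng.random(n_total) < params.rare_double_positive_fraction
    )
    is_lowdepth = rng.random(n_total) < params.lowdepth_cell_fraction

    depth = np.exp(rng.normal(0.0, params.depth_sigma, size=n_total))
    depth *= np.where(group == 0, params.group_depth[0], params.group_depth[1])
    depth[is_lowdepth] = params.lowdepth_depth

    mito_frac = _mito_fractions(rng, params.mito_law, n_total)

    # ---- sampling -------------------------------------------------------
    theta = params.dispersion
    non_mito = ~is_mito
    rows = []
    for i in range(n_total):
        mu = w.copy()
        if is_contaminant[i]:
            mu *= contam_mult
        else:
            mu *= fold[archetype_idx[i]]
            mu *= group_mult[group[i]]
            if is_dp[i]:
                mu[gidx["Ptprc"]] *= params.contaminant_fold
        f = mito_frac[i]
        nm_sum = mu[non_mito].sum()
        m_sum = mu[is_mito].sum()
        mu[non_mito] *= (1.0 - f) * depth[i] / nm_sum
        mu[is_mito] *= f * depth[i] / m_sum
        lam = rng.gamma(shape=theta, scale=mu / theta)
        rows.append(sparse.csr_matrix(rng.poisson(lam)))
    X = sparse.vstack(rows).tocsr()
    X.data = X.data.astype(np.int64)

    obs = pd.DataFrame(
        dict(
            group=pd.Categorical(np.where(group == 0, "healthy", "MI"),
                                 categories=["healthy", "MI"]),
            archetype=[("contaminant" if is_contaminant[i] else arks[archetype_idx[i]].name)
                       for i in range(n_total)],
            true_mito_fraction=mito_frac,
            is_lowdepth=is_lowdepth,
            is_double_positive=is_dp,
        ),
        index=[f"cell{i:05d}" for i in range(n_total)],
    )
    var = pd.DataFrame(
        dict(
            is_mito=is_mito,
            marker_of=[marker_of.get(g, "") for g in gene_names],
        ),
        index=gene_names,
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["simulation"] = dict(seed=int(params.seed), n_archetypes=len(arks))
    return adata
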