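"""Clone calling and clonal statistics for Confetti-labelled tissue maps.

A *clone* is a maximal connected set of two or more same-fluorophore cells
under the declared adjacency (6-connected lattice neighbourhood by default);
labelled cells without a same-colour neighbour are *singletons*.  A labelled
singleton or an entire clone each count as one *founder event* -- the number
of recombination events behind the observed labelling pattern.

The module also implements the merger-vs-expansion inference: if apparent
clones arose by merging independent founders rather than by clonal expansion,
clones of the *common* fluorophores would be systematically larger (two
adjacent founders share a colour with probability ``sum(p_c^2)``, which is
dominated by the frequent colours).  Observing no association between clone
size and colour frequency therefore supports expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .params import COLOURS, NO_COLOUR, DivisionLaw, _check_colour_probs
from .tissue import TissueMap


@dataclass
class CloneSet:
    """Partition of labelled cells into clones (size >= 2) and singletons."""

    clones: pd.DataFrame  # clone_id, colour, size, section_id, region, vessel_ids, member_cell_ids
    singletons: pd.DataFrame  # cell_id, colour, section_id, vessel_id, region
    adjacency: object = 6

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    @property
    def founder_events(self) -> int:
        return self.n_clones + self.n_singletons


def _component_labels_6(cells: pd.DataFrame) -> np.ndarray:
    """Connected components among same-colour labelled cells, 6-connectivity."""
    n = len(cells)
    pos = {}
    xs = cells["x"].to_numpy()
    ys = cells["y"].to_numpy()
    zs = cells["z"].to_numpy()
    cols = cells["colour"].to_numpy()
    for i in range(n):
        pos[(xs[i], ys[i], zs[i])] = i
    rows, cols_idx = [], []
    for i in range(n):
        for off in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            j = pos.get((xs[i] + off[0], ys[i] + off[1], zs[i] + off[2]))
            if j is not None and cols[j] == cols[i]:
                rows.append(i)
                cols_idx.append(j)
    graph = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols_idx)), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def _component_labels_radius(cells: pd.DataFrame, radius: float) -> np.ndarray:
    """Components among same-colour cells within Euclidean ``radius`` (for
    imported real segmentations where positions are not a clean lattice)."""
    n = len(cells)
    coords = cells[["x", "y", "z"]].to_numpy(dtype=float)
    cols = cells["colour"].to_numpy()
    pairs = cKDTree(coords).query_pairs(radius, output_type="ndarray")
    if len(pairs):
        keep = cols[pairs[:, 0]] == cols[pairs[:, 1]]
        pairs = pairs[keep]
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def call_clones(tissue: TissueMap, adjacency=6) -> CloneSet:
    """Partition labelled cells into maximal connected monochromatic components.

    Components of size >= 2 become clones; size-1 components are recorded as
    singletons.  ``adjacency`` is either ``6`` (lattice 6-connectivity,
    default) or ``("radius", r)`` for a metric-distance rule.
    """
    tissue.validate()
    lab = tissue.labelled.reset_index(drop=True)
    if len(lab) == 0:
        clones = pd.DataFrame(
            columns=["clone_id", "colour", "size", "section_id", "region",
                     "vessel_ids", "member_cell_ids"]
        )
        singles = pd.DataFrame(columns=["cell_id", "colour", "section_id", "vessel_id", "region"])
        return CloneSet(clones=clones, singletons=singles, adjacency=adjacency)

    if adjacency == 6 or adjacency == "6":
        labels = _component_labels_6(lab)
    elif isinstance(adjacency, tuple) and adjacency[0] == "radius":
        labels = _component_labels_radius(lab, float(adjacency[1]))
    else:
        raise ValueError(f"unknown adjacency rule {adjacency!r}; use 6 or ('radius', r)")

    lab = lab.assign(_comp=labels)
    clone_rows, single_rows = [], []
    clone_id = 0
    for _, grp in lab.groupby("_comp", sort=True):
        if len(grp) >= 2:
            clone_rows.append(
                dict(
                    clone_id=clone_id,
                    colour=grp["colour"].iloc[0],
                    size=len(grp),
                    section_id=int(grp["section_id"].iloc[0]),
                    region=grp["region"].iloc[0],
                    vessel_ids=tuple(sorted(grp["vessel_id"].unique().tolist())),
                    member_cell_ids=tuple(grp["cell_id"].tolist()),
                )
            )
            clone_id += 1
        else:
            r = grp.iloc[0]
            single_rows.append(
                dict(
                    cell_id=r["cell_id"],
                    colour=r["colour"],
                    section_id=int(r["section_id"]),
                    vessel_id=r["vessel_id"],
                    region=r["region"],
                )
            )
    clones = pd.DataFrame(
        clone_rows,
        columns=["clone_id", "colour", "size", "section_id", "region",
                 "vessel_ids", "member_cell_ids"],
    )
    singles = pd.DataFrame(
        single_rows, columns=["cell_id", "colour", "section_id", "vessel_id", "region"]
    )
    return CloneSet(clones=clones, singletons=singles, adjacency=adjacency)


# ---------------------------------------------------------------------------
# clonal statistics
# ---------------------------------------------------------------------------


@dataclass
class ClonalStats:
    """Per-sample clonal summary (pooled values plus a per-section table)."""

    has_labelled: bool
    mean_clone_size: float | None
    sd_clone_size: float | None
    per_colour_sizes: dict
    colour_fractions: dict
    n_clones: int
    n_singletons: int
    founder_events: int
    founder_events_per_section_mean: float | None
    founder_events_per_section_sd: float | None
    singleton_fraction: float | None
    monoclonal_vessel_fraction: float | None
    polychromatic_vessel_fraction: float | None
    n_classified_vessels: int
    edu_total_fraction: float | None
    edu_confetti_fraction: float | None
    per_section: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "per_section"}
        d["per_colour_sizes"] = {k: list(map(int, v)) for k, v in self.per_colour_sizes.items()}
        return d


def classify_vessels(tissue: TissueMap, min_labelled: int = 2) -> pd.DataFrame:
    """Classify each vessel as monoclonal, polychromatic or unclassified.

    A vessel with at least ``min_labelled`` labelled cells is *monoclonal* if
    all its labelled cells share one fluorophore and *polychromatic*
    otherwise; vessels below the threshold are unclassified and excluded from
    the fractions.  Classification depends only on the labelled cells of each
    vessel.
    """
    if min_labelled < 1:
        raise ValueError("min_labelled must be >= 1")
    cells = tissue.cells
    lab = tissue.labelled
    counts = lab.groupby("vessel_id")["colour"].agg(["size", "nunique"])
    out = pd.DataFrame(
        {
            "vessel_id": cells["vessel_id"].unique(),
        }
    ).set_index("vessel_id")
    out["section_id"] = cells.groupby("vessel_id")["section_id"].first()
    out["n_labelled"] = counts["size"].reindex(out.index).fillna(0).astype(int)
    out["n_colours"] = counts["nunique"].reindex(out.index).fillna(0).astype(int)
    status = np.where(
        out["n_labelled"] < min_labelled,
        "unclassified",
        np.where(out["n_colours"] <= 1, "monoclonal", "polychromatic"),
    )
    out["status"] = status
    return out.reset_index()


def vessel_fractions(vessel_table: pd.DataFrame) -> tuple[float | None, float | None, int]:
    """Pooled (monoclonal, polychromatic) fractions over classified vessels."""
    classified = vessel_table[vessel_table["status"] != "unclassified"]
    n = len(classified)
    if n == 0:
        return None, None, 0
    mono = float((classified["status"] == "monoclonal").mean())
    return mono, 1.0 - mono, n


def clonal_stats(
    clone_set: CloneSet, tissue: TissueMap, min_labelled_vessel: int = 2
) -> ClonalStats:
    """Compute all clonal summary statistics for a tissue map.

    With no labelled cells the statistics are reported as absent
    (``has_labelled=False``), not as zeros.
    """
    cells = tissue.cells
    lab = tissue.labelled
    n_lab = len(lab)
    if n_lab == 0:
        warnings.warn("no labelled cells; clonal statistics are undefined", stacklevel=2)
        return ClonalStats(
            has_labelled=False, mean_clone_size=None, sd_clone_size=None,
            per_colour_sizes={}, colour_fractions={}, n_clones=0, n_singletons=0,
            founder_events=0, founder_events_per_section_mean=None,
            founder_events_per_section_sd=None, singleton_fraction=None,
            monoclonal_vessel_fraction=None, polychromatic_vessel_fraction=None,
            n_classified_vessels=0, edu_total_fraction=None, edu_confetti_fraction=None,
            per_section=pd.DataFrame(),
        )

    sizes = clone_set.clones["size"].to_numpy()
    mean_size = float(sizes.mean()) if len(sizes) else None
    sd_size = float(sizes.std(ddof=1)) if len(sizes) > 1 else (0.0 if len(sizes) else None)
    per_colour_sizes = {
        c: clone_set.clones.loc[clone_set.clones["colour"] == c, "size"].tolist()
        for c in COLOURS
    }
    colour_fractions = {
        c: float((lab["colour"] == c).mean()) for c in COLOURS
    }

    singleton_cells = clone_set.n_singletons
    singleton_fraction = singleton_cells / n_lab

    edu_confetti = float(lab["edu"].mean())
    n_ec = len(cells)
    edu_ec = int(cells["edu"].sum())
    if tissue.background is not None and len(tissue.background):
        n_total = n_ec + int(tissue.background["n_cells"].sum())
        edu_total = (edu_ec + int(tissue.background["n_edu"].sum())) / n_total
    else:
        edu_total = edu_ec / n_ec  # EC-only denominator; flagged in the report

    vt = classify_vessels(tissue, min_labelled=min_labelled_vessel)
    mono, poly, n_classified = vessel_fractions(vt)

    # per-section table
    sections = tissue.section_ids()
    rows = []
    clone_by_sec = clone_set.clones.groupby("section_id") if len(clone_set.clones) else None
    single_by_sec = clone_set.singletons.groupby("section_id") if len(clone_set.singletons) else None
    for s in sections:
        sec_cells = cells[cells["section_id"] == s]
        sec_lab = sec_cells[sec_cells["colour"] != NO_COLOUR]
        nc = len(clone_by_sec.get_group(s)) if clone_by_sec is not None and s in clone_by_sec.groups else 0
        csizes = (
            clone_by_sec.get_group(s)["size"].to_numpy()
            if clone_by_sec is not None and s in clone_by_sec.groups
            else np.array([])
        )
        ns = len(single_by_sec.get_group(s)) if single_by_sec is not None and s in single_by_sec.groups else 0
        n_sec_lab = len(sec_lab)
        rows.append(
            dict(
                section_id=int(s),
                n_cells=len(sec_cells),
                n_labelled=n_sec_lab,
                n_clones=nc,
                n_singletons=ns,
                founder_events=nc + ns,
                mean_clone_size=float(csizes.mean()) if len(csizes) else np.nan,
                singleton_fraction=(ns / n_sec_lab) if n_sec_lab else np.nan,
                edu_confetti_fraction=float(sec_lab["edu"].mean()) if n_sec_lab else np.nan,
                yfp_fraction=float((sec_lab["colour"] == "YFP").mean()) if n_sec_lab else np.nan,
            )
        )
    per_section = pd.DataFrame(rows)
    fe = per_section["founder_events"].to_numpy(dtype=float)

    return ClonalStats(
        has_labelled=True,
        mean_clone_size=mean_size,
        sd_clone_size=sd_size,
        per_colour_sizes=per_colour_sizes,
        colour_fractions=colour_fractions,
        n_clones=clone_set.n_clones,
        n_singletons=clone_set.n_singletons,
        founder_events=clone_set.founder_events,
        founder_events_per_section_mean=float(fe.mean()),
        founder_events_per_section_sd=float(fe.std(ddof=1)) if len(fe) > 1 else 0.0,
        singleton_fraction=float(singleton_fraction),
        monoclonal_vessel_fraction=mono,
        polychromatic_vessel_fraction=poly,
        n_classified_vessels=n_classified,
        edu_total_fraction=float(edu_total),
        edu_confetti_fraction=edu_confetti,
        per_section=per_section,
    )


def estimate_recombination_efficiency(tissue: TissueMap) -> float:
    """Recover the Cre-recombination efficiency from ground-truth founder ids.

    Eligible cells are those present at induction: labelled founders (one per
    distinct ``founder_id``) plus unlabelled cells.  Labelled non-founder
    cells are post-induction progeny and are excluded from the denominator.
    """
    lab = tissue.labelled
    if lab["founder_id"].isna().all() and len(lab):
        raise ValueError("tissue has no ground-truth founder ids; cannot recover efficiency")
    n_founders = int(lab["founder_id"].nunique())
    n_unlabelled = int((tissue.cells["colour"] == NO_COLOUR).sum())
    eligible = n_founders + n_unlabelled
    if eligible == 0:
        raise ValueError("no eligible cells in tissue")
    return n_founders / eligible


# ---------------------------------------------------------------------------
# merger-vs-expansion inference
# ---------------------------------------------------------------------------


def colour_collision_probability(k: int, colour_probs) -> float:
    """Probability that ``k`` independent founders all drew the same fluorophore.

    Equals ``sum_c p_c**k``; for the uniform 4-colour vector this is
    ``4**(1-k)``.  This is the analytic null for a patch of ``k`` adjacent
    independent founders appearing monochromatic (a "colour collision").
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"k must be an integer >= 1, got {k!r}")
    p = _check_colour_probs(colour_probs)
    return float(np.sum(p ** k))


@dataclass
class MergerTestResult:
    statistic: float  # Spearman rho between clone size and colour frequency
    p_value: float  # one-sided permutation p (add-one rule)
    kw_statistic: float | None
    kw_pvalue: float | None
    n_resamples: int
    n_clones: int
    colour_freqs: dict
    expected_size_by_colour_under_merger: dict | None = None


def merger_expected_sizes(
    colour_probs,
    division_law: DivisionLaw,
    cluster_rate: float,
    n_events: int = 200_000,
    seed: int = 0,
) -> dict:
    """Expected apparent clone size per colour under the merger alternative.

    Simulates founder events of which a fraction ``cluster_rate`` arrive as
    adjacent pairs; pairs sharing a colour merge into one apparent clone.
    Common colours collide more often, so their apparent clones are larger.
    """
    rng = np.random.default_rng(seed)
    p = _check_colour_probs(colour_probs)
    sizes = division_law.sample(rng, n_events)
    colours = rng.choice(4, size=n_events, p=p)
    paired = rng.random(n_events // 2) < cluster_rate
    out_sizes: dict[int, list] = {c: [] for c in range(4)}
    i = 0
    for pair_flag in paired:
        if pair_flag and colours[i] == colours[i + 1]:
            out_sizes[colours[i]].append(int(sizes[i] + sizes[i + 1]))
        else:
            out_sizes[colours[i]].append(int(sizes[i]))
            out_sizes[colours[i + 1]].append(int(sizes[i + 1]))
        i += 2
    return {COLOURS[c]: float(np.mean(v)) for c, v in out_sizes.items() if v}


def sample_clone_set(
    n_clones: int,
    colour_probs,
    division_law: DivisionLaw | None = None,
    merger_boost: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a synthetic clone table (colour, size) for calibration experiments.

    Under the expansion regime (``merger_boost = 0``) clone size is
    independent of colour.  With ``merger_boost = b`` the expected clone size
    scales with colour frequency: the rarest colour keeps the base mean and
    the commonest gains a factor ``1 + b`` (a stylized merger signature).
    """
    rng = np.random.default_rng(seed)
    p = _check_colour_probs(colour_probs)
    law = division_law or DivisionLaw()
    colours = rng.choice(4, size=n_clones, p=p)
    if merger_boost == 0.0:
        sizes = law.sample(rng, n_clones)
    else:
        pmin, pmax = p.min(), p.max()
        span = (pmax - pmin) or 1.0
        sizes = np.empty(n_clones, dtype=np.int64)
        for c in range(4):
            mask = colours == c
            if not mask.any():
                continue
            mult = 1.0 + merger_boost * (p[c] - pmin) / span
            sizes[mask] = law.scaled(mult).sample(rng, int(mask.sum()))
    return pd.DataFrame({"colour": [COLOURS[c] for c in colours], "size": sizes})


def _rankdata(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a)


def merger_test(
    clones,
    colour_fractions: dict | None = None,
    n_resamples: int = 1000,
    seed: int | None = None,
    expected_under_merger: bool = False,
    merger_cluster_rate: float = 0.25,
) -> MergerTestResult:
    """Test whether clone size is associated with colour frequency.

    H0 (clonal expansion): clone size is independent of fluorophore.  Under
    the merger alternative, apparent clones of the common colours are larger,
    so the one-sided test statistic is the Spearman correlation between clone
    size and the frequency of the clone's colour; its null distribution is
    obtained by permuting colour labels over clones.  The p-value uses the
    add-one rule ``p = (1 + #{null >= obs}) / (1 + n_resamples)``.

    A Kruskal-Wallis test of size across colours is reported alongside
    (asymptotic p).  ``clones`` is a :class:`CloneSet` or a DataFrame with
    ``colour`` and ``size`` columns.
    """
    df = clones.clones if isinstance(clones, CloneSet) else clones
    if len(df) == 0:
        raise ValueError("no clones to test")
    colours = df["colour"].to_numpy()
    sizes = df["size"].to_numpy(dtype=float)
    present = pd.unique(colours)
    if len(present) < 2:
        raise ValueError("merger test undefined for monochromatic clone sets")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")

    if colour_fractions is None:
        vc = pd.Series(colours).value_counts(normalize=True)
        colour_fractions = vc.to_dict()
    freqs = np.array([colour_fractions.get(c, 0.0) for c in colours], dtype=float)

    rng = np.random.default_rng(seed)
    ry = _rankdata(sizes)
    rx = _rankdata(freqs)
    ry_c = ry - ry.mean()
    rx_c = rx - rx.mean()
    denom = np.sqrt((ry_c**2).sum() * (rx_c**2).sum())
    degenerate = denom == 0.0
    if degenerate:
        obs = 0.0
        p_value = 1.0
    else:
        obs = float((rx_c * ry_c).sum() / denom)
        # permute the colour labels over clones == permute the freq covariate
        perm = np.argsort(rng.random((n_resamples, len(sizes))), axis=1)
        null = (rx_c[perm] @ ry_c) / denom
        p_value = float((1 + int((null >= obs - 1e-12).sum())) / (1 + n_resamples))

    groups = [sizes[colours == c] for c in present]
    kw_stat = kw_p = None
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            kw = stats.kruskal(*groups)
        if np.isfinite(kw.statistic):
            kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)
    except ValueError:
        pass  # all sizes identical: KW undefined

    expected = None
    if expected_under_merger:
        p_vec = np.zeros(4)
        for i, c in enumerate(COLOURS):
            p_vec[i] = colour_fractions.get(c, 0.0)
        if p_vec.sum() > 0:
            p_vec = p_vec / p_vec.sum()
        base_mean = float(sizes.mean())
        law = DivisionLaw("fixed", mean=max(2.0, round(base_mean)), sd=0.0)
        expected = merger_expected_sizes(p_vec, law, merger_cluster_rate, seed=seed or 0)

    return MergerTestResult(
        statistic=obs,
        p_value=p_value,
        kw_statistic=kw_stat,
        kw_pvalue=kw_p,
        n_resamples=n_resamples,
        n_clones=len(df),
        colour_freqs={c: float(colour_fractions.get(c, 0.0)) for c in present},
        expected_size_by_colour_under_merger=expected,
    )


def compare_groups(
    per_section_a: pd.DataFrame,
    per_section_b: pd.DataFrame,
    metric: str,
    method: str = "mannwhitney",
) -> dict:
    """Two-sample comparison of a per-section clonal metric between groups.

    Default Mann-Whitney U (two-sided); ``method='welch'`` uses Welch's t.
    Returns group means +- SD, the difference of means and the p-value.
    """
    for name, df in (("a", per_section_a), ("b", per_section_b)):
        if metric not in df.columns:
            raise KeyError(f"metric {metric!r} absent from group {name}")
    a = per_section_a[metric].dropna().to_numpy(dtype=float)
    b = per_section_b[metric].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 sections per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        p = 1.0
    elif method == "mannwhitney":
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    elif method == "welch":
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return dict(
        metric=metric,
        method=method,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        difference=float(b.mean() - a.mean()),
        p_value=p,
        n_a=len(a),
        n_b=len(b),
    )
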