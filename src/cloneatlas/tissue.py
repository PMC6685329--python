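"""Tissue-map container and the Confetti lineage-tracing tissue simulator.

A :class:`TissueMap` is a table with one row per endothelial cell on an
integer 3D lattice: position, fluorophore label (or ``NONE``), vessel id, EdU
status, region tag, section id and -- for synthetic tissue -- the ground-truth
founder id.  An optional per-section *background* table carries the
non-endothelial compartment as counts only (used for the total-cell EdU
fraction; non-EC cells are never simulated individually).

Geometry of the simulator
-------------------------
Sections are non-overlapping z-slabs.  Within a section, vessel segments run
along the x axis, each in a private 3-cell-wide corridor (3x3 cross-section in
y/z) separated from its neighbours by empty lattice rows, so clones from
different vessels can never touch under 6-connectivity.  Eligible endothelial
cells ("anchors") are laid along each vessel with a forward gap of >= 3 lattice
steps after the previous patch, so independent founder patches are spatially
separated and the flood-fill clone caller recovers founder events exactly --
unless ``merger_regime`` is on, in which case a configurable fraction of
anchors is planted as *pairs of adjacent independent founders*, producing
apparent clone mergers whenever the pair shares a fluorophore.

Each anchor recombines with probability ``recombination_efficiency`` and, if
labelled, draws a fluorophore from ``colour_probs``.  A labelled founder
divides with the derived founder-level division probability; its clone size is
drawn from the division law and the patch is grown as a +x-biased Eden process
(constrained random walk) inside the vessel corridor, reproducing elongated
patches along vessels.  EdU marks each labelled cell independently at the
preset S-phase window rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    COLOURS,
    COLOUR_VOCAB,
    NO_COLOUR,
    CapacityError,
    SimTissueParams,
)

TISSUE_COLUMNS = [
    "cell_id",
    "x",
    "y",
    "z",
    "colour",
    "vessel_id",
    "edu",
    "region",
    "founder_id",
    "section_id",
]

# 6-connected lattice neighbourhood (the package-wide adjacency rule).
NEIGHBOUR_OFFSETS = (
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
)


@dataclass
class TissueMap:
    """Per-cell endothelial table plus optional non-EC background counts."""

    cells: pd.DataFrame
    background: pd.DataFrame | None = None  # columns: section_id, n_cells, n_edu
    params: SimTissueParams | None = field(default=None, repr=False)

    def __post_init__(self):
        missing = [c for c in TISSUE_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"tissue table missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        cells = self.cells
        dup_ids = cells.loc[cells["cell_id"].duplicated(), "cell_id"].unique()
        if len(dup_ids):
            raise ValueError(f"duplicate cell_id values: {sorted(dup_ids.tolist())[:10]}")
        bad = set(cells["colour"].unique()) - set(COLOUR_VOCAB)
        if bad:
            raise ValueError(
                f"unknown colour token(s) {sorted(bad)}; valid tokens are {list(COLOUR_VOCAB)}"
            )
        pos = cells[["x", "y", "z"]]
        dup_pos = pos.duplicated(keep=False)
        if dup_pos.any():
            offenders = cells.loc[dup_pos, "cell_id"].tolist()[:10]
            raise ValueError(f"cells share a lattice position; offending cell_ids include {offenders}")

    # -- convenience views -----------------------------------------------

    @property
    def labelled(self) -> pd.DataFrame:
        return self.cells[self.cells["colour"] != NO_COLOUR]

    @property
    def n_sections(self) -> int:
        return int(self.cells["section_id"].nunique())

    def section_ids(self) -> np.ndarray:
        return np.sort(self.cells["section_id"].unique())


def _grow_patch(
    rng: np.random.Generator,
    anchor: tuple,
    size: int,
    y_range: tuple,
    z_range: tuple,
    x_min: int,
    occupied: set,
) -> list:
    """Grow a connected patch of ``size`` sites from ``anchor`` inside a corridor.

    Eden growth with a +x bias: repeatedly pick a random patch cell and attach
    an unoccupied 6-neighbour, preferring the +x direction, constrained to
    ``x >= x_min`` and the corridor's y/z ranges.  The corridor is unbounded in
    +x, so growth always succeeds.
    """
    patch = [anchor]
    occupied.add(anchor)
    active = [anchor]
    # +x listed twice: mild elongation bias along the vessel axis.
    dirs = ((1, 0, 0),) + NEIGHBOUR_OFFSETS
    while len(patch) < size:
        i = rng.integers(len(active))
        cx, cy, cz = active[i]
        order = rng.permutation(len(dirs))
        placed = False
        for j in order:
            dx, dy, dz = dirs[j]
            cand = (cx + dx, cy + dy, cz + dz)
            if cand in occupied:
                continue
            if cand[0] < x_min:
                continue
            if not (y_range[0] <= cand[1] <= y_range[1]):
                continue
            if not (z_range[0] <= cand[2] <= z_range[1]):
                continue
            patch.append(cand)
            occupied.add(cand)
            active.append(cand)
            placed = True
            break
        if not placed:
            active.pop(i)
            if not active:  # pragma: no cover - corridor is +x unbounded
                raise CapacityError("patch growth exhausted its corridor")
    return patch


def simulate_tissue(params: SimTissueParams) -> TissueMap:
    """Simulate a Confetti-labelled endothelial tissue map.

    Deterministic given ``params.seed``.  Raises :class:`CapacityError` when
    the lattice slab cannot host the requested sections, vessels or clone
    sizes (never truncates silently).
    """
    if params.seed is None:
        raise ValueError("params.seed is required (reproducibility is mandatory)")
    rng = np.random.default_rng(params.seed)

    eps = params.recombination_efficiency
    d = params.founder_division_prob
    p = np.asarray(params.colour_probs, dtype=float)
    anchors = params.anchors_per_section
    w2 = params.two_anchor_vessel_fraction
    # Expected two-anchor vessels per section; the per-section count is
    # stochastically rounded so the realized vessel-type fraction is unbiased.
    n2_mean = anchors * w2 / (1.0 + w2)
    n2_max = int(np.ceil(n2_mean))
    max_vessels = anchors  # upper bound (all one-anchor)

    dim_x, dim_y, dim_z = params.lattice_dims
    if 4 * params.n_sections > dim_z:
        raise CapacityError(
            f"lattice z dimension {dim_z} too small for {params.n_sections} sections"
        )
    if max_vessels and 4 * max_vessels > dim_y:
        raise CapacityError(f"lattice y dimension {dim_y} too small for {max_vessels} vessels")

    records: list[tuple] = []
    bg_rows = []
    cell_id = 0
    vessel_id = 0
    founder_id = 0
    bg_rate = params.background_edu_rate

    for s in range(params.n_sections):
        z0 = 4 * s
        z_range = (z0, z0 + 2)
        zc = z0 + 1
        n2 = int(n2_mean) + int(rng.random() < (n2_mean - int(n2_mean)))
        n2 = min(n2, anchors // 2)
        n1 = anchors - 2 * n2
        vessel_types = np.array([2] * n2 + [1] * n1, dtype=np.int64)
        rng.shuffle(vessel_types)
        for vj, n_anchors in enumerate(vessel_types):
            yc = 4 * vj + 1
            y_range = (yc - 1, yc + 1)
            occupied: set = set()
            cursor = 0
            for _ in range(int(n_anchors)):
                planted_pair = params.merger_regime and rng.random() < params.merger_cluster_rate
                n_founders_here = 2 if planted_pair else 1
                for k in range(n_founders_here):
                    if cursor >= dim_x:
                        raise CapacityError(
                            f"section {s} vessel {vessel_id}: x extent {cursor} exceeds "
                            f"lattice dimension {dim_x}; enlarge lattice_dims or reduce "
                            "founder_density / clone sizes"
                        )
                    anchor = (cursor, yc, zc)
                    labelled = planted_pair or (rng.random() < eps)
                    if not labelled:
                        records.append(
                            (cell_id, *anchor, NO_COLOUR, vessel_id, False, params.region, -1, s)
                        )
                        cell_id += 1
                        occupied.add(anchor)
                        cursor += 3
                        continue
                    colour = COLOURS[rng.choice(4, p=p)]
                    if rng.random() < d:
                        size = int(params.division_law.sample(rng, 1)[0])
                    else:
                        size = 1
                    patch = _grow_patch(rng, anchor, size, y_range, z_range, cursor, occupied)
                    edu = rng.random(len(patch)) < params.edu_window_fraction
                    for (px, py, pz), e in zip(patch, edu):
                        records.append(
                            (cell_id, px, py, pz, colour, vessel_id, bool(e), params.region,
                             founder_id, s)
                        )
                        cell_id += 1
                    founder_id += 1
                    max_x = max(c[0] for c in patch)
                    # Planted pairs sit at adjacent sites; independent anchors
                    # keep a >= 3 gap so patches never touch.
                    cursor = max_x + (1 if (planted_pair and k == 0) else 3)
            vessel_id += 1
        if params.background_cells_per_section > 0:
            n_bg = params.background_cells_per_section
            bg_rows.append((s, n_bg, int(rng.binomial(n_bg, bg_rate))))

    cells = pd.DataFrame(records, columns=TISSUE_COLUMNS)
    cells["founder_id"] = cells["founder_id"].astype("Int64")
    cells.loc[cells["founder_id"] == -1, "founder_id"] = pd.NA
    background = (
        pd.DataFrame(bg_rows, columns=["section_id", "n_cells", "n_edu"]) if bg_rows else None
    )
    return TissueMap(cells=cells, background=background, params=params)
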