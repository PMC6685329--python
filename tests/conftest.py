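"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from cloneatlas import SimTissueParams, TissueMap
from cloneatlas.counts import Archetype, SimCountsParams
from cloneatlas.tissue import TISSUE_COLUMNS


# ---------------------------------------------------------------------------
# independent flood-fill oracle (breadth-first, dict-based; deliberately
# written differently from the package's sparse-graph implementation)
# ---------------------------------------------------------------------------


def flood_fill_components(cells: pd.DataFrame) -> list[frozenset]:
    """Monochromatic connected components (6-adjacency) among labelled cells."""
    lab = cells[cells["colour"] != "NONE"]
    by_pos = {
        (r.x, r.y, r.z): (r.cell_id, r.colour) for r in lab.itertuples(index=False)
    }
    seen: set = set()
    comps = []
    for pos, (cid, colour) in by_pos.items():
        if pos in seen:
            continue
        stack = [pos]
        seen.add(pos)
        comp = set()
        while stack:
            p = stack.pop()
            comp.add(by_pos[p][0])
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if q in by_pos and q not in seen and by_pos[q][1] == colour:
                    seen.add(q)
                    stack.append(q)
        comps.append(frozenset(comp))
    return comps


def make_tissue(rows, background=None) -> TissueMap:
    """Build a TissueMap from (cell_id, x, y, z, colour, vessel, edu, region,
    founder, section) tuples."""
    df = pd.DataFrame(rows, columns=TISSUE_COLUMNS)
    df["founder_id"] = df["founder_id"].astype("Int64")
    return TissueMap(cells=df, background=background)


def random_tissue(rng: np.random.Generator, shape=(15, 15, 5), fill=0.4) -> TissueMap:
    """Random colouring of a small lattice (includes unlabelled cells)."""
    nx, ny, nz = shape
    coords = np.array([(x, y, z) for x in range(nx) for y in range(ny) for z in range(nz)])
    keep = rng.random(len(coords)) < fill
    coords = coords[keep]
    colours = rng.choice(["YFP", "RFP", "nGFP", "mCFP", "NONE"], size=len(coords))
    rows = [
        (i, int(c[0]), int(c[1]), int(c[2]), col, 0, False, "healthy", pd.NA, 0)
        for i, (c, col) in enumerate(zip(coords, colours))
    ]
    return make_tissue(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def healthy_tissue():
    """A moderately sized healthy-preset simulation shared across tests."""
    from cloneatlas import simulate_tissue, tissue_preset

    return simulate_tissue(tissue_preset("healthy", seed=42, n_sections=10))


@pytest.fixture(scope="session")
def two_state_counts() -> ad.AnnData:
    """Two archetypes with disjoint 10-gene marker sets at fold-change 8."""
    from cloneatlas import simulate_counts

    arks = (
        Archetype(name="A", markers={f"GA{i}": 8.0 for i in range(10)},
                  healthy_share=0.5, n_program_genes=0),
        Archetype(name="B", markers={f"GB{i}": 8.0 for i in range(10)},
                  healthy_share=0.5, n_program_genes=0),
    )
    params = SimCountsParams(
        n_cells=(250, 250), n_genes=800, archetypes=arks,
        contaminant_fraction=0.0, lowdepth_cell_fraction=0.0,
        mito_law=("fixed", 0.05), seed=7,
    )
    return simulate_counts(params)


def make_counts_adata(matrix, gene_names, groups=None) -> ad.AnnData:
    """Small dense-count AnnData for QC boundary tests."""
    from scipy import sparse

    X = sparse.csr_matrix(np.asarray(matrix))
    obs = pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    if groups is not None:
        obs["group"] = groups
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=list(gene_names)))
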