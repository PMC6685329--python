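"""Tissue simulator: determinism, conservation laws, capacity, merger planting."""

import numpy as np
import pandas as pd
import pytest

from cloneatlas import CapacityError, DivisionLaw, SimTissueParams, simulate_tissue, tissue_preset
from conftest import flood_fill_components


def small_params(**overrides):
    base = dict(
        founder_density=20.0, n_sections=3, background_cells_per_section=0,
        monoclonal_vessel_target=0.745, seed=1,
    )
    base.update(overrides)
    return SimTissueParams(**base)


def test_zero_recombination_gives_no_labels():
    t = simulate_tissue(small_params(recombination_efficiency=0.0, seed=3))
    assert len(t.labelled) == 0
    assert (t.cells["colour"] == "NONE").all()


def test_seeded_determinism():
    a = simulate_tissue(small_params(seed=11))
    b = simulate_tissue(small_params(seed=11))
    pd.testing.assert_frame_equal(a.cells, b.cells)
    c = simulate_tissue(small_params(seed=12))
    assert not a.cells.equals(c.cells)


def test_seed_required():
    with pytest.raises(ValueError, match="seed"):
        simulate_tissue(small_params(seed=None))


def test_positions_unique_and_founder_colour_shared(healthy_tissue):
    cells = healthy_tissue.cells
    assert not cells[["x", "y", "z"]].duplicated().any()
    lab = healthy_tissue.labelled
    assert (lab.groupby("founder_id")["colour"].nunique() == 1).all()


def test_colour_conservation(healthy_tissue):
    """Founder colour fractions converge to colour_probs (law of large numbers)."""
    lab = healthy_tissue.labelled
    founders = lab.drop_duplicates("founder_id")
    n = len(founders)
    probs = dict(zip(("YFP", "RFP", "nGFP", "mCFP"), healthy_tissue.params.colour_probs))
    for colour, p in probs.items():
        frac = (founders["colour"] == colour).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 4 * se


def test_founder_conservation_no_merger(healthy_tissue):
    """Distinct founder ids == monochromatic components (flood-fill oracle)."""
    comps = flood_fill_components(healthy_tissue.cells)
    assert len(comps) == healthy_tissue.labelled["founder_id"].nunique()


def test_ground_truth_patch_size_matches_target():
    """Mean ground-truth patch size of dividing founders hits the preset mean."""
    sizes = []
    for seed in range(4):
        t = simulate_tissue(tissue_preset("healthy", seed=seed, n_sections=30))
        per_founder = t.labelled.groupby("founder_id").size()
        sizes.append(per_founder[per_founder >= 2])
    sizes = np.concatenate([s.to_numpy() for s in sizes])
    se = sizes.std(ddof=1) / np.sqrt(len(sizes))
    assert abs(sizes.mean() - 4.0) < 3 * se


def test_capacity_error_on_tiny_lattice():
    with pytest.raises(CapacityError):
        simulate_tissue(small_params(lattice_dims=(5, 4096, 4096), seed=1))
    with pytest.raises(CapacityError, match="sections"):
        simulate_tissue(small_params(n_sections=10, lattice_dims=(1000, 4096, 8), seed=1))


def test_merger_regime_monochromatic_clusters():
    """With a single colour, planted multi-founder clusters are monochromatic
    and ground-truth founders exceed apparent components."""
    params = small_params(
        colour_probs=(1.0, 0.0, 0.0, 0.0),
        monoclonal_vessel_target=None,  # single colour: all vessels monoclonal
        merger_regime=True,
        merger_cluster_rate=0.5,
        founder_density=30.0,
        seed=21,
    )
    t = simulate_tissue(params)
    lab = t.labelled
    assert set(lab["colour"]) == {"YFP"}
    comps = flood_fill_components(t.cells)
    n_founders = lab["founder_id"].nunique()
    assert n_founders > len(comps)
    # each component is monochromatic by construction of the oracle itself;
    # verify multi-founder components exist
    founder_of = lab.set_index("cell_id")["founder_id"]
    multi = [c for c in comps if founder_of.loc[list(c)].nunique() > 1]
    assert multi


def test_edu_only_on_labelled_cells(healthy_tissue):
    unlab = healthy_tissue.cells[healthy_tissue.cells["colour"] == "NONE"]
    assert not unlab["edu"].any()


def test_background_compartment_counts():
    t = simulate_tissue(small_params(background_cells_per_section=5000, seed=4))
    assert len(t.background) == 3
    assert (t.background["n_edu"] <= t.background["n_cells"]).all()
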