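"""Clone calling, clonal statistics, vessel classification, collision maths."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cloneatlas import (
    call_clones,
    classify_vessels,
    clonal_stats,
    colour_collision_probability,
    compare_groups,
    estimate_recombination_efficiency,
    vessel_fractions,
)
from conftest import flood_fill_components, make_tissue, random_tissue


def _row(cid, x, y, z, colour, vessel=0, edu=False, founder=pd.NA, section=0):
    return (cid, x, y, z, colour, vessel, edu, "healthy", founder, section)


class TestCallClones:
    def test_empty_tissue(self):
        t = make_tissue([_row(0, 0, 0, 0, "NONE")])
        cs = call_clones(t)
        assert cs.n_clones == 0 and cs.n_singletons == 0

    def test_definition_case(self):
        """Two adjacent YFP cells form one clone; a lone RFP is a singleton."""
        t = make_tissue([
            _row(0, 0, 0, 0, "YFP"),
            _row(1, 1, 0, 0, "YFP"),
            _row(2, 2, 0, 0, "RFP"),
        ])
        cs = call_clones(t)
        assert cs.n_clones == 1
        assert cs.clones.iloc[0]["colour"] == "YFP"
        assert cs.clones.iloc[0]["size"] == 2
        assert cs.n_singletons == 1
        assert cs.singletons.iloc[0]["colour"] == "RFP"

    def test_same_colour_required_for_adjacency(self):
        t = make_tissue([_row(0, 0, 0, 0, "YFP"), _row(1, 1, 0, 0, "RFP")])
        cs = call_clones(t)
        assert cs.n_clones == 0 and cs.n_singletons == 2

    def test_duplicate_positions_rejected(self):
        t = make_tissue([_row(0, 0, 0, 0, "YFP")])
        t.cells = pd.concat([t.cells, t.cells.assign(cell_id=99)], ignore_index=True)
        with pytest.raises(ValueError, match="position"):
            call_clones(t)

    def test_unknown_colour_rejected(self):
        t = make_tissue([_row(0, 0, 0, 0, "YFP")])
        t.cells.loc[0, "colour"] = "GFP"
        with pytest.raises(ValueError, match="GFP"):
            call_clones(t)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_tissues(self, seed):
        t = random_tissue(np.random.default_rng(seed))
        cs = call_clones(t)
        ours = {frozenset(c) for c in cs.clones["member_cell_ids"]}
        ours |= {frozenset([c]) for c in cs.singletons["cell_id"]}
        assert ours == set(flood_fill_components(t.cells))

    def test_radius_adjacency_matches_lattice_at_r1(self, rng):
        t = random_tissue(rng)
        a = call_clones(t, adjacency=6)
        b = call_clones(t, adjacency=("radius", 1.0))
        assert a.founder_events == b.founder_events

    def test_merging_two_clones_reduces_events_by_one(self):
        """Metamorphic: recolouring an adjacent clone to match its neighbour
        merges them, reducing founder events by exactly one."""
        rows = [
            _row(0, 0, 0, 0, "YFP"), _row(1, 1, 0, 0, "YFP"),
            _row(2, 2, 0, 0, "RFP"), _row(3, 3, 0, 0, "RFP"),
        ]
        before = call_clones(make_tissue(rows))
        rows_merged = [r[:4] + ("YFP",) + r[5:] for r in rows]
        after = call_clones(make_tissue(rows_merged))
        assert after.founder_events == before.founder_events - 1

    def test_conservation_of_labelled_cells(self, healthy_tissue):
        cs = call_clones(healthy_tissue)
        total = cs.clones["size"].sum() + cs.n_singletons
        assert total == len(healthy_tissue.labelled)


class TestClonalStats:
    def test_direct_count_example(self):
        """One clone of 4 YFP cells + 1 RFP singleton."""
        rows = [_row(i, i, 0, 0, "YFP") for i in range(4)]
        rows.append(_row(4, 10, 0, 0, "RFP"))
        t = make_tissue(rows)
        st_ = clonal_stats(call_clones(t), t)
        assert st_.mean_clone_size == 4
        assert st_.founder_events == 2
        assert st_.singleton_fraction == pytest.approx(0.2)
        assert st_.colour_fractions["YFP"] == pytest.approx(0.8)
        assert st_.colour_fractions["RFP"] == pytest.approx(0.2)

    def test_all_edu_gives_unit_confetti_fraction(self):
        rows = [_row(i, i, 0, 0, "YFP", edu=True) for i in range(3)]
        t = make_tissue(rows)
        st_ = clonal_stats(call_clones(t), t)
        assert st_.edu_confetti_fraction == 1.0

    def test_no_labelled_cells_flagged_absent(self):
        t = make_tissue([_row(0, 0, 0, 0, "NONE")])
        with pytest.warns(UserWarning, match="no labelled"):
            st_ = clonal_stats(call_clones(t), t)
        assert not st_.has_labelled
        assert st_.mean_clone_size is None

    def test_colour_fractions_sum_to_one(self, healthy_tissue):
        st_ = clonal_stats(call_clones(healthy_tissue), healthy_tissue)
        assert sum(st_.colour_fractions.values()) == pytest.approx(1.0)
        assert st_.founder_events >= st_.n_clones
        assert st_.monoclonal_vessel_fraction + st_.polychromatic_vessel_fraction == pytest.approx(1.0)

    def test_recombination_efficiency_recovery(self, healthy_tissue):
        eps = estimate_recombination_efficiency(healthy_tissue)
        assert eps == pytest.approx(0.466, abs=0.03)


class TestClassifyVessels:
    def test_monoclonal_vessel(self):
        rows = [_row(i, i, 0, 0, "RFP", vessel=7) for i in range(5)]
        vt = classify_vessels(make_tissue(rows))
        assert vt.loc[vt["vessel_id"] == 7, "status"].item() == "monoclonal"

    def test_polychromatic_vessel(self):
        rows = [_row(i, i, 0, 0, "YFP", vessel=1) for i in range(3)]
        rows.append(_row(3, 10, 0, 0, "mCFP", vessel=1))
        vt = classify_vessels(make_tissue(rows))
        assert vt["status"].item() == "polychromatic"

    def test_below_threshold_unclassified(self):
        rows = [_row(0, 0, 0, 0, "YFP", vessel=1), _row(1, 5, 5, 0, "NONE", vessel=2)]
        vt = classify_vessels(make_tissue(rows), min_labelled=2)
        assert set(vt["status"]) == {"unclassified"}
        mono, poly, n = vessel_fractions(vt)
        assert mono is None and n == 0

    def test_min_labelled_validated(self, healthy_tissue):
        with pytest.raises(ValueError):
            classify_vessels(healthy_tissue, min_labelled=0)


class TestColourCollision:
    def test_k1_is_one(self):
        assert colour_collision_probability(1, (0.4, 0.3, 0.2, 0.1)) == pytest.approx(1.0)

    def test_uniform_k2(self):
        assert colour_collision_probability(2, (0.25,) * 4) == pytest.approx(0.25)

    def test_uniform_law(self):
        for k in range(1, 7):
            assert colour_collision_probability(k, (0.25,) * 4) == pytest.approx(4.0 ** (1 - k))

    def test_published_bias_vector(self, rng):
        """Direct sum of squares, cross-checked by Monte Carlo founder pairs."""
        p = (0.519 / 1.007, 0.257 / 1.007, 0.113 / 1.007, 0.118 / 1.007)
        got = colour_collision_probability(2, p)
        assert got == pytest.approx(sum(x * x for x in p), abs=1e-15)
        draws = rng.choice(4, size=(10**6, 2), p=np.array(p))
        mc = (draws[:, 0] == draws[:, 1]).mean()
        assert got == pytest.approx(mc, abs=3 * np.sqrt(got * (1 - got) / 10**6))

    @given(k=st.integers(1, 8))
    @settings(max_examples=20, deadline=None)
    def test_strictly_decreasing_in_k(self, k):
        p = (0.519 / 1.007, 0.257 / 1.007, 0.113 / 1.007, 0.118 / 1.007)
        assert colour_collision_probability(k + 1, p) < colour_collision_probability(k, p)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            colour_collision_probability(0, (0.25,) * 4)
        with pytest.raises(ValueError):
            colour_collision_probability(2, (0.5, 0.5, 0.5, -0.5))


class TestCompareGroups:
    def test_identical_groups(self):
        df = pd.DataFrame({"mean_clone_size": [4.0, 4.0, 4.0]})
        out = compare_groups(df, df.copy(), "mean_clone_size")
        assert out["p_value"] == 1.0
        assert out["difference"] == 0.0

    def test_missing_metric(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(KeyError):
            compare_groups(df, df, "missing_metric")

    def test_welch_option(self):
        a = pd.DataFrame({"m": np.arange(10.0)})
        b = pd.DataFrame({"m": np.arange(10.0) + 5})
        out = compare_groups(a, b, "m", method="welch")
        assert out["p_value"] < 0.01
        assert out["difference"] == pytest.approx(5.0)
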