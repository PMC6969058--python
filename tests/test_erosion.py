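"""Extinction orders and diversity-erosion curves."""

import numpy as np
import pandas as pd
import pytest

from test_functional import euclid
from thermovuln.erosion import (ErosionError, ErosionScenario, build_orders,
                                compare_curves, fric_curve,
                                iucn_vulnerability_order, pd_curve,
                                run_erosion, vulnerability_order)
from thermovuln.functional import FunctionalSpace, hull_volume
from thermovuln.phylo import faith_pd
from thermovuln.vulnerability import compute_vulnerability
from test_phylo import random_trees


def vdf(d):
    S = pd.Series({k: 1.0 for k in d})
    P = pd.Series(d)
    return compute_vulnerability(S, P)


def space_from_points(pts, names=None):
    pts = np.asarray(pts, float)
    names = names or [f"s{i}" for i in range(len(pts))]
    coords = pd.DataFrame(pts, index=names,
                          columns=[f"axis{k+1}" for k in range(pts.shape[1])])
    D = pd.DataFrame(euclid(pts), index=names, columns=names)
    return FunctionalSpace(coordinates=coords,
                           eigenvalues=np.ones(pts.shape[1]),
                           quality_msd=0.0, distances=D)


class TestOrders:
    def test_vulnerability_order(self):
        assert vulnerability_order(vdf({"A": 0.9, "B": 0.5, "C": 0.1})) == \
            ["A", "B", "C"]

    def test_all_equal_falls_back_to_lexicographic(self):
        assert vulnerability_order(vdf({"B": 1.0, "A": 1.0, "C": 1.0})) == \
            ["A", "B", "C"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(8)
        d = {f"s{i:02d}": float(rng.random()) for i in range(40)}
        got = vulnerability_order(vdf(d))
        assert got == sorted(d, key=lambda k: (-d[k], k))

    def test_iucn_group_precedence(self):
        V = vdf({"cr_low": 0.01, "lc_high": 1.9})
        status = pd.Series({"cr_low": "CR", "lc_high": "LC"})
        assert iucn_vulnerability_order(V, status) == ["cr_low", "lc_high"]

    def test_iucn_same_status_reduces_to_vulnerability(self):
        V = vdf({"a": 0.2, "b": 0.9, "c": 0.5})
        status = pd.Series({k: "EN" for k in "abc"})
        assert iucn_vulnerability_order(V, status) == vulnerability_order(V)

    def test_iucn_two_key_sort_oracle(self):
        rng = np.random.default_rng(11)
        cats = ["CR", "EN", "VU", "NT", "LC", "DD"]
        d = {f"s{i:02d}": float(rng.random()) for i in range(30)}
        status = pd.Series({k: cats[rng.integers(6)] for k in d})
        got = iucn_vulnerability_order(vdf(d), status)
        oracle = sorted(d, key=lambda k: (cats.index(status[k]), -d[k], k))
        assert got == oracle

    def test_random_orders_seeded_and_distinct(self):
        pool = [f"s{i}" for i in range(12)]
        scen = ErosionScenario("random", n_replicates=5, seed=42)
        a = build_orders(scen, pool)
        b = build_orders(scen, pool)
        assert a == b
        assert len({tuple(o) for o in a}) == 5

    def test_iucn_random_respects_groups(self):
        pool = ["x", "y", "z", "w"]
        status = pd.Series({"x": "LC", "y": "CR", "z": "LC", "w": "EN"})
        scen = ErosionScenario("iucn_random", n_replicates=3, seed=0)
        for order in build_orders(scen, pool, iucn=status):
            assert order[0] == "y" and order[1] == "w"

    def test_deterministic_kind_forces_single_replicate(self):
        scen = ErosionScenario("vulnerability", n_replicates=999)
        assert scen.n_replicates == 1


class TestCurves:
    def test_fric_curve_start_one_and_monotone(self):
        rng = np.random.default_rng(3)
        space = space_from_points(rng.random((10, 3)))
        order = list(space.coordinates.index)
        rng.shuffle(order)
        curve = fric_curve(space, order)
        assert curve[0] == 1.0
        assert np.all(np.diff(curve) <= 1e-12)
        assert curve[-1] == 0.0  # empty pool

    def test_pd_curve_matches_naive_recomputation(self):
        tree = random_trees(1, 9, seed=5)[0]
        rng = np.random.default_rng(1)
        order = list(rng.permutation(tree.tip_labels))
        curve = pd_curve(tree, order)
        for k in range(1, len(order)):
            remaining = order[k:]
            assert curve[k] == pytest.approx(
                faith_pd(tree, remaining).fraction_of_pool)
        assert curve[0] == 1.0 and curve[-1] == 0.0

    def test_pd_curve_monotone(self):
        tree = random_trees(1, 12, seed=6)[0]
        order = sorted(tree.tip_labels)
        curve = pd_curve(tree, order)
        assert np.all(np.diff(curve) <= 1e-12)

    def test_max_steps_truncation(self):
        tree = random_trees(1, 10, seed=7)[0]
        curve = pd_curve(tree, sorted(tree.tip_labels), max_steps=4)
        assert curve.size == 5


class TestRunErosion:
    def test_stochastic_curves_reproducible(self):
        trees = random_trees(3, 8, seed=2)
        scen = ErosionScenario("random", n_replicates=25, seed=9)
        a = run_erosion(scen, "pd", trees=trees)
        b = run_erosion(scen, "pd", trees=trees)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.sd, b.sd)

    def test_random_mean_k1_matches_exhaustive_single_removals(self):
        """With n=8, the random-curve mean at k=1 estimates the average
        over the 8 possible single removals; 999 replicates pin it within
        Monte-Carlo error."""
        rng = np.random.default_rng(17)
        space = space_from_points(rng.random((8, 4)))
        names = list(space.coordinates.index)
        pool_vol, _ = hull_volume(space.coordinates.to_numpy())
        singles = []
        for drop in names:
            rest = [s for s in names if s != drop]
            vol, _ = hull_volume(space.coordinates.loc[rest].to_numpy())
            singles.append(vol / pool_vol)
        exact = np.mean(singles)
        scen = ErosionScenario("random", n_replicates=999, seed=4)
        curve = run_erosion(scen, "fric", space=space, max_steps=1)
        se = np.std(singles, ddof=0) / np.sqrt(999)
        assert abs(curve.values[1] - exact) < 4 * se + 1e-12

    def test_vulnerability_scenario_uses_ranking(self):
        trees = random_trees(2, 6, seed=3)
        V = vdf({t: v for t, v in zip(sorted(trees[0].tip_labels),
                                      [0.9, 0.1, 0.5, 0.7, 0.3, 0.2])})
        curve = run_erosion(ErosionScenario("vulnerability"), "pd",
                            trees=trees, V=V)
        assert curve.species_removed == vulnerability_order(V)
        assert curve.values[0] == 1.0 and curve.values[-1] == 0.0
        assert (curve.sd == 0).all()

    def test_fric_monotone_along_any_scenario(self):
        rng = np.random.default_rng(31)
        space = space_from_points(rng.random((12, 4)))
        scen = ErosionScenario("random", n_replicates=10, seed=5)
        for order in build_orders(scen, space.species):
            curve = fric_curve(space, order)
            assert np.all(np.diff(curve) <= 1e-12)

    def test_curve_dataframe_has_both_step_scales(self):
        trees = random_trees(1, 6, seed=8)
        curve = run_erosion(ErosionScenario("random", n_replicates=2, seed=1),
                            "pd", trees=trees)
        df = curve.to_dataframe()
        assert {"step", "pct_removed", "mean", "sd"} <= set(df.columns)
        assert df["pct_removed"].iloc[-1] == pytest.approx(100.0)


class TestCompareCurves:
    def test_identical_curves_zero_everywhere(self):
        trees = random_trees(1, 6, seed=10)
        c = run_erosion(ErosionScenario("random", n_replicates=3, seed=2),
                        "pd", trees=trees)
        for k in range(c.steps.size):
            assert compare_curves(c, c, k) == 0.0

    def test_step_zero_difference_zero(self):
        trees = random_trees(1, 6, seed=10)
        a = run_erosion(ErosionScenario("random", n_replicates=3, seed=2),
                        "pd", trees=trees)
        b = run_erosion(ErosionScenario("random", n_replicates=3, seed=7),
                        "pd", trees=trees)
        assert compare_curves(a, b, 0) == 0.0

    def test_vertex_first_order_loses_more_than_random(self):
        """Removing hull vertices first erodes FRic faster than random."""
        rng = np.random.default_rng(23)
        pts = np.vstack([np.eye(4) * 3, rng.random((8, 4)) * 0.5 + 0.25])
        space = space_from_points(pts)
        names = list(space.coordinates.index)
        vertex_first = names[:4] + names[4:]
        vertex_curve = fric_curve(space, vertex_first)
        random_mean = run_erosion(
            ErosionScenario("random", n_replicates=200, seed=3),
            "fric", space=space, max_steps=4)
        excess = 100 * (random_mean.values[3] - vertex_curve[3])
        assert excess > 0

    def test_mismatched_pools_rejected(self):
        t6 = random_trees(1, 6, seed=1)
        t8 = random_trees(1, 8, seed=1)
        a = run_erosion(ErosionScenario("random", n_replicates=2, seed=0),
                        "pd", trees=t6)
        b = run_erosion(ErosionScenario("random", n_replicates=2, seed=0),
                        "pd", trees=t8)
        with pytest.raises(ErosionError, match="same pool"):
            compare_curves(a, b, 1)
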