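"""Functional space: weights, Gower, PCoA, quality, FRic, originality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermovuln.functional import (FunctionalSpaceError, GowerPCoA,
                                   fric, function_weights,
                                   functional_originality, gower_distance,
                                   hull_volume, pcoa, space_quality_msd)
from thermovuln.functional import FunctionalSpace
from thermovuln.schema import SchemaError, Trait, TraitSchema


def schema_of(*traits):
    return TraitSchema(traits=tuple(traits))


class TestFunctionWeights:
    def test_one_trait_per_category(self):
        s = schema_of(
            Trait("f", "feeding", "quantitative"),
            Trait("h", "habitat", "quantitative"),
            Trait("r", "reproduction", "quantitative"),
            Trait("s", "social_behavior", "quantitative"),
            Trait("b", "biology", "quantitative"))
        w = function_weights(s)
        assert np.allclose(w, 0.2)

    def test_two_traits_split_their_fifth(self):
        s = schema_of(
            Trait("f1", "feeding", "quantitative"),
            Trait("f2", "feeding", "quantitative"),
            Trait("h", "habitat", "quantitative"),
            Trait("r", "reproduction", "quantitative"),
            Trait("s", "social_behavior", "quantitative"),
            Trait("b", "biology", "quantitative"))
        w = function_weights(s)
        assert w["f1"] == w["f2"] == pytest.approx(0.1)
        assert w.sum() == pytest.approx(1.0)

    def test_default_schema_weights_sum_to_one(self, schema16):
        w = function_weights(schema16)
        assert len(w) == 13
        assert w.sum() == pytest.approx(1.0)

    def test_uncovered_category_rejected(self):
        s = schema_of(Trait("f", "feeding", "quantitative"))
        with pytest.raises(SchemaError):
            function_weights(s)


def five_cat_schema():
    return schema_of(
        Trait("mass", "biology", "quantitative"),
        Trait("diet", "feeding", "qualitative",
              {"fish": 1, "krill": 2, "squid": 0}),
        Trait("h", "habitat", "quantitative"),
        Trait("r", "reproduction", "quantitative"),
        Trait("soc", "social_behavior", "qualitative",
              {"solitary": 2, "gregarious": 0}))


class TestGower:
    def test_identical_rows_distance_zero(self):
        s = five_cat_schema()
        traits = pd.DataFrame(
            {"mass": [1.0, 1.0], "diet": ["fish", "fish"], "h": [2.0, 2.0],
             "r": [3.0, 3.0], "soc": ["solitary", "solitary"]},
            index=["a", "b"])
        d = gower_distance(traits, s)
        assert d.loc["a", "b"] == 0.0

    def test_opposite_extremes_distance_one(self):
        s = five_cat_schema()
        traits = pd.DataFrame(
            {"mass": [0.0, 10.0], "diet": ["fish", "krill"], "h": [0.0, 5.0],
             "r": [0.0, 1.0], "soc": ["solitary", "gregarious"]},
            index=["a", "b"])
        d = gower_distance(traits, s)
        assert d.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_arithmetic_oracle(self):
        """3 species x 2 traits against term-by-term hand computation."""
        s = schema_of(
            Trait("mass", "biology", "quantitative"),
            Trait("diet", "feeding", "qualitative", {"fish": 1, "krill": 2}),
            Trait("h", "habitat", "quantitative"),
            Trait("r", "reproduction", "quantitative"),
            Trait("soc", "social_behavior", "quantitative"))
        traits = pd.DataFrame(
            {"mass": [0.0, 5.0, 10.0], "diet": ["fish", "fish", "krill"],
             "h": [1.0, 1.0, 1.0], "r": [2.0, 2.0, 2.0], "soc": [0.0, 0.0, 0.0]},
            index=list("abc"))
        d = gower_distance(traits, s)
        # weights: each category 0.2; constant traits contribute 0 numerator
        # d(a,b) = 0.2*(5/10) / 1.0 ; d(a,c) = 0.2*1 + 0.2*1 ; d(b,c) = 0.2*0.5+0.2
        assert d.loc["a", "b"] == pytest.approx(0.1)
        assert d.loc["a", "c"] == pytest.approx(0.4)
        assert d.loc["b", "c"] == pytest.approx(0.3)

    def test_pairwise_deletion_for_missing(self):
        s = five_cat_schema()
        traits = pd.DataFrame(
            {"mass": [0.0, 10.0], "diet": [None, "krill"], "h": [0.0, 5.0],
             "r": [0.0, 1.0], "soc": ["solitary", "gregarious"]},
            index=["a", "b"])
        d = gower_distance(traits, s)
        assert d.loc["a", "b"] == pytest.approx(0.8 / 0.8)  # diet dropped

    def test_no_shared_traits_rejected(self):
        s = five_cat_schema()
        traits = pd.DataFrame(
            {"mass": [0.0, None], "diet": [None, "krill"], "h": [1.0, None],
             "r": [1.0, None], "soc": [None, "gregarious"]},
            index=["a", "b"])
        with pytest.raises(FunctionalSpaceError, match="share no"):
            gower_distance(traits, s)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_bounds_symmetry_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        s = five_cat_schema()
        traits = pd.DataFrame({
            "mass": rng.normal(size=n) * 10,
            "diet": rng.choice(["fish", "krill", "squid"], n),
            "h": rng.random(n),
            "r": rng.random(n),
            "soc": rng.choice(["solitary", "gregarious"], n),
        }, index=[f"s{i}" for i in range(n)])
        d = gower_distance(traits, s).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


def euclid(X):
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


class TestPCoA:
    def test_collinear_points_one_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])[:, None]
        D = pd.DataFrame(euclid(x), index=list("abcde"), columns=list("abcde"))
        space = pcoa(D, n_axes=1)
        got = euclid(space.coordinates.to_numpy())
        assert np.allclose(got, D.to_numpy(), atol=1e-8)
        assert space.quality_msd == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_reconstruction_4d(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        D = pd.DataFrame(euclid(X))
        space = pcoa(D, n_axes=4)
        assert np.allclose(euclid(space.coordinates.to_numpy()), D, atol=1e-8)
        assert np.all(np.diff(space.eigenvalues) <= 1e-9)  # decreasing
        assert np.allclose(space.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_permutation_equivariance_up_to_sign(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        names = [f"s{i}" for i in range(8)]
        D = pd.DataFrame(euclid(X), index=names, columns=names)
        perm = list(rng.permutation(names))
        a = pcoa(D, 2).coordinates
        b = pcoa(D.loc[perm, perm], 2).coordinates.loc[names]
        for col in a.columns:
            assert (np.allclose(a[col], b[col], atol=1e-8)
                    or np.allclose(a[col], -b[col], atol=1e-8))

    def test_cross_check_against_skbio(self, schema16, small_study):
        """Independent oracle: scikit-bio's PCoA on the same Gower matrix."""
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix
        D = gower_distance(small_study.traits, schema16)
        ours = pcoa(D, n_axes=4)
        theirs = skbio_pcoa(DistanceMatrix(D.to_numpy(), ids=list(D.index)),
                            number_of_dimensions=4)
        ref = theirs.samples.to_numpy()[:, :4]
        got = ours.coordinates.to_numpy()
        for k in range(4):
            assert (np.allclose(got[:, k], ref[:, k], atol=1e-6)
                    or np.allclose(got[:, k], -ref[:, k], atol=1e-6))

    def test_too_few_positive_eigenvalues(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])[:, None]
        D = pd.DataFrame(euclid(x))
        with pytest.raises(FunctionalSpaceError, match="positive eigenvalues"):
            pcoa(D, n_axes=4)


class TestQuality:
    def test_information_loss_positive_msd(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        D = pd.DataFrame(euclid(X))
        assert pcoa(D, n_axes=1).quality_msd > 0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 3))
        D = pd.DataFrame(euclid(X))
        space = pcoa(D, n_axes=2)
        got = space_quality_msd(D, space)
        Y = space.coordinates.to_numpy()
        E = euclid(Y)
        E = E * (D.to_numpy().max() / E.max())
        acc, cnt = 0.0, 0
        for i in range(7):
            for j in range(i + 1, 7):
                acc += (D.iloc[i, j] - E[i, j]) ** 2
                cnt += 1
        assert got == pytest.approx(acc / cnt)


class TestFRic:
    def unit_square_space(self, extra=None):
        pts = {"a": (0, 0), "b": (0, 1), "c": (1, 0), "d": (1, 1)}
        if extra:
            pts.update(extra)
        names = list(pts)
        coords = pd.DataFrame([pts[n] for n in names], index=names,
                              columns=["axis1", "axis2"]).astype(float)
        D = pd.DataFrame(euclid(coords.to_numpy()), index=names, columns=names)
        return FunctionalSpace(coordinates=coords,
                               eigenvalues=np.array([1.0, 1.0]),
                               quality_msd=0.0, distances=D)

    def test_unit_square_area(self):
        space = self.unit_square_space()
        assert fric(space).volume == pytest.approx(1.0)

    def test_interior_point_changes_nothing(self):
        space = self.unit_square_space(extra={"mid": (0.5, 0.5)})
        full = fric(space)
        no_mid = fric(space, ["a", "b", "c", "d"])
        assert full.volume == pytest.approx(no_mid.volume) == pytest.approx(1.0)
        assert no_mid.fraction_of_pool == pytest.approx(1.0)

    def test_degenerate_subsets_flagged_zero(self):
        space = self.unit_square_space()
        small = fric(space, ["a", "b"])
        assert small.volume == 0.0 and small.degenerate
        flat = fric(space, ["a", "b"])  # collinear pair in 2-D
        assert flat.volume == 0.0

    def test_monte_carlo_inclusion_oracle_4d(self):
        """Hull volume of 20 random 4-D points vs rejection sampling."""
        rng = np.random.default_rng(12)
        pts = rng.random((20, 4))
        vol, degen = hull_volume(pts)
        assert not degen
        from scipy.spatial import ConvexHull
        eqs = ConvexHull(pts).equations
        lo, hi = pts.min(0), pts.max(0)
        box = np.prod(hi - lo)
        n = 1_000_000
        samples = rng.random((n, 4)) * (hi - lo) + lo
        inside = (samples @ eqs[:, :4].T + eqs[:, 4] <= 1e-12).all(axis=1)
        mc = box * inside.mean()
        assert vol == pytest.approx(mc, rel=0.02)


class TestOriginality:
    def test_duplicate_pair_zero(self):
        D = pd.DataFrame([[0, 0, 0.5], [0, 0, 0.5], [0.5, 0.5, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        orig = functional_originality(D)
        assert orig["a"] == orig["b"] == 0.0

    def test_equilateral_configuration(self):
        c = 0.37
        D = pd.DataFrame(np.full((4, 4), c) - np.eye(4) * c)
        assert (functional_originality(D) == c).all()

    def test_matches_double_loop_oracle(self, schema16, small_study):
        D = gower_distance(small_study.traits, schema16)
        got = functional_originality(D)
        for i, sp in enumerate(D.index):
            expect = min(D.iloc[i, j] for j in range(len(D)) if j != i)
            assert got[sp] == pytest.approx(expect)

    def test_far_species_do_not_change_it(self):
        D = np.array([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]])
        base = functional_originality(pd.DataFrame(D[:2, :2]))
        full = functional_originality(pd.DataFrame(D))
        assert full.iloc[0] == base.iloc[0]


class TestGowerPCoAEstimator:
    def test_fit_attributes(self, schema16, small_study):
        m = GowerPCoA(schema16, n_axes=4).fit(small_study.traits)
        assert m.space_.coordinates.shape == (15, 4)
        assert m.quality_msd_ >= 0
        assert (m.originality_ > 0).any()
        coords = m.transform(small_study.traits)
        assert coords.equals(m.space_.coordinates)
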