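"""Compositional statistics: CLR/Aitchison, PCoA, ANOSIM, Pearson."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from markerbench.compost import (
    DistanceMatrix, aitchison_distance, aitchison_matrix, anosim, clr,
    pcoa, pearson,
)


class TestPearson:
    def test_identical_vectors(self):
        assert pearson([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == pytest.approx(1.0)

    def test_three_point_value_against_direct_formula(self):
        a = np.array([0.2, 0.3, 0.5])
        b = np.array([0.5, 0.3, 0.2])
        da, db = a - a.mean(), b - b.mean()
        oracle = float((da @ db) / np.sqrt((da @ da) * (db @ db)))
        assert oracle == pytest.approx(-13 / 14)
        assert pearson(a, b) == pytest.approx(oracle)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([0.5, 0.5, 0.5], [0.2, 0.3, 0.5])


class TestClr:
    def test_uniform_maps_to_zero(self):
        assert np.allclose(clr(np.ones(5) / 5), 0.0)

    def test_half_quarter_quarter(self):
        got = clr(np.array([0.5, 0.25, 0.25]))
        # oracle: direct log / geometric-mean arithmetic
        x = np.array([0.5, 0.25, 0.25])
        oracle = np.log(x) - np.log(x).mean()
        assert np.allclose(got, oracle)
        assert got[0] == pytest.approx(0.4621, abs=1e-4)
        assert got[1] == pytest.approx(-0.2310, abs=1e-4)

    def test_components_sum_to_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.dirichlet(np.ones(int(rng.integers(3, 30))))
            assert abs(clr(x).sum()) < 1e-9

    def test_zero_replacement_policy(self):
        x = np.array([0.6, 0.4, 0.0])
        out = clr(x)
        # delta = half the smallest nonzero part, then renormalize
        repl = np.array([0.6, 0.4, 0.2])
        repl = repl / repl.sum()
        assert np.allclose(out, np.log(repl) - np.log(repl).mean())

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            clr(np.zeros(3))

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_clr_sum_zero_and_scale_invariance(self, parts):
        x = np.array(parts)
        assert abs(clr(x / x.sum()).sum()) < 1e-9
        assert aitchison_distance(x, 7.5 * x) < 1e-9


class TestAitchison:
    def test_identity_and_symmetry(self):
        a = np.array([0.2, 0.3, 0.5])
        b = np.array([0.1, 0.6, 0.3])
        assert aitchison_distance(a, a) == 0.0
        assert aitchison_distance(a, b) == pytest.approx(
            aitchison_distance(b, a))

    def test_scale_invariance(self):
        counts = np.array([10.0, 30.0, 60.0])
        props = np.array([0.1, 0.3, 0.6])
        assert aitchison_distance(counts, props) < 1e-12

    def test_against_bruteforce_clr_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.dirichlet(np.ones(6))
            b = rng.dirichlet(np.ones(6))
            la, lb = np.log(a), np.log(b)
            oracle = np.sqrt((((la - la.mean()) - (lb - lb.mean())) ** 2
                              ).sum())
            assert aitchison_distance(a, b) == pytest.approx(oracle,
                                                             abs=1e-12)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x, y, z = (rng.dirichlet(np.ones(5)) for _ in range(3))
            dxy = aitchison_distance(x, y)
            dyz = aitchison_distance(y, z)
            dxz = aitchison_distance(x, z)
            assert dxz <= dxy + dyz + 1e-12

    def test_matches_skbio_clr(self):
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(3)
        x = rng.dirichlet(np.ones(8))
        assert np.allclose(clr(x), skbio_clr(x))


class TestPcoa:
    def test_collinear_points(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                                     dtype=float))
        coords, eig = pcoa(dm)
        assert eig[1] == pytest.approx(0.0, abs=1e-9)
        axis = coords.iloc[:, 0].to_numpy()
        spacing = np.abs(np.diff(np.sort(axis)))
        assert np.allclose(spacing, 1.0, atol=1e-8)

    def test_distance_reconstruction(self):
        rng = np.random.default_rng(4)
        profiles = [rng.dirichlet(np.ones(10)) for _ in range(7)]
        dm = aitchison_matrix(profiles, [f"p{i}" for i in range(7)])
        coords, eig = pcoa(dm)
        assert eig.min() > -1e-9
        X = coords.to_numpy()
        recon = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        assert np.allclose(recon, dm.matrix, atol=1e-8)

    def test_duplicated_point_coincides(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(6))
        q = rng.dirichlet(np.ones(6))
        dm = aitchison_matrix([p, q, p], ["a", "b", "a2"])
        coords, _ = pcoa(dm)
        assert np.allclose(coords.loc["a"], coords.loc["a2"], atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]],
                                                dtype=float))


def _exhaustive_anosim_p(dm, grouping):
    """Oracle: exact permutation distribution over all label orderings."""
    n = len(grouping)
    condensed = dm.matrix[np.triu_indices(n, k=1)]
    ranks_full = sps.rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    denom = (n * (n - 1) / 2) / 2

    def r_of(labels):
        labels = np.asarray(labels)
        within = labels[iu] == labels[ju]
        return (ranks_full[~within].mean() - ranks_full[within].mean()) / denom

    observed = r_of(grouping)
    rs = [r_of(perm) for perm in itertools.permutations(grouping)]
    return observed, np.mean([r >= observed - 1e-12 for r in rs])


class TestAnosim:
    def test_well_separated_clusters(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.01, (8, 2)),
                         rng.normal(5, 0.01, (8, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"x{i}" for i in range(16)], d)
        labels = ["a"] * 8 + ["b"] * 8
        R, p = anosim(dm, labels, n_permutations=999, seed=0)
        assert R == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """n=6 toy: permutation p from full enumeration vs Monte Carlo."""
        rng = np.random.default_rng(7)
        d = rng.random((6, 6))
        d = np.triu(d, 1)
        d = d + d.T
        dm = DistanceMatrix([f"x{i}" for i in range(6)], d)
        labels = ["a", "a", "a", "b", "b", "b"]
        obs_oracle, p_oracle = _exhaustive_anosim_p(dm, labels)
        R, p_mc = anosim(dm, labels, n_permutations=9999, seed=1)
        assert R == pytest.approx(obs_oracle)
        # Monte-Carlo p converges to the exhaustive value (add-one bias ~1e-4)
        assert p_mc == pytest.approx(p_oracle, abs=3 * np.sqrt(
            p_oracle * (1 - p_oracle) / 9999) + 2e-3)

    def test_matches_skbio_r_statistic(self):
        import skbio

        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1, (10, 3))
        pts[5:] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"x{i}" for i in range(10)], d)
        labels = ["a"] * 5 + ["b"] * 5
        R, _ = anosim(dm, labels, n_permutations=99, seed=0)
        sk = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d, ids=dm.labels), grouping=labels,
            permutations=0)
        assert R == pytest.approx(float(sk["test statistic"]))

    def test_null_p_values_roughly_uniform(self):
        """Shuffled labels on structureless data: p ~ Uniform(0,1]."""
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(100):
            d = rng.random((8, 8))
            d = np.triu(d, 1)
            d = d + d.T
            dm = DistanceMatrix([f"x{i}" for i in range(8)], d)
            labels = list(rng.permutation(["a"] * 4 + ["b"] * 4))
            ps.append(anosim(dm, labels, n_permutations=99, seed=rng)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_r_bounds_and_group_validation(self):
        dm = DistanceMatrix(["a", "b", "c", "d"],
                            np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError):
            anosim(dm, ["x", "x", "x", "y"], 99, 0)
        R, p = anosim(dm, ["x", "x", "y", "y"], 99, 0)
        assert -1 <= R <= 1
        assert 0 < p <= 1
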