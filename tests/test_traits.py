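import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import rmtnet
from rmtnet.tables import StandardizedTable, TraitTable
from rmtnet.traits import (
    connectivity_distance_matrix,
    gs_distance_matrix,
    gs_topology_correlation,
    mantel_test,
    module_trait_correlations,
    otu_significance,
    partial_mantel_test,
)


def make_std(rows):
    rows = np.asarray(rows, dtype=float)
    rows = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, keepdims=True)
    return StandardizedTable(
        otu_ids=[f"o{i}" for i in range(rows.shape[0])],
        sample_ids=[f"s{j}" for j in range(rows.shape[1])],
        values=rows,
        row_means=np.zeros(rows.shape[0]),
        row_sds=np.ones(rows.shape[0]),
    )


def make_traits(cols, names=None, sample_ids=None):
    cols = np.asarray(cols, dtype=float)
    names = names or [f"t{j}" for j in range(cols.shape[1])]
    sample_ids = sample_ids or [f"s{j}" for j in range(cols.shape[0])]
    return TraitTable(sample_ids, names, cols)


def random_distance(rng, n):
    return squareform(pdist(rng.standard_normal((n, 3))))


class TestOtuSignificance:
    def test_identities(self):
        x = np.array([1.0, 4.0, 2.0, 6.0, 3.0, 5.0])
        orth = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        orth -= orth @ (x - x.mean()) / np.sum((x - x.mean()) ** 2) * (x - x.mean())
        std = make_std([x])
        traits = make_traits(np.column_stack([x, orth]))
        gs = otu_significance(std, traits)
        assert gs.values[0, 0] == pytest.approx(1.0)
        assert gs.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_squaring_of_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(40)
        noise = rng.standard_normal(40)
        t = x + noise * np.sqrt(3)  # target correlation 0.5
        gs = otu_significance(make_std([x]), make_traits(t[:, None]))
        r = np.corrcoef((x - x.mean()) / x.std(), (t - t.mean()) / t.std())[0, 1]
        assert gs.values[0, 0] == pytest.approx(r**2, abs=1e-12)

    def test_invariant_to_affine_trait_rescaling(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((3, 12))
        t = rng.standard_normal(12)
        std = make_std(x)
        gs1 = otu_significance(std, make_traits(t[:, None]))
        gs2 = otu_significance(std, make_traits((5.0 * t - 7.0)[:, None]))
        assert np.allclose(gs1.values, gs2.values, atol=1e-12)

    def test_constant_trait_flagged(self):
        std = make_std(np.random.default_rng(0).standard_normal((2, 8)))
        with pytest.warns(UserWarning):
            gs = otu_significance(std, make_traits(np.ones((8, 1)), names=["flat"]))
        assert np.isnan(gs.values).all()


class TestGsTopologyCorrelation:
    def test_affine_relation(self):
        k = np.array([1.0, 2, 3, 4, 5])
        r, p = gs_topology_correlation(2 * k + 1, k)
        assert r == pytest.approx(1.0)
        r, _ = gs_topology_correlation(-3 * k + 2, k)
        assert r == pytest.approx(-1.0)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            r, p = gs_topology_correlation(
                rng.standard_normal(100), rng.standard_normal(100)
            )
            ps.append(p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMantel:
    def test_identical_matrices(self):
        d = random_distance(np.random.default_rng(1), 10)
        res = mantel_test(d, d, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 200.0)

    def test_linear_reversal(self):
        d = random_distance(np.random.default_rng(2), 8)
        rev = d.max() + 1.0 - d
        np.fill_diagonal(rev, 0.0)
        res = mantel_test(d, rev, n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_statistic_is_lower_triangle_pearson(self):
        rng = np.random.default_rng(3)
        dx, dy = random_distance(rng, 9), random_distance(rng, 9)
        res = mantel_test(dx, dy, n_perm=9, seed=0)
        iu = np.triu_indices(9, 1)
        assert res.r == pytest.approx(np.corrcoef(dx[iu], dy[iu])[0, 1], abs=1e-12)

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(6)
        dx, dy = random_distance(rng, 12), random_distance(rng, 12)
        res = mantel_test(dx, dy, n_perm=999, seed=1)
        r_ref, p_ref, _ = skbio_mantel(dx, dy, permutations=999, alternative="greater")
        assert res.r == pytest.approx(float(r_ref), abs=1e-10)
        assert abs(res.p - float(p_ref)) < 0.06  # permutation noise only

    def test_p_value_floor(self):
        d = random_distance(np.random.default_rng(4), 7)
        res = mantel_test(d, d, n_perm=49, seed=0)
        assert res.p >= 1.0 / 50.0

    def test_constant_matrix_flagged(self):
        res = mantel_test(np.zeros((5, 5)), random_distance(np.random.default_rng(0), 5))
        assert res.flag == "constant distance matrix"
        assert np.isnan(res.r)


class TestPartialMantel:
    def test_uncorrelated_control_changes_little(self):
        rng = np.random.default_rng(11)
        dx, dy, dz = (random_distance(rng, 12) for _ in range(3))
        plain = mantel_test(dx, dy, n_perm=99, seed=0)
        partial = partial_mantel_test(dx, dy, dz, n_perm=99, seed=0)
        assert abs(partial.r - plain.r) < 0.25

    def test_perfect_control_removes_signal(self):
        rng = np.random.default_rng(12)
        dx = random_distance(rng, 10)
        dy = random_distance(rng, 10)
        res = partial_mantel_test(dx, dy, dy, n_perm=99, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-9)

    def test_fully_degenerate_flagged(self):
        d = random_distance(np.random.default_rng(13), 8)
        res = partial_mantel_test(d, d, d, n_perm=49, seed=0)
        assert res.flag == "zero residual variance"
        assert res.r == 0.0


class TestDistanceMatrices:
    def test_connectivity_distance_is_absolute_difference(self):
        k = np.array([1.0, 3.0, 6.0])
        d = connectivity_distance_matrix(k)
        assert d[0, 1] == 2.0 and d[0, 2] == 5.0 and d[1, 2] == 3.0

    def test_gs_distance_is_euclidean_over_traits(self):
        gs = rmtnet.GSMatrix(["a", "b"], ["t1", "t2"], np.array([[0.0, 0.0], [3.0, 4.0]]))
        d = gs_distance_matrix(gs)
        assert d[0, 1] == pytest.approx(5.0)


class TestModuleTraitGrid:
    def test_exact_and_negated_trait(self):
        rng = np.random.default_rng(5)
        e = rng.standard_normal(14)
        eig = pd.DataFrame([e, -e], index=[1, 2], columns=[f"s{j}" for j in range(14)])
        traits = make_traits(e[:, None], names=["env"], sample_ids=list(eig.columns))
        r, p = module_trait_correlations(eig, traits)
        assert r.loc[1, "env"] == pytest.approx(1.0)
        assert r.loc[2, "env"] == pytest.approx(-1.0)
        assert p.loc[1, "env"] < 1e-6

    def test_null_pair_not_spuriously_tight(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            e = rng.standard_normal(14)
            t = rng.standard_normal(14)
            eig = pd.DataFrame([e], index=[1], columns=[f"s{j}" for j in range(14)])
            traits = make_traits(t[:, None], names=["env"], sample_ids=list(eig.columns))
            r, p = module_trait_correlations(eig, traits)
            hits += (abs(r.loc[1, "env"]) < 0.99) and (p.loc[1, "env"] > 0.001)
        assert hits >= 95
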