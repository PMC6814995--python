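"""Co-expression network core: scaling, adjacency, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import nmomics as nm
from nmomics.network import GREY, _first_pc, detect_modules


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap, straight from the definition."""
    n = a.shape[0]
    out = np.eye(n)
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            den = min(k[i], k[j]) + 1 - a[i, j]
            out[i, j] = (l_ij + a[i, j]) / den if den > 0 else 1.0
    return out


def random_network(rng, n=15) -> nm.CoexpressionNetwork:
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    idx = pd.Index([f"A{i}" for i in range(n)])
    return nm.CoexpressionNetwork(beta=6, adjacency=pd.DataFrame(a, index=idx, columns=idx))


class TestScaleToIntRange:
    def _scaled(self, values, **kw):
        frame = pd.DataFrame({"s1": values})
        frame.index = [f"A{i}" for i in range(len(values))]
        return nm.scale_to_int_range({"layer": frame}, **kw)

    @pytest.mark.parametrize(
        "values, expected",
        [([-2.0, 0.0, 2.0], [0, 50, 100]), ([-2.0, -1.0, 2.0], [0, 25, 100])],
    )
    def test_linear_endpoint_mapping(self, values, expected):
        out = self._scaled(values)
        np.testing.assert_array_equal(out.values.to_numpy().ravel(), expected)

    def test_constant_layer_maps_to_midpoint(self):
        out = self._scaled([3.0, 3.0, 3.0])
        np.testing.assert_array_equal(out.values.to_numpy(), 50.0)

    def test_layers_scaled_independently(self):
        a = pd.DataFrame({"s1": [-4.0], "s2": [4.0]}, index=["P1"])
        b = pd.DataFrame({"s1": [-1.0], "s2": [1.0]}, index=["M1"])
        out = nm.scale_to_int_range({"prot": a, "met": b})
        assert out.values.loc["P1"].tolist() == [0.0, 100.0]
        assert out.values.loc["M1"].tolist() == [0.0, 100.0]
        assert out.layer_of.tolist() == ["prot", "met"]

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nm.scale_to_int_range({"layer": pd.DataFrame()})

    def test_output_is_integer_in_range(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(40, 8)), index=[f"A{i}" for i in range(40)])
        out = nm.scale_to_int_range({"x": frame}).values.to_numpy()
        assert np.array_equal(out, np.round(out))
        assert out.min() == 0 and out.max() == 100


class TestAdjacency:
    def _frame(self, rows):
        return pd.DataFrame(np.asarray(rows, float), index=[f"A{i}" for i in range(len(rows))])

    def test_affine_copies_fully_connected_any_beta(self):
        x = self._frame([[1, 2, 3, 4], [7, 9, 11, 13]])
        for beta in (1, 6, 18):
            net = nm.adjacency(x, beta=beta)
            assert net.adjacency.iloc[0, 1] == pytest.approx(1.0)

    def test_uncorrelated_profiles_give_zero(self):
        x = self._frame([[1, -1, 1, -1], [1, 1, -1, -1]])
        net = nm.adjacency(x, beta=18)
        assert net.adjacency.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_soft_power_evaluation(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=200)
        # construct a pair with sample correlation exactly 0.9
        other = 0.9 * (base - base.mean()) / base.std()
        z = rng.normal(size=200)
        z = z - z.mean()
        z -= (z @ base - z.mean() * base.sum()) / ((base - base.mean()) @ base) * (base - base.mean())
        other += np.sqrt(1 - 0.81) * z / z.std()
        x = self._frame([base, other])
        net = nm.adjacency(x, beta=18)
        assert net.adjacency.iloc[0, 1] == pytest.approx(0.9**18, rel=1e-6)

    def test_signed_network_formula(self):
        x = self._frame([[1, 2, 3, 4], [4, 3, 2, 1]])
        net = nm.adjacency(x, beta=2, network_type="signed")
        # cor = -1 -> ((1-1)/2)^2 = 0
        assert net.adjacency.iloc[0, 1] == pytest.approx(0.0)

    def test_unsigned_invariant_under_negation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 10))
        a1 = nm.adjacency(self._frame(x), beta=6).adjacency.to_numpy()
        x2 = x.copy()
        x2[0] = -3 * x2[0] + 1
        a2 = nm.adjacency(self._frame(x2), beta=6).adjacency.to_numpy()
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            nm.adjacency(self._frame([[1, 2], [2, 1]]))


class TestScaleFreeFit:
    def test_power_law_network_beats_random(self):
        # rank-one adjacency with Pareto weights has power-law connectivity;
        # a uniform-random network of the same size does not
        rng = np.random.default_rng(0)
        n = 200
        w = rng.pareto(1.5, n) + 0.05
        w = np.clip(w / w.max(), 0.01, 1.0)
        a = np.outer(w, w)
        np.fill_diagonal(a, 1.0)
        idx = pd.Index([f"A{i}" for i in range(n)])
        scale_free = nm.CoexpressionNetwork(
            beta=6, adjacency=pd.DataFrame(a, index=idx, columns=idx)
        )
        r2_sf, slope = nm.scale_free_fit(scale_free)
        r2_rand, _ = nm.scale_free_fit(random_network(rng, n))
        assert r2_sf > 0.8
        assert slope < 0
        assert r2_sf > r2_rand + 0.3

    def test_single_analyte_rejected(self):
        net = nm.CoexpressionNetwork(
            beta=6, adjacency=pd.DataFrame([[1.0]], index=["A0"], columns=["A0"])
        )
        with pytest.raises(ValueError):
            nm.scale_free_fit(net)

    def test_constant_connectivity_undefined(self):
        idx = pd.Index(["A0", "A1"])
        net = nm.CoexpressionNetwork(
            beta=6, adjacency=pd.DataFrame(np.eye(2), index=idx, columns=idx)
        )
        r2, slope = nm.scale_free_fit(net)
        assert np.isnan(r2)


class TestTOM:
    def test_isolated_nodes_have_zero_overlap(self):
        idx = pd.Index(["A0", "A1", "A2"])
        net = nm.CoexpressionNetwork(
            beta=6, adjacency=pd.DataFrame(np.eye(3), index=idx, columns=idx)
        )
        tom = nm.tom_similarity(net).tom.to_numpy()
        assert np.array_equal(tom, np.eye(3))

    def test_three_node_hand_computation(self):
        idx = pd.Index(["A0", "A1", "A2"])
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        net = nm.CoexpressionNetwork(beta=6, adjacency=pd.DataFrame(a, index=idx, columns=idx))
        tom = nm.tom_similarity(net).tom
        # l_12 = 0.25; (0.25 + 0.5) / (min(1,1) + 1 - 0.5) = 0.5
        assert tom.iloc[0, 1] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            net = random_network(rng, 15)
            t = nm.tom_similarity(net).tom.to_numpy()
            np.testing.assert_allclose(t, tom_oracle(net.adjacency.to_numpy()), atol=1e-12)

    def test_tom_bounded_and_symmetric(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            net = random_network(rng, rng.integers(5, 25))
            t = nm.tom_similarity(net).tom.to_numpy()
            assert (t >= 0).all() and (t <= 1).all()
            np.testing.assert_allclose(t, t.T)


class TestDetectModules:
    def _fit(self, ds, min_module_size=25, **kw):
        from conftest import fold_changes_from_dataset

        fcs = fold_changes_from_dataset(ds)
        scaled = nm.scale_to_int_range({k: f.log2fc for k, f in fcs.items()})
        net = nm.tom_similarity(nm.adjacency(scaled))
        return scaled, detect_modules(scaled, net, min_module_size=min_module_size, **kw)

    def test_zero_noise_recovers_planted_partition(self, zero_noise_dataset):
        _, part = self._fit(zero_noise_dataset)
        truth = zero_noise_dataset.truth.module_of.reindex(part.module_of.index)
        assert adjusted_rand_score(truth, part.module_of) == pytest.approx(1.0)
        assert len(part.modules) == 3

    def test_min_size_above_all_modules_gives_all_grey(self, zero_noise_dataset):
        _, part = self._fit(zero_noise_dataset, min_module_size=31)
        assert (part.module_of == GREY).all()

    def test_highly_correlated_modules_merge(self):
        # two planted blocks driven by eigengenes with correlation ~0.97
        rng = np.random.default_rng(0)
        e1 = rng.standard_normal(12)
        z = rng.standard_normal(12)
        e1s = (e1 - e1.mean()) / e1.std()
        z = z - z.mean()
        z -= (z @ e1s) / (e1s @ e1s) * e1s
        e2 = 0.97 * e1s + np.sqrt(1 - 0.97**2) * z / z.std()
        x = np.vstack([np.outer(rng.uniform(0.7, 1.0, 30), e1s), np.outer(rng.uniform(0.7, 1.0, 30), e2)])
        frame = pd.DataFrame(x, index=[f"A{i}" for i in range(60)], columns=[f"s{j}" for j in range(12)])
        net = nm.tom_similarity(nm.adjacency(frame))
        part = detect_modules(frame, net, min_module_size=10, merge_cut_height=0.1)
        assert len(part.modules) == 1

    def test_partition_stable_under_permutation(self, small_dataset):
        from conftest import fold_changes_from_dataset

        fcs = fold_changes_from_dataset(small_dataset)
        scaled = nm.scale_to_int_range({k: f.log2fc for k, f in fcs.items()})
        net = nm.tom_similarity(nm.adjacency(scaled))
        part1 = detect_modules(scaled.values, net)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(scaled.values))
        shuffled = scaled.values.iloc[perm]
        net2 = nm.tom_similarity(nm.adjacency(shuffled))
        part2 = detect_modules(shuffled, net2)
        aligned = part2.module_of.reindex(part1.module_of.index)
        assert adjusted_rand_score(part1.module_of, aligned) == pytest.approx(1.0)

    def test_non_grey_modules_respect_min_size(self, fitted_results):
        sizes = fitted_results.module_sizes.drop(GREY, errors="ignore")
        assert (sizes >= fitted_results.partition.min_module_size).all()


class TestModuleEigengenes:
    def test_identical_profiles_give_variance_one(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        x = pd.DataFrame(
            np.vstack([2 * profile + 1, profile, 3 * profile]),
            index=["A0", "A1", "A2"],
            columns=[f"s{j}" for j in range(6)],
        )
        part = nm.ModulePartition(module_of=pd.Series("blue", index=x.index))
        me = nm.module_eigengenes(x, part)
        assert me.variance_explained["blue"] == pytest.approx(1.0)
        r = np.corrcoef(me.values["blue"], profile)[0, 1]
        assert r == pytest.approx(1.0)

    def test_variance_explained_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            block = rng.standard_normal((10, 8))
            scores, ve = _first_pc(block)
            z = (block - block.mean(axis=1, keepdims=True)) / block.std(axis=1, ddof=1, keepdims=True)
            evals = np.linalg.eigvalsh(z @ z.T)
            assert ve == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_sign_convention_follows_mean_profile(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(9)
        x = pd.DataFrame(
            np.outer(rng.uniform(0.8, 1.0, 12), base) + 0.01 * rng.standard_normal((12, 9)),
            index=[f"A{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(9)],
        )
        part = nm.ModulePartition(module_of=pd.Series("blue", index=x.index))
        me = nm.module_eigengenes(x, part)
        z = ((x.T - x.T.mean()) / x.T.std()).T
        assert np.corrcoef(me.values["blue"], z.mean(axis=0))[0, 1] > 0

    def test_eigengene_unit_variance(self, fitted_results):
        sds = fitted_results.eigengenes.values.std(ddof=1)
        np.testing.assert_allclose(sds.to_numpy(), 1.0, atol=1e-9)

    def test_zero_variance_analytes_dropped(self):
        x = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [2.0, 4.0, 6.0, 8.0]],
            index=["A0", "A1", "A2"],
            columns=[f"s{j}" for j in range(4)],
        )
        part = nm.ModulePartition(module_of=pd.Series("blue", index=x.index))
        me = nm.module_eigengenes(x, part)
        assert me.variance_explained["blue"] == pytest.approx(1.0)
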