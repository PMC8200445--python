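"""Adjacency, scale-free fit, TOM, consensus, module detection, merging."""

import itertools

import numpy as np
import pandas as pd
import pytest

from coexmeta.config import PipelineConfig
from coexmeta.network import (AdjacencyMatrix, ModulePartition,
                              calibrate_toms, consensus_tom, detect_modules,
                              merge_modules, module_eigengenes, pick_beta,
                              scale_free_fit, signed_adjacency, tom)

from conftest import make_dataset

CFG = PipelineConfig()


def brute_force_tom(A):
    """O(n^3) literal triple loop over the TOM definition."""
    n = A.shape[0]
    T = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            T[i, j] = (l + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
    return T


def random_adjacency(rng, n):
    M = rng.uniform(0, 1, size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 1.0)
    return M


class TestAdjacency:
    def test_formula_at_extreme_correlations(self):
        # two identical genes -> cor 1 -> Adj 1; anti-correlated -> 0
        X = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 4.0, 6.0, 8.0],
                      [4.0, 3.0, 2.0, 1.0]])
        A = signed_adjacency(X, beta=6).A
        assert A[0, 1] == pytest.approx(1.0)
        assert A[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_value(self):
        # orthogonal patterns: cor 0 -> (1/2)^beta
        X = np.array([[1.0, -1.0, 1.0, -1.0],
                      [1.0, 1.0, -1.0, -1.0]])
        A = signed_adjacency(X, beta=6).A
        assert A[0, 1] == pytest.approx(0.5 ** 6)

    def test_zero_variance_gene_named(self):
        X = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="zero-variance gene GFLAT"):
            signed_adjacency(X, 6, genes=["GOK", "GFLAT"])

    def test_symmetric_unit_interval_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(rng.integers(5, 30), 10))
            A = signed_adjacency(X, int(rng.integers(1, 12))).A
            assert np.allclose(A, A.T)
            assert A.min() >= 0 and A.max() <= 1


class TestScaleFreeFit:
    def test_constructed_power_law_fits_high(self):
        rng = np.random.default_rng(1)
        # connectivity profile drawn from a discrete power law
        k = (rng.pareto(2.0, size=2000) + 1) * 2
        # build a star-free surrogate: diagonal-dominant adjacency whose
        # row sums reproduce k is enough, scale_free_fit only reads k
        n = k.size
        A = np.zeros((n, n))
        # distribute each node's connectivity over two fixed neighbours
        for i in range(n):
            A[i, (i + 1) % n] = k[i] / 2
            A[(i + 1) % n, i] = k[i] / 2
            A[i, (i + 2) % n] = k[i] / 2
            A[(i + 2) % n, i] = k[i] / 2
        r2, slope = scale_free_fit(AdjacencyMatrix(
            np.clip(A / A.max(), 0, 1), beta=1))
        assert r2 >= 0.9
        assert slope < 0

    def test_identical_connectivities_give_zero(self):
        A = np.full((50, 50), 0.3)
        np.fill_diagonal(A, 1.0)
        r2, slope = scale_free_fit(AdjacencyMatrix(A, beta=1))
        assert r2 == 0.0

    def test_r_squared_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            A = random_adjacency(rng, 40)
            r2, _ = scale_free_fit(AdjacencyMatrix(A, beta=1))
            assert 0.0 <= r2 <= 1.0


class TestPickBeta:
    def test_matches_exhaustive_scan_oracle(self, small_group):
        datasets, _ = small_group
        X = datasets[0].X
        beta, scan = pick_beta(X, CFG)
        # independent scan re-deriving the rule from the primitives
        fits = []
        for b in range(1, CFG.beta_max + 1):
            r2, slope = scale_free_fit(signed_adjacency(X, b))
            fits.append((b, r2, slope))
        qualifying = [b for b, r2, s in fits
                      if r2 >= CFG.scale_free_r2_min and s < 0]
        expected = qualifying[0] if qualifying else \
            max(fits, key=lambda t: t[1])[0]
        assert beta == expected

    def test_pure_noise_falls_back_to_argmax_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(150, 12))
        beta, scan = pick_beta(X, CFG)
        if scan.attrs["warning"]:
            assert beta == int(scan.loc[scan["r_squared"].idxmax(), "beta"])
        else:  # unlikely on pure noise, but then the rule must hold
            ok = scan[(scan["r_squared"] >= 0.8) & (scan["slope"] < 0)]
            assert beta == int(ok["beta"].iloc[0])


class TestTOM:
    def test_two_gene_network_equals_adjacency(self):
        for a in (0.2, 0.7, 1.0):
            A = np.array([[1.0, a], [a, 1.0]])
            T = tom(AdjacencyMatrix(A, 1))
            assert T[0, 1] == pytest.approx(a)

    def test_complete_graph_is_all_ones(self):
        A = np.ones((6, 6))
        np.testing.assert_allclose(tom(AdjacencyMatrix(A, 1)), 1.0)

    def test_matches_brute_force_on_random_10_gene_networks(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            A = random_adjacency(rng, 10)
            np.testing.assert_allclose(tom(AdjacencyMatrix(A, 1)),
                                       brute_force_tom(A), atol=1e-10)

    def test_entries_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            T = tom(AdjacencyMatrix(random_adjacency(rng, 15), 1))
            assert np.allclose(T, T.T)
            assert T.min() >= 0 and T.max() <= 1


class TestCalibration:
    def test_identical_toms_unchanged(self):
        rng = np.random.default_rng(6)
        T = tom(AdjacencyMatrix(random_adjacency(rng, 12), 1))
        calibrated, factors = calibrate_toms([T, T.copy()], 0.95)
        np.testing.assert_allclose(calibrated[0], T)
        np.testing.assert_allclose(calibrated[1], T)

    def test_scaled_pair_calibrates_to_common_matrix(self):
        rng = np.random.default_rng(7)
        T1 = 0.3 * tom(AdjacencyMatrix(random_adjacency(rng, 12), 1))
        T2 = 2.0 * T1
        calibrated, _ = calibrate_toms([T1, T2], 0.95)
        np.testing.assert_allclose(calibrated[0], calibrated[1], atol=1e-12)

    def test_all_toms_share_quantile_after_calibration(self):
        rng = np.random.default_rng(8)
        toms = [tom(AdjacencyMatrix(random_adjacency(rng, 15), 1)) * s
                for s in (0.2, 0.35, 0.15)]
        calibrated, _ = calibrate_toms(toms, 0.95)
        off = ~np.eye(15, dtype=bool)
        qs = [np.quantile(T[off], 0.95) for T in calibrated]
        assert max(qs) - min(qs) < 1e-12


class TestConsensus:
    def test_identical_inputs_pass_through(self):
        rng = np.random.default_rng(9)
        T = tom(AdjacencyMatrix(random_adjacency(rng, 10), 1))
        ctom, dis = consensus_tom([T, T])
        np.testing.assert_allclose(ctom, T)
        assert np.allclose(np.diag(dis), 0)

    def test_zero_input_dominates(self):
        T = np.random.default_rng(10).uniform(size=(8, 8))
        ctom, _ = consensus_tom([T, np.zeros_like(T)])
        np.testing.assert_allclose(ctom, 0.0)

    def test_elementwise_minimum_oracle_and_bound(self):
        rng = np.random.default_rng(11)
        toms = [rng.uniform(size=(12, 12)) for _ in range(3)]
        ctom, _ = consensus_tom(toms)
        for i in range(12):
            for j in range(12):
                assert ctom[i, j] == min(t[i, j] for t in toms)
        for T in toms:
            assert (ctom <= T + 1e-15).all()


class TestDetectModules:
    def block_distance(self, sizes, within, between):
        n = sum(sizes)
        D = np.full((n, n), between)
        start = 0
        for s in sizes:
            D[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(D, 0.0)
        return D

    def test_two_forced_blocks(self):
        D = self.block_distance([60, 60], 0.05, 0.95)
        part = detect_modules(D, CFG)
        sizes = part.sizes()
        assert sorted(sizes.tolist()) == [60, 60]

    def test_sub_threshold_block_stays_unassigned(self):
        rng = np.random.default_rng(12)
        n_noise = 160
        D = np.full((40 + n_noise, 40 + n_noise), 0.0)
        noise = rng.uniform(0.85, 1.0, size=(n_noise, n_noise))
        D[40:, 40:] = (noise + noise.T) / 2
        D[:40, :40] = 0.05
        D[:40, 40:] = 0.95
        D[40:, :40] = 0.95
        np.fill_diagonal(D, 0.0)
        part = detect_modules(D, CFG)  # min size 50 > 40
        assert (part.labels.iloc[:40] == "M0").all()

    def test_labels_ordered_by_size(self):
        D = self.block_distance([80, 60, 100], 0.05, 0.95)
        part = detect_modules(D, CFG)
        assert (part.labels.value_counts()[["M1", "M2", "M3"]]
                .tolist() == [100, 80, 60])


class TestEigengenes:
    def test_copies_of_one_vector(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        X = np.vstack([2 * v + 1, 0.5 * v - 2, v])
        ds = make_dataset(X, genes=["a", "b", "c"])
        part = ModulePartition(pd.Series(["M1"] * 3, index=["a", "b", "c"]))
        eg = module_eigengenes(part, [ds])
        scores = eg.scores["D1"]["M1"].to_numpy()
        vz = (v - v.mean()) / v.std()
        cor = np.corrcoef(scores, vz)[0, 1]
        assert cor == pytest.approx(1.0)
        assert eg.variance_explained[("M1", "D1")] == pytest.approx(1.0)

    def test_sign_convention_with_mixed_orientations(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        X = np.vstack([v, v, -v + 10])  # majority positive
        ds = make_dataset(X, genes=["a", "b", "c"])
        part = ModulePartition(pd.Series(["M1"] * 3, index=["a", "b", "c"]))
        eg = module_eigengenes(part, [ds])
        scores = eg.scores["D1"]["M1"].to_numpy()
        mean_profile = ((X - X.mean(1, keepdims=True)) /
                        X.std(1, keepdims=True)).mean(0)
        assert np.dot(scores, mean_profile) > 0

    def test_variance_explained_bounds(self, small_group):
        datasets, truth = small_group
        part = ModulePartition(truth.module_assignment)
        eg = module_eigengenes(part, datasets)
        for val in eg.variance_explained.values():
            assert 0 < val <= 1


class TestMergeModules:
    def _shared_factor_group(self, rho_distinct, sizes=("A", "B", "C")):
        """Three pseudo-modules driven by one common subject factor."""
        rng = np.random.default_rng(13)
        n_samples = 24
        common = rng.normal(size=n_samples)
        genes, rows, labels = [], [], []
        for m, mod in enumerate(sizes):
            distinct = rng.normal(size=n_samples)
            for g in range(6):
                rows.append(common + rho_distinct * distinct +
                            0.1 * rng.normal(size=n_samples))
                genes.append(f"{mod}{g}")
                labels.append(f"M{m + 1}")
        ds = make_dataset(np.array(rows), genes=genes)
        part = ModulePartition(pd.Series(labels, index=genes))
        return ds, part

    def test_identical_eigengenes_merge(self):
        ds, part = self._shared_factor_group(rho_distinct=0.05)
        eg = module_eigengenes(part, [ds])
        merged, _ = merge_modules(part, eg, [ds], CFG)
        assert len(merged.modules) == 1

    def test_uncorrelated_in_one_dataset_blocks_merge(self):
        # same genes, two datasets; eigengenes correlate in ds1 but the
        # second dataset scrambles module M2, so the minimum rule blocks
        ds1, part = self._shared_factor_group(rho_distinct=0.05,
                                              sizes=("A", "B"))
        rng = np.random.default_rng(14)
        X2 = ds1.X.copy()
        X2[6:12] = rng.normal(size=(6, X2.shape[1]))  # M2 genes scrambled
        ds2 = make_dataset(X2, dataset_id="D2", genes=ds1.genes)
        eg = module_eigengenes(part, [ds1, ds2])
        merged, _ = merge_modules(part, eg, [ds1, ds2], CFG)
        assert len(merged.modules) == 2

    def test_chain_merge_is_order_independent(self):
        ds, part = self._shared_factor_group(rho_distinct=0.3)
        eg = module_eigengenes(part, [ds])
        merged, _ = merge_modules(part, eg, [ds], CFG)
        # exhaustive oracle: try every merge order; all must converge to
        # the same final label structure (partition of gene sets)
        def eig_cor(p):
            e = module_eigengenes(p, [ds])
            out = {}
            for a, b in itertools.combinations(p.modules, 2):
                va = e.scores["D1"][a]
                vb = e.scores["D1"][b]
                out[(a, b)] = float(np.corrcoef(va, vb)[0, 1])
            return out

        def final_partitions(p):
            cors = eig_cor(p)
            qualifying = [k for k, v in cors.items()
                          if v > CFG.merge_cor_min]
            if not qualifying:
                return {frozenset(frozenset(p.genes_of(m))
                                  for m in p.modules)}
            results = set()
            for a, b in qualifying:
                nxt = ModulePartition(p.labels.replace({b: a}))
                results |= final_partitions(nxt)
            return results

        oracle = final_partitions(part)
        assert len(oracle) == 1
        got = frozenset(frozenset(merged.genes_of(m))
                        for m in merged.modules)
        assert got in oracle
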