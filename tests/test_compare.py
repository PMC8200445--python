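"""Module label matching, RRHO, and cross-condition gene classes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexmeta.compare import (GENE_CLASSES, classify_genes, match_labels,
                              rank_scores, rrho)
from coexmeta.config import PipelineConfig
from coexmeta.network import ModulePartition

CFG = PipelineConfig()


def partition_from_blocks(blocks, universe):
    labels = pd.Series("M0", index=universe, dtype=object)
    for name, genes in blocks.items():
        labels.loc[genes] = name
    return ModulePartition(labels)


def meta_table(q_values, mean_lfc, directions=None, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(q_values))]
    tab = pd.DataFrame({"q": q_values, "mean_logFC": mean_lfc},
                       index=pd.Index(genes, name="gene_id"))
    if directions is None:
        directions = ["none"] * len(genes)
    tab["direction"] = directions
    return tab


class TestMatchLabels:
    def test_identical_partitions_map_identically(self):
        universe = [f"g{i}" for i in range(200)]
        part = partition_from_blocks(
            {"M1": universe[:60], "M2": universe[60:120]}, universe)
        match = match_labels(part, part)
        assert match.relabel_map == {"M1": "M1", "M2": "M2"}
        assert match.unmatched_source == []

    def test_disjoint_source_module_gets_fresh_label(self):
        universe = [f"g{i}" for i in range(300)]
        ref = partition_from_blocks({"M1": universe[:60]}, universe)
        src = partition_from_blocks({"M1": universe[100:160]}, universe)
        match = match_labels(ref, src)
        assert match.unmatched_source == ["M1"]
        assert match.relabel_map["M1"] != "M1"

    def test_different_universes_rejected(self):
        a = partition_from_blocks({}, ["g1", "g2"])
        b = partition_from_blocks({}, ["g1", "g3"])
        with pytest.raises(ValueError, match="universes"):
            match_labels(a, b)

    def test_constructed_overlap_matches_assignment_oracle(self):
        """Greedy ascending-p assignment agrees with the brute-force best
        assignment on a small 3x3 overlap with one ambiguous cell."""
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(400)]
        pool = iter(universe)
        ref_blocks, src_blocks = {}, {}
        shared = {}
        # M1/M2 share most genes with S1/S2; S3 overlaps both M2 and M3
        for name, size in (("M1", 60), ("M2", 60), ("M3", 50)):
            ref_blocks[name] = [next(pool) for _ in range(size)]
        src_blocks["S1"] = ref_blocks["M1"][:50]
        src_blocks["S2"] = ref_blocks["M2"][:40] + ref_blocks["M3"][:10]
        src_blocks["S3"] = ref_blocks["M2"][40:55] + ref_blocks["M3"][10:40]
        ref = partition_from_blocks(ref_blocks, universe)
        src = partition_from_blocks(src_blocks, universe)
        match = match_labels(ref, src)
        # oracle: evaluate every one-to-one assignment by total -log p of
        # significant cells, maximizing coverage then significance
        pv = match.p_values
        best, best_score = None, None
        for perm in itertools.permutations(pv.index, len(pv.columns)):
            score = sum(-np.log(pv.loc[r, s])
                        for r, s in zip(perm, pv.columns)
                        if match.q_values.loc[r, s] < 0.05)
            if best_score is None or score > best_score:
                best, best_score = perm, score
        expected = {s: r for r, s in zip(best, pv.columns)
                    if match.q_values.loc[r, s] < 0.05}
        for s, r in expected.items():
            assert match.relabel_map[s] == r


class TestRRHO:
    def test_hand_computed_hypergeometric_cell(self):
        # N=10, both top-3 lists identical -> p = 1/C(10,3)
        q = [1e-6, 1e-5, 1e-4, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        lfc = [1.0] * 3 + [0.01] * 7
        a = meta_table(q, lfc)
        b = meta_table(q, lfc)
        small = CFG.replace(rrho_step_fraction=0.1)  # step 1
        res = rrho(a, b, small)
        grid = res.grids["up-up"]
        expected = -np.log10(1 / 120)
        assert grid.loc[3, 3] == pytest.approx(expected, rel=1e-9)
        assert grid.loc[3, 3] == pytest.approx(2.079, abs=1e-3)

    def test_identity_tables_peak_on_diagonal_quadrants(self):
        rng = np.random.default_rng(2)
        n = 200
        q = rng.uniform(1e-8, 1, size=n)
        lfc = rng.normal(size=n)
        a = meta_table(q, lfc)
        res = rrho(a, a.copy(), CFG)
        up = res.optima["up-up"][2]
        down = res.optima["down-down"][2]
        cross = max(res.optima["up-down"][2], res.optima["down-up"][2])
        assert up > cross and down > cross
        # bonferroni line for the concordant grids
        n_cells = sum(g.size for g in res.grids.values())
        assert cross < -np.log10(0.05 / n_cells) + 1

    def test_grid_equals_direct_hypergeometric(self):
        """Every grid cell equals an independently computed hypergeometric
        tail on explicitly ranked lists."""
        rng = np.random.default_rng(3)
        n = 200
        for _ in range(2):
            a = meta_table(rng.uniform(1e-9, 1, n), rng.normal(size=n))
            b = meta_table(rng.uniform(1e-9, 1, n), rng.normal(size=n))
            res = rrho(a, b, CFG)
            sa, sb = rank_scores(a), rank_scores(b)
            for quadrant, grid in res.grids.items():
                if grid.empty:
                    continue
                da, db = quadrant.split("-")
                la = sa.sort_values(ascending=(da == "down"),
                                    kind="stable")
                lb = sb.sort_values(ascending=(db == "down"),
                                    kind="stable")
                # deterministic tie-break by gene id
                la = sa.rename_axis("g").reset_index().sort_values(
                    ["score", "g"], ascending=[da == "down", True])["g"]
                lb = sb.rename_axis("g").reset_index().sort_values(
                    ["score", "g"], ascending=[db == "down", True])["g"]
                for i in grid.index[:5]:
                    for j in grid.columns[:5]:
                        k = len(set(la[:i]) & set(lb[:j]))
                        expected = -np.log10(max(
                            stats.hypergeom.sf(k - 1, n, i, j), 1e-300))
                        assert grid.loc[i, j] == pytest.approx(
                            expected, rel=1e-9)

    def test_independent_scores_stay_below_bonferroni(self):
        """Null RRHO grids do not cross the Bonferroni-corrected 0.05
        line in at least 9/10 seeds."""
        crossings = 0
        for seed in range(10):
            rng = np.random.default_rng(600 + seed)
            n = 200
            a = meta_table(rng.uniform(size=n), rng.normal(size=n))
            b = meta_table(rng.uniform(size=n), rng.normal(size=n))
            res = rrho(a, b, CFG)
            n_cells = sum(g.size for g in res.grids.values())
            line = -np.log10(0.05 / max(n_cells, 1))
            peak = max(v for _, _, v in res.optima.values())
            crossings += peak >= line
        assert crossings <= 1

    def test_small_universe_rejected(self):
        a = meta_table([0.5] * 5, [1.0] * 5)
        with pytest.raises(ValueError, match="too small"):
            rrho(a, a.copy(), CFG)


def test_planted_class_recovery():
    """Shared, unique and inverted planted genes are labelled with the
    matching RRHO class in >= 70% of cases (multi-seed average)."""
    from coexmeta.gene_meta import gene_meta_table
    from coexmeta.simulate import ComparisonSpec, simulate_comparison
    rates = {"shared": [], "unique_A": [], "inverted": []}
    for seed in range(5):
        spec = ComparisonSpec(n_genes=4000, module_sizes=(), n_pairs=20,
                              n_shared=100, n_unique_a=100, n_unique_b=100,
                              n_inverted=50, effect_size=0.5,
                              seed=700 + seed)
        ds_a, ds_b, truth = simulate_comparison(CFG, spec)
        table_a = gene_meta_table(ds_a, CFG)
        table_b = gene_meta_table(ds_b, CFG)
        classes = classify_genes(table_a, table_b,
                                 rrho(table_a, table_b, CFG))
        cls = truth.effect_class
        rates["shared"].append(classes[cls == "shared"].str.startswith(
            "common-concordant").mean())
        rates["unique_A"].append(classes[cls == "unique_A"].str.startswith(
            "unique-A").mean())
        rates["inverted"].append(classes[cls == "inverted"].str.startswith(
            "common-discordant").mean())
    for key, vals in rates.items():
        assert np.mean(vals) >= 0.7, (key, vals)


class TestClassifyGenes:
    def build_pair(self):
        genes = [f"g{i}" for i in range(20)]
        qa = [1e-4] * 7 + [0.5] * 13
        qb = [1e-4] * 3 + [0.5] * 3 + [1e-4] * 3 + [0.5] * 11
        dir_a = (["up"] * 7 + ["none"] * 13)
        dir_b = (["up"] * 3 + ["none"] * 3 + ["down"] * 3 + ["none"] * 11)
        a = meta_table(qa, [0.5] * 7 + [0.0] * 13, dir_a, genes)
        b = meta_table(qb, [0.5] * 3 + [0.0] * 3 + [-0.5] * 3 + [0.0] * 11,
                       dir_b, genes)
        return a, b, genes

    def test_quoted_definitions(self):
        a, b, genes = self.build_pair()

        class FakeRRHO:
            optimal_sets = {"up-up": {"g0", "g1"}, "down-down": set(),
                            "up-down": {"g6"}, "down-up": set()}

        classes = classify_genes(a, b, FakeRRHO())
        # DE up in both and inside the up-up optimal set
        assert classes["g0"] == "common-concordant-up"
        # DE up in both but outside every optimal set
        assert classes["g2"] == "none"
        # DE-up in A, DE-down in B, inside up-down optimal set
        assert classes["g6"] == "common-discordant-A-up-B-down"
        # DE in A only, not in any optimal set
        assert classes["g3"] == "unique-A-up"
        # DE in A only but inside an optimal set: neither common nor unique
        a2, b2, _ = self.build_pair()

        class FakeRRHO2:
            optimal_sets = {"up-up": {"g3"}, "down-down": set(),
                            "up-down": set(), "down-up": set()}

        classes2 = classify_genes(a2, b2, FakeRRHO2())
        assert classes2["g3"] == "none"

    def test_classes_exclusive_and_exhaustive(self):
        a, b, genes = self.build_pair()

        class FakeRRHO:
            optimal_sets = {"up-up": {"g0"}, "down-down": set(),
                            "up-down": set(), "down-up": set()}

        classes = classify_genes(a, b, FakeRRHO())
        assert set(classes.index) == set(genes)
        assert classes.isin(GENE_CLASSES).all()
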