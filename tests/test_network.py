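from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from eddi.datatypes import CellAnnotation
from eddi.labeling import DependentSet
from eddi.modes import DDPRecord
from eddi.network import (
    build_network,
    enrichment_to_frame,
    linkage_to_newick,
    mode_matrix,
    mode_profile_clustering,
    overrepresentation,
    read_gmt,
    tissue_composition,
)


def _rec(dep, gene, mode="over", seesaw=None, separable=False, r=0.8):
    return DDPRecord(
        dependency_id=dep,
        predictor_id=gene,
        log2_fold_change=2.0 if mode == "over" else -2.0,
        adj_p=0.01,
        mode=mode,
        separable=separable,
        seesaw=seesaw,
        template_r=r,
    )


class TestBuildNetwork:
    def test_shared_predictor_creates_projection_edge(self):
        net = build_network([_rec("D1", "g"), _rec("D2", "g")])
        assert net.ddp_nodes == {"g"}
        assert net.projection["D1"]["D2"]["weight"] == 1

    def test_unshared_predictor_gives_empty_network(self):
        net = build_network([_rec("D1", "g")])
        assert net.ddp_nodes == frozenset()
        assert net.graph.number_of_edges() == 0

    def test_no_labeled_records_rejected(self):
        bare = DDPRecord("D1", "g", 0.0, 1.0, None, False, None, 0.0)
        with pytest.raises(ValueError, match="no labeled"):
            build_network([bare])

    def test_projection_weights_match_bruteforce(self, rng):
        """Projection weights equal direct pairwise set intersections."""
        deps = [f"D{i}" for i in range(5)]
        genes = [f"g{j}" for j in range(12)]
        records, sets = [], {d: set() for d in deps}
        for d in deps:
            for g in rng.choice(genes, size=6, replace=False):
                records.append(_rec(d, str(g)))
                sets[d].add(str(g))
        net = build_network(records)
        shared = {g for g in genes if sum(g in s for s in sets.values()) >= 2}
        for a, b in combinations(deps, 2):
            expected = len(sets[a] & sets[b] & shared)
            got = net.projection[a][b]["weight"] if net.projection.has_edge(a, b) else 0
            assert got == expected

    def test_projection_symmetric_no_self_edges(self, rng):
        records = [_rec(f"D{i}", g) for i in range(3) for g in ("x", "y")]
        net = build_network(records)
        for a, b, d in net.projection.edges(data=True):
            assert a != b
            assert net.projection[b][a]["weight"] == d["weight"]

    def test_exports(self, tmp_path):
        net = build_network([_rec("D1", "g"), _rec("D2", "g")])
        net.write_graphml(tmp_path / "n.graphml")
        net.write_edgelist(tmp_path / "e.csv")
        net.write_projection(tmp_path / "p.csv")
        proj = pd.read_csv(tmp_path / "p.csv")
        assert proj.shared_ddps.tolist() == [1]


def assert_linkage_matches_bruteforce_agglomeration(link, points):
    """Follow the linkage's merges and check each one against a direct
    O(n^3) agglomeration: at every step the merged pair must attain the
    minimal average Hamming distance over all current cluster pairs
    (any minimizer is a valid merge when distances tie), at exactly
    that height."""
    dist = lambda a, b: np.mean(points[a] != points[b])

    def avg_dist(ca, cb):
        return np.mean([dist(a, b) for a in ca for b in cb])

    n = len(points)
    clusters = {i: frozenset([i]) for i in range(n)}
    for step in range(link.shape[0]):
        a, b = int(link[step, 0]), int(link[step, 1])
        height = link[step, 2]
        merged_dist = avg_dist(clusters[a], clusters[b])
        min_dist = min(
            avg_dist(clusters[i], clusters[j])
            for i, j in combinations(sorted(clusters), 2)
        )
        assert merged_dist == pytest.approx(height, abs=1e-12)
        assert merged_dist == pytest.approx(min_dist, abs=1e-12)
        clusters[n + step] = clusters.pop(a) | clusters.pop(b)


class TestModeClustering:
    def test_identical_profiles_merge_first(self):
        records = [
            _rec("D1", "a"), _rec("D1", "b"),
            _rec("D2", "a"), _rec("D2", "b"),
            _rec("D3", "a", mode="under", r=-0.8),
        ]
        result = mode_profile_clustering(records)
        order = list(result.dependency_order)
        assert abs(order.index("D1") - order.index("D2")) == 1

    def test_merge_order_matches_bruteforce(self, rng):
        """Linkage merge order equals direct O(n^3) agglomeration."""
        modes_pool = ["over", "under", "suppressed_under"]
        records = []
        for i in range(5):
            for j in range(6):
                if rng.uniform() < 0.7:
                    m = modes_pool[int(rng.integers(3))]
                    records.append(_rec(f"D{i}", f"g{j}", mode=m, r=0.8 if m == "over" else -0.8))
        mat = mode_matrix(records)
        result = mode_profile_clustering(records)
        assert_linkage_matches_bruteforce_agglomeration(
            result.dependency_linkage, mat.to_numpy()
        )

    def test_single_dependency_trivial_ordering(self):
        result = mode_profile_clustering([_rec("D1", "a"), _rec("D1", "b")])
        assert result.dependency_order == ("D1",)
        assert result.dependency_linkage is None

    def test_newick_export_contains_all_labels(self):
        records = [_rec(f"D{i}", g) for i in range(3) for g in ("x", "y")]
        result = mode_profile_clustering(records)
        tree = result.newick("dependencies")
        assert tree.endswith(";")
        for d in ("D0", "D1", "D2"):
            assert d in tree


class TestTissueComposition:
    ANN = CellAnnotation(
        pd.Series(
            {f"C{i}": ("skin" if i < 8 else "lung") for i in range(12)}
        )
    )

    def test_fractions(self):
        ds = DependentSet("D", frozenset({f"C{i}" for i in range(10)}), ("g",))
        table = tissue_composition([ds], self.ANN)
        skin = table[table.tissue == "skin"].iloc[0]
        assert skin.fraction == pytest.approx(0.8)
        assert skin.penetrance == pytest.approx(1.0)  # all 8 skin lines dependent
        assert table.groupby("dependency_id").fraction.sum().iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_empty_set_gives_no_rows(self):
        assert tissue_composition([DependentSet("D")], self.ANN).empty

    def test_unannotated_cell_raises(self):
        ds = DependentSet("D", frozenset({"UNKNOWN"}), ())
        with pytest.raises(Exception, match="UNKNOWN"):
            tissue_composition([ds], self.ANN)

    def test_fractions_sum_to_one_random(self, rng):
        cells = list(self.ANN.cell_ids)
        sets = [
            DependentSet(f"D{k}", frozenset(rng.choice(cells, size=5, replace=False)))
            for k in range(4)
        ]
        table = tissue_composition(sets, self.ANN)
        sums = table.groupby("dependency_id").fraction.sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


def _hypergeom_tail_bruteforce(k, M, K, N):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, N) + 1):
        total += comb(K, x) * comb(M - K, N - x) / comb(M, N)
    return total


class TestOverrepresentation:
    def test_query_equal_to_set_is_top_hit(self):
        universe = {f"u{i}" for i in range(10)} | {f"g{i}" for i in range(10)}
        gene_sets = {
            "self": {f"g{i}" for i in range(10)},
            "other": {f"u{i}" for i in range(10)},
        }
        results = overrepresentation(gene_sets["self"], gene_sets, universe, min_overlap=5)
        by_name = {r.set_name: r for r in results}
        assert by_name["self"].p == min(r.p for r in results)
        assert by_name["self"].enriched

    def test_p_matches_bruteforce_tail(self):
        # universe 20, set 5, query 5, overlap 3
        universe = [f"x{i}" for i in range(20)]
        gene_set = set(universe[:5])
        query = set(universe[2:7])  # overlap {x2,x3,x4} = 3
        (res,) = overrepresentation(query, {"s": gene_set}, universe, min_overlap=1)
        assert res.overlap == 3
        assert res.p == pytest.approx(_hypergeom_tail_bruteforce(3, 20, 5, 5), rel=1e-10)

    def test_random_instances_match_enumeration(self, rng):
        """Implementation p equals brute-force tail for universes <= 25."""
        for _ in range(20):
            M = int(rng.integers(8, 26))
            universe = [f"x{i}" for i in range(M)]
            K = int(rng.integers(1, M))
            N = int(rng.integers(1, M))
            gene_set = set(rng.choice(universe, size=K, replace=False))
            query = set(rng.choice(universe, size=N, replace=False))
            (res,) = overrepresentation(query, {"s": gene_set}, universe, min_overlap=1)
            expected = _hypergeom_tail_bruteforce(res.overlap, M, K, N)
            assert res.p == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_min_overlap_rule_excludes_regardless_of_p(self):
        universe = [f"x{i}" for i in range(12)]
        gene_set = set(universe[:4])
        (res,) = overrepresentation(set(universe[:4]), {"s": gene_set}, universe, min_overlap=5)
        assert res.overlap == 4 and not res.enriched

    def test_fdr_at_least_p(self, rng):
        universe = [f"x{i}" for i in range(25)]
        gene_sets = {
            f"s{j}": set(rng.choice(universe, size=8, replace=False)) for j in range(6)
        }
        query = set(universe[:10])
        for r in overrepresentation(query, gene_sets, universe):
            assert r.fdr >= r.p - 1e-15

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            overrepresentation({"alien"}, {"s": {"x"}}, {"x"})

    def test_frame_conversion(self):
        universe = [f"x{i}" for i in range(10)]
        results = overrepresentation(set(universe[:5]), {"s": set(universe[:5])}, universe)
        frame = enrichment_to_frame(results)
        assert list(frame.columns[:2]) == ["set_name", "overlap"]


def test_gmt_reader(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "pathway_a\tdesc\tG1\tG2\tG3\n"
        "pathway_b\thttp://x\tG2\tG4\n"
        "\n"
    )
    sets = read_gmt(path)
    assert sets == {"pathway_a": {"G1", "G2", "G3"}, "pathway_b": {"G2", "G4"}}


def test_linkage_to_newick_leaf_count():
    from scipy.cluster import hierarchy

    link = hierarchy.linkage(np.array([[0.0], [1.0], [5.0]]), method="average")
    tree = linkage_to_newick(link, ["a", "b", "c"])
    assert tree.count(",") == 2 and tree.endswith(";")
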