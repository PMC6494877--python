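"""Exact subgraph counting: fast paths, ESU, conversion, orbit statistics."""

import itertools

import numpy as np
import pytest

from motifvar import (
    Motif,
    SampledGraph,
    count_all_k,
    count_motif,
    enumerate_connected_motifs,
    generate_graph,
    orbit_degree_stats,
    parse_motif_spec,
)
from motifvar.counting import (
    conversion_matrix,
    count_triangles,
    count_wedges,
)


def graph(n, edges):
    return SampledGraph(n=n, edges=np.array(sorted(edges), dtype=np.int64))


@pytest.fixture(scope="module")
def small_random_graphs():
    return [generate_graph(14, 2.5, seed=s) for s in range(100)]


def brute_force_induced(g, k):
    adj = g.adjacency_sets()
    cat = enumerate_connected_motifs(k)
    idx = {m.canonical_id: i for i, m in enumerate(cat)}
    vec = np.zeros(len(cat), dtype=np.int64)
    for sub in itertools.combinations(range(g.n), k):
        edges = [
            (a, b)
            for a, b in itertools.combinations(range(k), 2)
            if sub[b] in adj[sub[a]]
        ]
        if len(edges) < k - 1:
            continue
        mo = Motif(k, edges)
        if mo.is_connected():
            vec[idx[mo.canonical_id]] += 1
    return vec


class TestCountMotif:
    def test_complete_graph_combinatorics(self, k4_graph):
        assert count_motif(k4_graph, parse_motif_spec("triangle")) == 4
        assert count_motif(k4_graph, parse_motif_spec("wedge")) == 12

    def test_square_in_diamond(self):
        g = graph(4, [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3)])
        sq = parse_motif_spec("square")
        assert count_motif(g, sq, induced=False) == 1
        assert count_motif(g, sq, induced=True) == 0

    def test_girth_five(self):
        c5 = graph(5, [(i, (i + 1) % 5) for i in range(5)])
        assert count_motif(c5, parse_motif_spec("triangle")) == 0

    def test_motif_larger_than_graph(self):
        g = graph(3, [(0, 1), (1, 2)])
        with pytest.raises(ValueError):
            count_motif(g, parse_motif_spec("k4"))


class TestCountAllK:
    def test_k5_induced_only_k4(self):
        k5 = graph(5, [(a, b) for a in range(5) for b in range(a + 1, 5)])
        tab = count_all_k(k5, 4, induced=True)
        nonzero = {m.m: c for m, c in zip(tab.motifs, tab.induced_vector()) if c}
        assert nonzero == {6: 5}

    def test_star_induced_only_claws(self):
        star = graph(6, [(0, i) for i in range(1, 6)])
        tab = count_all_k(star, 4, induced=True)
        nonzero = {m.m: c for m, c in zip(tab.motifs, tab.induced_vector()) if c}
        assert nonzero == {3: 10}  # choose 3 of 5 leaves

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_against_subset_oracle_on_simulated_graph(self, k):
        g = generate_graph(45, 2.5, seed=17)
        tab = count_all_k(g, k, induced=True)
        assert np.array_equal(tab.induced_vector(), brute_force_induced(g, k))

    def test_fast_paths_agree_with_enumeration(self, small_random_graphs):
        for g in small_random_graphs:
            tab = count_all_k(g, 3, induced=True)
            by_edges = {m.m: c for m, c in zip(tab.motifs, tab.non_induced_vector())}
            assert count_wedges(g) == by_edges[2]
            assert count_triangles(g) == by_edges[3]


class TestConversion:
    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_matrix_roundtrips_count_vectors(self, k):
        g = generate_graph(35, 2.5, seed=23)
        tab = count_all_k(g, k, induced=True)
        M = conversion_matrix(k)
        assert np.array_equal(M @ tab.induced_vector(), tab.non_induced_vector())
        # unimodular: induced counts recoverable from non-induced
        back = np.linalg.solve(M.astype(float), tab.non_induced_vector().astype(float))
        assert np.allclose(back, tab.induced_vector())

    def test_square_conversion_row(self):
        """squares = induced squares + 1 diamond + 3 K4 (per occurrence)."""
        cat = enumerate_connected_motifs(4)
        idx = {m.canonical_id: i for i, m in enumerate(cat)}
        M = conversion_matrix(4)
        row = M[idx[parse_motif_spec("square").canonical_id]]
        assert row[idx[parse_motif_spec("square").canonical_id]] == 1
        assert row[idx[parse_motif_spec("diamond").canonical_id]] == 1
        assert row[idx[parse_motif_spec("k4").canonical_id]] == 3


class TestOrbitDegreeStats:
    def test_star_center_and_leaves(self):
        star = graph(6, [(0, i) for i in range(1, 6)])
        stats = orbit_degree_stats(star)
        claws = [r for r in stats.records if r.graphlet.m == 3]
        assert len(claws) == 2
        by_size = {len(r.orbit_vertices): r for r in claws}
        assert by_size[1].mean_degree == pytest.approx(5.0)  # center orbit
        assert by_size[3].mean_degree == pytest.approx(1.0)  # leaf orbit

    def test_paw_fixture_hand_enumeration(self):
        """Triangle 0-1-2 with pendant path 0-3-4: the subsets {0,1,2,3} (paw)
        and {0,1,3,4}, {0,2,3,4} (paths) are the only connected 4-sets."""
        g = graph(5, [(0, 1), (0, 2), (1, 2), (0, 3), (3, 4)])
        stats = orbit_degree_stats(g)
        by_m = {}
        for r in stats.records:
            by_m.setdefault(r.graphlet.m, []).append(r)
        assert set(by_m) == {3, 4}  # path4 (3 edges) and paw (4 edges)
        assert sum(r.occurrences for r in by_m[4]) == 4  # one paw occurrence
        assert sum(r.occurrences for r in by_m[3]) == 8  # two path occurrences
        # paw orbit degrees: attachment vertex 0 has graph degree 3, the
        # pendant (vertex 3) and the far triangle pair (1, 2) have degree 2
        paw_degs = sorted(
            (len(r.orbit_vertices), r.mean_degree) for r in by_m[4]
        )
        assert paw_degs == [(1, 2.0), (1, 3.0), (2, 2.0)]

    def test_occurrence_identity(self):
        for seed in (1, 2, 3):
            g = generate_graph(30, 2.5, seed=seed)
            stats = orbit_degree_stats(g)
            tab = count_all_k(g, 4, induced=True)
            total_occ = sum(r.occurrences for r in stats.records)
            assert total_occ == 4 * int(tab.induced_vector().sum())
            # per-graphlet identity
            for i, m in enumerate(tab.motifs):
                occ = sum(
                    r.occurrences for r in stats.records if r.graphlet_index == i
                )
                assert occ == 4 * tab.induced_vector()[i]

    def test_small_graph_empty(self):
        g = graph(3, [(0, 1), (1, 2)])
        assert orbit_degree_stats(g).records == ()

    def test_hub_orbits_out_degree_constant_orbits(self):
        """On a simulated scale-free graph the empirical orbit degrees follow
        the typical-variation ordering: cutoff-scale orbits sit above
        constant-degree orbits."""
        from fractions import Fraction as F

        from motifvar import optimize

        g = generate_graph(2000, 2.5, seed=29)
        stats = orbit_degree_stats(g)
        cat = enumerate_connected_motifs(4)
        hub_vals, const_vals = [], []
        for r in stats.records:
            res = optimize(cat[r.graphlet_index], F(5, 2), mode="typical",
                          variant="graphlet")
            if not res.feasible:
                continue
            val, role = res.vertex_roles[r.orbit_vertices[0]]
            if val == "varies":
                continue
            alpha = F(val)
            if alpha >= F(1, 2):
                hub_vals.append(r.mean_log_degree)
            elif alpha == 0:
                const_vals.append(r.mean_log_degree)
        assert hub_vals and const_vals
        assert min(hub_vals) > max(const_vals) - 0.05
        assert np.mean(hub_vals) > np.mean(const_vals)
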