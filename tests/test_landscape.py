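import numpy as np
import pandas as pd
import pytest

from cryptomotu.distances import DistanceMatrix, k2p_matrix
from cryptomotu.errors import CoverageError, GeometryError
from cryptomotu.landscape import (
    EdgeValue,
    delaunay_network,
    edge_values,
    exclude_lineages,
    interpolate_surface,
    intersite_divergence,
    site_haplotype_counts,
)
from cryptomotu.seqio import SiteTable


def site_table(rows):
    df = pd.DataFrame(rows, columns=["site_id", "lat", "lon", "altitude_m", "country"])
    return SiteTable(df.set_index("site_id"))


def toy_matrix():
    d = np.array([[0.0, 0.2], [0.2, 0.0]])
    return DistanceMatrix(["H1", "H2"], d, 1)


class TestDelaunayNetwork:
    def test_triangle_has_three_edges(self):
        sites = site_table(
            [("A", 45, 5, 0, "FR"), ("B", 46, 6, 0, "FR"), ("C", 45, 7, 0, "FR")]
        )
        assert len(delaunay_network(sites)) == 3

    def test_convex_quadrilateral_has_five_edges(self):
        sites = site_table(
            [
                ("A", 45, 5, 0, "FR"),
                ("B", 45, 6, 0, "FR"),
                ("C", 46, 6, 0, "FR"),
                ("D", 46, 5, 0, "FR"),
            ]
        )
        # Euler relation for planar triangulations: E = 3n - 3 - h = 5
        assert len(delaunay_network(sites)) == 5

    def test_edges_unique_and_loop_free(self, sim5):
        edges = delaunay_network(sim5.sites)
        assert all(a != b for a, b in edges)
        assert len(edges) == len({tuple(sorted(e)) for e in edges})

    def test_too_few_or_collinear_sites_rejected(self):
        with pytest.raises(GeometryError):
            delaunay_network(site_table([("A", 45, 5, 0, "FR"), ("B", 46, 6, 0, "FR")]))
        collinear = site_table(
            [("A", 45, 5, 0, "FR"), ("B", 45, 6, 0, "FR"), ("C", 45, 7, 0, "FR")]
        )
        with pytest.raises(GeometryError):
            delaunay_network(collinear)


class TestIntersiteDivergence:
    def test_shared_monomorphic_sites_diverge_zero(self):
        counts = {"A": {"H1": 3}, "B": {"H1": 2}}
        assert intersite_divergence("A", "B", counts, toy_matrix()) == 0.0

    def test_distinct_monomorphic_sites(self):
        counts = {"A": {"H1": 1}, "B": {"H2": 1}}
        assert intersite_divergence("A", "B", counts, toy_matrix()) == pytest.approx(0.2)

    def test_individual_weighting(self):
        # site A: 2x H1; site B: 1x H1 + 1x H2, d(H1,H2)=0.2
        counts = {"A": {"H1": 2}, "B": {"H1": 1, "H2": 1}}
        v = intersite_divergence("A", "B", counts, toy_matrix(), "individual")
        assert v == pytest.approx((2 * 0.0 + 2 * 0.2) / 4)

    def test_haplotype_weighting_ignores_counts(self):
        counts = {"A": {"H1": 100}, "B": {"H1": 1, "H2": 1}}
        v = intersite_divergence("A", "B", counts, toy_matrix(), "haplotype")
        assert v == pytest.approx(0.1)

    def test_empty_site_rejected(self):
        with pytest.raises(CoverageError):
            intersite_divergence("A", "B", {"A": {"H1": 1}}, toy_matrix())

    def test_short_haplotypes_filtered_from_counts(self, sim5):
        full = site_haplotype_counts(sim5.alignment, sim5.haplotypes, min_length=497)
        everything = site_haplotype_counts(sim5.alignment, sim5.haplotypes, min_length=0)
        assert sum(sum(c.values()) for c in full.values()) <= sum(
            sum(c.values()) for c in everything.values()
        )


class TestInterpolateSurface:
    def grid_edges(self, values):
        pts = [(5.0, 45.0), (6.0, 45.0), (5.5, 46.0)]
        return [
            EdgeValue(f"a{i}", f"b{i}", pt, v)
            for i, (pt, v) in enumerate(zip(pts, values))
        ]

    def test_constant_field_is_constant(self):
        surf = interpolate_surface(self.grid_edges([0.1, 0.1, 0.1]), (25, 25))
        assert np.allclose(surf.values[~surf.mask], 0.1)

    def test_cell_at_midpoint_takes_exact_value(self):
        edges = self.grid_edges([0.05, 0.25, 0.10])
        surf = interpolate_surface(edges, (30, 30), pad_frac=0.0)
        # corner cells of the unpadded grid coincide with the first two midpoints
        assert surf.values[0, 0] == pytest.approx(0.05)
        assert surf.values[0, -1] == pytest.approx(0.25)

    def test_values_bounded_by_input_extremes(self, sim5, sim5_matrix):
        counts = site_haplotype_counts(sim5.alignment, sim5.haplotypes, 497)
        net = delaunay_network(sim5.sites)
        evals = edge_values(net, sim5.sites, counts, sim5_matrix)
        surf = interpolate_surface(evals, (40, 40), 2.0, sim5.sites)
        vals = surf.values[~surf.mask]
        inputs = [e.value for e in evals]
        assert vals.min() >= min(inputs) - 1e-12
        assert vals.max() <= max(inputs) + 1e-12

    def test_deterministic_and_edge_order_invariant(self):
        edges = self.grid_edges([0.05, 0.25, 0.10])
        a = interpolate_surface(edges, (20, 20))
        b = interpolate_surface(list(reversed(edges)), (20, 20))
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.mask, b.mask)

    def test_refined_grid_agrees_at_shared_centers(self):
        edges = self.grid_edges([0.05, 0.25, 0.10])
        coarse = interpolate_surface(edges, (11, 11), pad_frac=0.0)
        fine = interpolate_surface(edges, (21, 21), pad_frac=0.0)
        # every coarse center is also a fine center (odd refinement)
        assert coarse.values[3, 4] == pytest.approx(fine.values[6, 8], abs=1e-9)

    def test_no_edges_rejected(self):
        with pytest.raises(GeometryError):
            interpolate_surface([], (10, 10))


class TestExcludeLineages:
    def test_empty_exclusion_is_identity(self, sim5):
        rep = exclude_lineages(sim5.alignment, sim5.true_partition, [], sim5.haplotypes)
        assert len(rep.records) == len(sim5.alignment)
        assert not rep.empty

    def test_exclude_all_gives_empty_result(self, sim5):
        labels = sorted(set(sim5.true_partition.labels.values()))
        rep = exclude_lineages(
            sim5.alignment, sim5.true_partition, labels, sim5.haplotypes
        )
        assert rep.empty and rep.n_sites == 0 and rep.n_haplotypes == 0

    def test_unknown_label_rejected(self, sim5):
        with pytest.raises(CoverageError):
            exclude_lineages(
                sim5.alignment, sim5.true_partition, ["NOPE"], sim5.haplotypes
            )

    def test_remaining_sites_match_truth_table(self, sim5):
        excluded = sorted(set(sim5.true_partition.labels.values()))[:2]
        rep = exclude_lineages(
            sim5.alignment, sim5.true_partition, excluded, sim5.haplotypes
        )
        # oracle from the generator's truth: sites where any remaining
        # lineage was actually sampled
        kept_lineages = set(sim5.true_partition.labels.values()) - set(excluded)
        expected_sites = {
            rec.site_id
            for rec in sim5.alignment
            if sim5.truth.record_lineage[rec.record_id] in kept_lineages
        }
        assert {r.site_id for r in rep.records} == expected_sites
        assert rep.n_sites == len(expected_sites)
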