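import itertools

import numpy as np
import pandas as pd
import pytest

from cryptomotu.diversity_stats import (
    altitudinal_summary,
    concordance_count,
    haversine_km,
    incidence,
    latitudinal_bins,
    nestedness,
    range_classes,
    rare_motu_profile,
    syntopy_rates,
)
from cryptomotu.errors import CoverageError, EmptyInputError
from cryptomotu.partition import Partition
from cryptomotu.seqio import BarcodeAlignment, SequenceRecord, SiteTable


def site_table(rows):
    df = pd.DataFrame(rows, columns=["site_id", "lat", "lon", "altitude_m", "country"])
    return SiteTable(df.set_index("site_id"))


def table_from(counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    return pd.DataFrame(counts).T.fillna(0).astype(int)


class TestIncidence:
    def test_single_cell(self):
        records = [SequenceRecord(f"r{i}", "S1", "ACGT") for i in range(5)]
        p = Partition("CUSTOM", {f"r{i}": "M1" for i in range(5)})
        sites = site_table([("S1", 45.0, 5.0, 100, "FR")])
        t = incidence(records, p, sites)
        assert t.loc["S1", "M1"] == 5

    def test_grand_total_equals_record_count(self, sim5):
        t = incidence(sim5.alignment, sim5.true_partition, sim5.sites, sim5.haplotypes)
        assert int(t.values.sum()) == len(sim5.alignment)

    def test_unknown_site_reported(self):
        records = [SequenceRecord("r1", "S9", "ACGT")]
        p = Partition("CUSTOM", {"r1": "M1"})
        sites = site_table([("S1", 45.0, 5.0, 100, "FR")])
        with pytest.raises(CoverageError, match="r1"):
            incidence(records, p, sites)

    def test_unlabelled_record_reported(self):
        records = [SequenceRecord("r1", "S1", "ACGT")]
        p = Partition("CUSTOM", {"other": "M1"})
        sites = site_table([("S1", 45.0, 5.0, 100, "FR")])
        with pytest.raises(CoverageError, match="r1"):
            incidence(records, p, sites)


class TestSyntopy:
    def test_monomorphic_sites_give_zero(self):
        t = table_from({"S1": {"M1": 4}, "S2": {"M2": 3}})
        res = syntopy_rates(t)
        assert res.pct_multi == 0.0
        assert res.n_eligible == 2

    def test_undersampled_sites_excluded(self):
        t = table_from({"S1": {"M1": 1}, "S2": {"M1": 2, "M2": 2}})
        res = syntopy_rates(t, min_individuals=2)
        assert res.n_eligible == 1
        assert res.pct_multi == 100.0

    def test_three_motu_sites_counted(self):
        t = table_from({"S1": {"M1": 1, "M2": 1, "M3": 1}, "S2": {"M1": 2}})
        assert syntopy_rates(t).n_sites_3plus == 1

    def test_no_eligible_sites_is_an_error(self):
        t = table_from({"S1": {"M1": 1}})
        with pytest.raises(EmptyInputError):
            syntopy_rates(t, min_individuals=5)

    def test_non_increasing_under_nested_coarsening(self, sim12):
        """Coarsening MOTUs can only reduce within-site co-occurrence."""
        fine = sim12.true_partition
        # merge lineage pairs into a strictly coarser nested partition
        coarse_labels = {
            h: f"grp{int(lab[3:]) // 2}" for h, lab in fine.labels.items()
        }
        coarse = Partition("CUSTOM", coarse_labels)
        t_fine = incidence(sim12.alignment, fine, sim12.sites, sim12.haplotypes)
        t_coarse = incidence(sim12.alignment, coarse, sim12.sites, sim12.haplotypes)
        assert syntopy_rates(t_coarse).pct_multi <= syntopy_rates(t_fine).pct_multi


class TestRareMotu:
    def test_uneven_site_counts_toward_both_cutoffs(self):
        t = table_from({"S1": {"M1": 11, "M2": 1}})
        res = rare_motu_profile(t, min_individuals=10)
        assert res[0.2] == 100.0 and res[0.1] == 100.0

    def test_even_site_counts_toward_neither(self):
        t = table_from({"S1": {"M1": 6, "M2": 6}})
        res = rare_motu_profile(t, min_individuals=10)
        assert res[0.2] == 0.0 and res[0.1] == 0.0

    def test_cutoff_monotonicity(self, sim12):
        t = incidence(
            sim12.alignment, sim12.true_partition, sim12.sites, sim12.haplotypes
        )
        res = rare_motu_profile(t)
        assert res[0.2] >= res[0.1]


class TestNestedness:
    def test_identical_partitions(self):
        p = Partition("CUSTOM", {"a": "x", "b": "x", "c": "y"})
        res = nestedness(p, p)
        assert set(res.fine_per_coarse.values()) == {1}
        assert res.violations == []

    def test_singleton_fine_counts_equal_coarse_sizes(self):
        coarse = Partition("CUSTOM", {"a": "x", "b": "x", "c": "y"})
        fine = Partition("CUSTOM", {"a": "a", "b": "b", "c": "c"})
        res = nestedness(fine, coarse)
        assert res.fine_per_coarse == {"x": 2, "y": 1}

    def test_straddling_fine_motu_is_a_violation(self):
        coarse = Partition("CUSTOM", {"a": "x", "b": "y"})
        fine = Partition("CUSTOM", {"a": "f", "b": "f"})
        res = nestedness(fine, coarse)
        assert res.violations == ["f"]

    def test_resl_nested_in_truth_on_generator_data(self, sim12, sim12_matrix):
        from cryptomotu.delimit_resl import resl_delimit

        fine = resl_delimit(sim12.haplotypes, sim12_matrix).partition
        res = nestedness(fine, sim12.true_partition)
        assert res.violations == []
        assert res.max_count >= 1


class TestConcordance:
    def test_identical_partitions_count_all(self):
        p = Partition("CUSTOM", {"a": "x", "b": "x", "c": "y"})
        assert concordance_count([p, p, p]) == 2

    def test_crossed_partitions_count_zero(self):
        p1 = Partition("CUSTOM", {"a": "x", "b": "x", "c": "y", "d": "y"})
        p2 = Partition("CUSTOM", {"a": "x", "b": "y", "c": "x", "d": "y"})
        assert concordance_count([p1, p2]) == 0

    def test_partial_overlap_example(self):
        p1 = Partition("CUSTOM", {"A": "1", "B": "1", "C": "2"})
        p2 = Partition("CUSTOM", {"A": "1", "B": "1", "C": "2"})
        p3 = Partition("CUSTOM", {"A": "1", "B": "2", "C": "3"})
        assert concordance_count([p1, p2, p3]) == 1  # only {C}

    def test_matches_brute_force_and_order_invariant(self):
        rng = np.random.default_rng(8)
        ids = [f"h{i}" for i in range(12)]
        parts = [
            Partition("CUSTOM", {h: f"g{rng.integers(4)}" for h in ids})
            for _ in range(3)
        ]
        expected = len(
            set.intersection(*(set(map(frozenset, p.as_sets())) for p in parts))
        )
        for perm in itertools.permutations(parts):
            assert concordance_count(list(perm)) == expected


class TestGeography:
    def test_haversine_known_values(self):
        assert haversine_km(45.0, 5.0, 45.0, 6.0) == pytest.approx(78.6, abs=0.2)
        assert haversine_km(44.0, 5.0, 52.0, 17.0) > 1000

    def test_range_classes(self):
        sites = site_table(
            [
                ("S1", 45.0, 5.0, 100, "FR"),
                ("S2", 45.0, 6.0, 100, "FR"),
                ("S3", 52.0, 17.0, 100, "PL"),
            ]
        )
        t = table_from(
            {"S1": {"A": 1, "B": 1, "C": 1}, "S2": {"B": 1}, "S3": {"C": 1}}
        )
        rc = range_classes(t, sites)
        assert rc["A"].category == "narrow" and rc["A"].max_km == 0.0
        assert rc["B"].category == "narrow"  # ~78.6 km
        assert rc["C"].category == "widespread"

    def test_missing_coordinates_rejected(self):
        sites = site_table([("S1", 45.0, 5.0, 100, "FR")])
        t = table_from({"S1": {"A": 1}, "S9": {"A": 1}})
        with pytest.raises(CoverageError):
            range_classes(t, sites)

    def test_latitudinal_bins(self):
        sites = site_table(
            [("S1", 45.7, 5.0, 100, "FR"), ("S2", 45.8, 5.1, 100, "FR")]
        )
        t = table_from({"S1": {"A": 1}, "S2": {"A": 2}})
        bins = latitudinal_bins(t, sites)
        assert bins.to_dict() == {45.5: 1}  # one MOTU counts once per band

    def test_altitudinal_summary(self):
        sites = site_table(
            [
                ("S1", 45.0, 5.0, 200, "FR"),
                ("S2", 45.1, 5.1, 400, "FR"),
                ("S3", 45.2, 5.2, 900, "FR"),
            ]
        )
        t = table_from({"S1": {"A": 1}, "S2": {"A": 1}, "S3": {"A": 1}})
        stats, hist = altitudinal_summary(t, sites, min_sites=3)
        row = stats.set_index("motu").loc["A"]
        assert row["alt_min"] == 200 and row["alt_max"] == 900
        assert row["alt_mean"] == pytest.approx(500.0)
        assert hist.loc[200.0] == 1 and hist.sum() == 3

    def test_motus_below_min_sites_have_no_box_stats(self):
        sites = site_table([("S1", 45.0, 5.0, 200, "FR")])
        t = table_from({"S1": {"A": 1}})
        stats, _ = altitudinal_summary(t, sites, min_sites=3)
        assert stats.empty
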