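"""Taxonomy cleanup, genus agglomeration, and the abundance-occurrence core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import soilcore as sc
from soilcore.core import UNCLASSIFIED_PREFIX
from soilcore.exceptions import AnalysisError

from conftest import random_community_table


def make_taxonomy(lineages: dict) -> sc.TaxonomyMap:
    parsed = pd.DataFrame(
        [sc.parse_lineage(s) for s in lineages.values()], index=list(lineages)
    )
    return sc.TaxonomyMap(parsed)


def brute_force_core(table, metadata, threshold_percent, statistic="mean"):
    """Independent oracle: test the three core predicates genus by genus.

    Plain loops over raw counts: (1) mean (or max) per-sample relative
    abundance in the understory group of each site reaches the threshold,
    (2) zero counts in every gap sample anywhere, (3) positive counts in
    every understory sample anywhere.
    """
    counts = table.counts
    rel = counts / counts.sum(axis=0)
    cutoff = threshold_percent / 100.0
    core = set()
    for genus in counts.index:
        if genus.startswith(UNCLASSIFIED_PREFIX):
            continue
        ok = True
        for site in metadata.sites:
            samples = metadata.samples(site=site, microhabitat="understory")
            values = [rel.loc[genus, s] for s in samples]
            stat = sum(values) / len(values) if statistic == "mean" else max(values)
            if not stat >= cutoff:
                ok = False
        for s in metadata.samples(microhabitat="gap"):
            if counts.loc[genus, s] > 0:
                ok = False
        for s in metadata.samples(microhabitat="understory"):
            if not counts.loc[genus, s] > 0:
                ok = False
        if ok:
            core.add(genus)
    return core


class TestCleanTaxa:
    def test_removes_features_without_phylum(self, tiny_table):
        tax = make_taxonomy(
            {
                "GenusA": "k__Bacteria",
                "GenusB": "k__Bacteria; p__Acidobacteriota; c__; o__; f__; g__GenusB",
                "GenusC": "k__Fungi; p__Ascomycota",
            }
        )
        cleaned, removed = sc.clean_taxa(tiny_table, tax)
        assert removed == ["GenusA"]
        assert list(cleaned.feature_ids) == ["GenusB", "GenusC"]

    def test_counts_removed(self, two_site_metadata):
        rng = np.random.default_rng(0)
        table = random_community_table(rng, 10, two_site_metadata.sample_ids)
        lineages = {
            fid: ("k__Bacteria" if i < 3 else f"k__Bacteria; p__P; c__; o__; f__; g__{fid}")
            for i, fid in enumerate(table.feature_ids)
        }
        cleaned, removed = sc.clean_taxa(table, make_taxonomy(lineages))
        assert len(removed) == 3 and cleaned.n_features == 7


class TestAgglomerate:
    def test_sums_shared_genus(self):
        frame = pd.DataFrame(
            {"S1": [1, 3], "S2": [2, 4]}, index=["ASV1", "ASV2"]
        )
        tax = make_taxonomy(
            {
                "ASV1": "k__Bacteria; p__Pseudomonadota; c__; o__; f__; g__Reyranella",
                "ASV2": "k__Bacteria; p__Pseudomonadota; c__; o__; f__; g__Reyranella",
            }
        )
        genus = sc.agglomerate_to_genus(sc.FeatureTable(frame), tax)
        assert genus.counts.loc["Reyranella"].tolist() == [4, 6]

    def test_distinct_genera_unchanged(self, tiny_table):
        tax = make_taxonomy(
            {fid: f"k__Bacteria; p__P; c__; o__; f__; g__{fid}" for fid in tiny_table.feature_ids}
        )
        genus = sc.agglomerate_to_genus(tiny_table, tax)
        assert genus.n_features == tiny_table.n_features

    def test_conserves_per_sample_totals(self, two_site_metadata):
        rng = np.random.default_rng(8)
        table = random_community_table(rng, 30, two_site_metadata.sample_ids)
        genera = [f"g{i % 7}" for i in range(30)]
        tax = make_taxonomy(
            {fid: f"k__Bacteria; p__P; c__; o__; f__; g__{g}"
             for fid, g in zip(table.feature_ids, genera)}
        )
        genus = sc.agglomerate_to_genus(table, tax)
        assert (genus.counts.sum() == table.counts.sum()).all()

    def test_missing_genus_pooled_under_sentinel(self):
        frame = pd.DataFrame({"S1": [2, 5]}, index=["ASV1", "ASV2"])
        tax = make_taxonomy(
            {
                "ASV1": "k__Fungi; p__Basidiomycota; c__; o__; f__Agaricaceae",
                "ASV2": "k__Fungi; p__Basidiomycota; c__; o__; f__Agaricaceae",
            }
        )
        genus = sc.agglomerate_to_genus(sc.FeatureTable(frame), tax)
        label = f"{UNCLASSIFIED_PREFIX}family:Agaricaceae"
        assert genus.counts.loc[label, "S1"] == 7


class TestGroupAbundanceSets:
    def _table(self, values, metadata):
        frame = pd.DataFrame(
            np.tile(values, (len(metadata.sample_ids), 1)).T,
            index=[f"g{i}" for i in range(len(values))],
            columns=metadata.sample_ids,
        )
        return sc.FeatureTable(frame)

    def test_threshold_is_inclusive(self, two_site_metadata):
        # genus at exactly 0.2% relative abundance enters the set
        table = self._table([2, 998], two_site_metadata)
        sets = sc.group_abundance_sets(table, two_site_metadata, 0.2)
        assert all("g0" in s for s in sets.sets.values())

    def test_threshold_zero_includes_any_presence(self, two_site_metadata):
        frame = pd.DataFrame(
            0, index=["g0", "g1"], columns=two_site_metadata.sample_ids
        )
        frame.loc["g1"] = 5
        frame.loc["g0", two_site_metadata.samples(site="SiteA")[0]] = 1
        sets = sc.group_abundance_sets(sc.FeatureTable(frame), two_site_metadata, 0.0)
        in_any = set().union(*sets.sets.values())
        assert in_any == {"g0", "g1"}

    def test_mean_statistic_hand_arithmetic(self):
        # 2 samples with relative abundances 0.004 and 0: mean 0.002 = 0.2% -> in;
        # 0.003 and 0: mean 0.0015 < 0.2% -> out
        meta = sc.SampleMetadata(
            pd.DataFrame(
                {"site": ["A", "A"], "microhabitat": ["understory", "understory"]},
                index=["S1", "S2"],
            )
        )
        frame = pd.DataFrame(
            {"S1": [4, 3, 993], "S2": [0, 0, 1000]}, index=["in", "out", "bulk"]
        )
        sets = sc.group_abundance_sets(sc.FeatureTable(frame), meta, 0.2)
        assert "in" in sets.sets[("A", "understory")]
        assert "out" not in sets.sets[("A", "understory")]

    def test_unclassified_excluded_but_in_denominator(self, two_site_metadata):
        frame = pd.DataFrame(
            {s: [10, 990] for s in two_site_metadata.sample_ids},
            index=["g0", f"{UNCLASSIFIED_PREFIX}unknown"],
        )
        sets = sc.group_abundance_sets(sc.FeatureTable(frame), two_site_metadata, 0.5)
        for members in sets.sets.values():
            assert members == {"g0"}  # 10/1000 = 1% >= 0.5%, denominator includes the pool


class TestOccupancy:
    def test_fractions(self, two_site_metadata):
        frame = pd.DataFrame(0, index=["g0"], columns=two_site_metadata.sample_ids)
        understory = two_site_metadata.samples(microhabitat="understory")
        frame.loc["g0", understory] = 1
        table = sc.FeatureTable(frame)
        # occupancy needs no all-zero guard; raw counts only
        assert sc.occupancy(table, two_site_metadata, "g0", microhabitat="understory") == 1.0
        assert sc.occupancy(table, two_site_metadata, "g0", microhabitat="gap") == 0.0
        frame2 = frame.copy()
        frame2.loc["g0", understory[2:]] = 0
        assert sc.occupancy(
            sc.FeatureTable(frame2), two_site_metadata, "g0", microhabitat="understory"
        ) == pytest.approx(2 / 6)

    def test_unknown_genus_error(self, tiny_table, two_site_metadata):
        with pytest.raises(AnalysisError, match="nope"):
            sc.occupancy(tiny_table, two_site_metadata, "nope")


class TestIdentifyCore:
    def test_recovers_planted_core(self, default_bundle):
        table, taxonomy, metadata, truth = default_bundle
        genus = sc.agglomerate_to_genus(table, taxonomy)
        result = sc.identify_core(genus, metadata, 0.2)
        assert result.core_genera == truth.core_genera

    def test_single_gap_read_disqualifies(self, two_site_metadata):
        frame = pd.DataFrame(1, index=["cand", "bulk"],
                             columns=two_site_metadata.sample_ids)
        frame.loc["bulk"] = 100
        gap = two_site_metadata.samples(microhabitat="gap")
        frame.loc["cand", gap] = 0
        frame.loc["cand", gap[0]] = 1  # one read in one gap sample
        result = sc.identify_core(sc.FeatureTable(frame), two_site_metadata, 0.2)
        assert "cand" not in result.core_genera

    def test_one_missing_understory_sample_disqualifies(self, two_site_metadata):
        frame = pd.DataFrame(1, index=["cand", "bulk"],
                             columns=two_site_metadata.sample_ids)
        frame.loc["bulk"] = 100
        frame.loc["cand", two_site_metadata.samples(microhabitat="gap")] = 0
        frame.loc["cand", two_site_metadata.samples(microhabitat="understory")[0]] = 0
        result = sc.identify_core(sc.FeatureTable(frame), two_site_metadata, 0.2)
        assert "cand" not in result.core_genera

    def test_core_invariants_hold(self, default_bundle):
        table, taxonomy, metadata, truth = default_bundle
        genus = sc.agglomerate_to_genus(table, taxonomy)
        result = sc.identify_core(genus, metadata, 0.2)
        for genus_id in result.core_genera:
            und, gap = result.occupancy[genus_id]
            assert und == 1.0 and gap == 0.0
            for site in metadata.sites:
                assert genus_id in result.exclusive_understory[site]

    def test_matches_brute_force_oracle_on_random_tables(self, two_site_metadata):
        rng = np.random.default_rng(17)
        for trial in range(20):
            table = random_community_table(rng, 20, two_site_metadata.sample_ids)
            for threshold in (0.2, 1.0):
                result = sc.identify_core(table, two_site_metadata, threshold)
                expected = brute_force_core(table, two_site_metadata, threshold)
                assert result.core_genera == expected


class TestThresholdSweep:
    def test_sets_nest_and_counts_decrease(self, default_bundle):
        table, taxonomy, metadata, _ = default_bundle
        genus = sc.agglomerate_to_genus(table, taxonomy)
        sweep = sc.threshold_sweep(genus, metadata)
        for lo, hi in zip(sweep, sweep[1:]):
            assert hi.core_genera <= lo.core_genera
            for group in lo.group_sets.sets:
                assert hi.group_sets.sets[group] <= lo.group_sets.sets[group]

    def test_equals_independent_calls(self, two_site_metadata):
        rng = np.random.default_rng(23)
        table = random_community_table(rng, 50, two_site_metadata.sample_ids)
        sweep = sc.threshold_sweep(table, two_site_metadata)
        for res in sweep:
            single = sc.identify_core(table, two_site_metadata, res.threshold)
            assert res.core_genera == single.core_genera
            assert res.group_sets.sets == single.group_sets.sets

    def test_rejects_bad_grids(self, tiny_table, two_site_metadata):
        with pytest.raises(AnalysisError):
            sc.threshold_sweep(tiny_table, two_site_metadata, thresholds=[0.2, 0.2])
        with pytest.raises(AnalysisError):
            sc.threshold_sweep(tiny_table, two_site_metadata, thresholds=[-1.0])


class TestVennPartition:
    def test_brute_force_example(self):
        part = sc.venn_partition({"A": {"a", "b"}, "B": {"b", "c"}, "C": set(), "D": set()})
        assert part.regions[frozenset({"A"})] == {"a"}
        assert part.regions[frozenset({"A", "B"})] == {"b"}
        assert part.regions[frozenset({"B"})] == {"c"}
        assert sum(len(m) for m in part.regions.values()) == 3

    def test_identical_sets_single_region(self):
        s = {"x", "y"}
        part = sc.venn_partition({k: set(s) for k in "ABCD"})
        assert part.regions[frozenset("ABCD")] == s
        assert all(not m for combo, m in part.regions.items() if combo != frozenset("ABCD"))

    def test_requires_exactly_four_sets(self):
        with pytest.raises(AnalysisError):
            sc.venn_partition({"A": set(), "B": set()})

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.tuples(*[st.sets(st.integers(min_value=0, max_value=15)) for _ in range(4)])
    )
    def test_partition_property(self, sets):
        named = dict(zip("ABCD", sets))
        part = sc.venn_partition(named)
        union = set().union(*sets)
        regions = list(part.regions.values())
        assert set().union(*regions) == union if regions else not union
        assert sum(len(r) for r in regions) == len(union)  # pairwise disjoint
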