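"""The abundance-occurrence core-microbiota framework.

A genus is a *core* member when it clears three predicates:

1. **Abundance** - its group-level relative abundance (default: mean of
   per-sample relative abundances across the group's samples) reaches the
   threshold in the understory group of *both* sites;
2. **Gap exclusion** - it is absent (raw count zero) from every gap
   sample; a single read in a single gap sample disqualifies it, since
   the null model is complete absence from soils not influenced by the
   plant;
3. **Occupancy** - it is present (raw count > 0) in 100% of the
   understory samples pooled over both sites.

Thresholds are swept over a grid (default 0.2, 0.5, 1, 5 percent) to show
how the retained sets shrink, and 4-set Venn partitions summarize sharing
between the site x microhabitat groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .containers import GAP, UNDERSTORY, FeatureTable, SampleMetadata, TaxonomyMap
from .exceptions import AnalysisError

#: Prefix of the pooled label for features without a genus assignment;
#: such pools are never core candidates but still count toward
#: relative-abundance denominators.
UNCLASSIFIED_PREFIX = "unclassified:"

DEFAULT_THRESHOLDS = (0.2, 0.5, 1.0, 5.0)


def clean_taxa(
    table: FeatureTable, taxonomy: TaxonomyMap
) -> tuple[FeatureTable, list[str]]:
    """Drop features that could not be classified at the phylum level."""
    has_phylum = taxonomy.has_rank("phylum").reindex(table.feature_ids, fill_value=False)
    removed = table.feature_ids[~has_phylum].tolist()
    kept = FeatureTable(table.counts.loc[has_phylum].copy(), normalized=table.normalized)
    return kept, removed


def agglomerate_to_genus(table: FeatureTable, taxonomy: TaxonomyMap) -> FeatureTable:
    """Sum counts of features sharing a genus label.

    Features with no genus assignment are pooled under a sentinel label
    ``unclassified:<lowest named rank>`` (e.g. ``unclassified:f__Agaricaceae``
    becomes ``unclassified:family:Agaricaceae``); sentinel pools are
    ineligible for core candidacy. Per-sample totals are conserved exactly.
    """
    labels = []
    for fid in table.feature_ids:
        if fid in taxonomy.feature_ids:
            genus = taxonomy.genus(fid)
            if genus is not None:
                labels.append(genus)
                continue
            lowest = taxonomy.lowest_named_rank(fid)
            if lowest is not None:
                labels.append(f"{UNCLASSIFIED_PREFIX}{lowest[0]}:{lowest[1]}")
                continue
        labels.append(f"{UNCLASSIFIED_PREFIX}unknown")
    grouped = table.counts.groupby(pd.Index(labels, name="genus"), sort=True).sum()
    return FeatureTable(grouped, normalized=table.normalized)


def _eligible_genera(table: FeatureTable) -> pd.Index:
    return table.feature_ids[~table.feature_ids.str.startswith(UNCLASSIFIED_PREFIX)]


def _relative(table: FeatureTable) -> pd.DataFrame:
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise AnalysisError(f"all-zero sample(s): {zero}")
    return table.counts.div(totals, axis=1)


@dataclass
class GroupAbundanceSets:
    """Genera clearing a relative-abundance threshold in each group."""

    threshold: float  # percent
    statistic: str
    sets: dict[tuple[str, str], set[str]]  # (site, microhabitat) -> genus set


def group_abundance_sets(
    genus_table: FeatureTable,
    metadata: SampleMetadata,
    threshold_percent: float,
    statistic: str = "mean",
) -> GroupAbundanceSets:
    """Per (site, microhabitat) group, the genera whose group-level relative
    abundance is ``>= threshold_percent / 100``.

    ``statistic`` chooses the group-level summary of per-sample relative
    abundances: ``mean`` (default) or ``max``. The comparison is inclusive.
    Unclassified sentinel pools contribute to denominators but never enter
    the sets.
    """
    if threshold_percent < 0:
        raise AnalysisError(f"threshold must be >= 0, got {threshold_percent}")
    if statistic not in {"mean", "max"}:
        raise AnalysisError(f"unknown group statistic {statistic!r}")
    rel = _relative(genus_table)
    eligible = _eligible_genera(genus_table)
    cutoff = threshold_percent / 100.0
    sets: dict[tuple[str, str], set[str]] = {}
    for site, habitat in metadata.groups():
        samples = metadata.samples(site=site, microhabitat=habitat)
        if len(samples) == 0:
            raise AnalysisError(f"group ({site}, {habitat}) has no samples")
        sub = rel.loc[eligible, samples]
        summary = sub.mean(axis=1) if statistic == "mean" else sub.max(axis=1)
        if threshold_percent == 0:
            chosen = summary.index[(sub > 0).any(axis=1)]
        else:
            chosen = summary.index[summary >= cutoff]
        sets[(site, habitat)] = set(chosen)
    return GroupAbundanceSets(threshold=threshold_percent, statistic=statistic, sets=sets)


def occupancy(
    genus_table: FeatureTable,
    metadata: SampleMetadata,
    genus: str,
    site: str | None = None,
    microhabitat: str | None = None,
) -> float:
    """Fraction of the selected samples in which ``genus`` has raw count > 0."""
    if genus not in genus_table.feature_ids:
        raise AnalysisError(f"unknown genus {genus!r}")
    samples = metadata.samples(site=site, microhabitat=microhabitat)
    if len(samples) == 0:
        raise AnalysisError("sample selector matches no samples")
    row = genus_table.counts.loc[genus, samples]
    return float((row > 0).sum() / len(samples))


@dataclass
class CoreResult:
    """Outcome of the core-identification pipeline at one threshold."""

    threshold: float  # percent
    statistic: str
    group_sets: GroupAbundanceSets
    exclusive_understory: dict[str, set[str]]  # site -> understory-only genera
    core_genera: set[str]
    occupancy: dict[str, tuple[float, float]]  # genus -> (understory frac, gap frac)
    gap_exclusion: str = "pooled"


def identify_core(
    genus_table: FeatureTable,
    metadata: SampleMetadata,
    threshold_percent: float,
    statistic: str = "mean",
    gap_exclusion: str = "pooled",
) -> CoreResult:
    """Run the full abundance-occurrence pipeline at one threshold.

    With ``gap_exclusion="pooled"`` (default) any raw presence in any gap
    sample at either site disqualifies a genus from both sites' exclusive
    sets; ``"per_site"`` excludes only on that site's own gaps (the
    cross-site core still requires absence from all gaps via the
    occupancy predicate).
    """
    if gap_exclusion not in {"pooled", "per_site"}:
        raise AnalysisError(f"unknown gap_exclusion mode {gap_exclusion!r}")
    sites = metadata.sites
    for site in sites:
        for habitat in (UNDERSTORY, GAP):
            if len(metadata.samples(site=site, microhabitat=habitat)) == 0:
                raise AnalysisError(f"metadata lacks {habitat} samples at site {site!r}")

    groups = group_abundance_sets(genus_table, metadata, threshold_percent, statistic)

    gap_all = metadata.samples(microhabitat=GAP)
    present_any_gap = set(
        genus_table.feature_ids[(genus_table.counts[gap_all] > 0).any(axis=1)]
    )
    exclusive: dict[str, set[str]] = {}
    for site in sites:
        if gap_exclusion == "pooled":
            gap_hits = present_any_gap
        else:
            site_gaps = metadata.samples(site=site, microhabitat=GAP)
            gap_hits = set(
                genus_table.feature_ids[(genus_table.counts[site_gaps] > 0).any(axis=1)]
            )
        exclusive[site] = groups.sets[(site, UNDERSTORY)] - gap_hits

    candidates = set.intersection(*(exclusive[s] for s in sites)) if sites else set()
    occ: dict[str, tuple[float, float]] = {}
    core = set()
    for genus in sorted(candidates):
        und = occupancy(genus_table, metadata, genus, microhabitat=UNDERSTORY)
        gap = occupancy(genus_table, metadata, genus, microhabitat=GAP)
        occ[genus] = (und, gap)
        if und == 1.0 and gap == 0.0:
            core.add(genus)
    return CoreResult(
        threshold=threshold_percent,
        statistic=statistic,
        group_sets=groups,
        exclusive_understory=exclusive,
        core_genera=core,
        occupancy=occ,
        gap_exclusion=gap_exclusion,
    )


def threshold_sweep(
    genus_table: FeatureTable,
    metadata: SampleMetadata,
    thresholds=DEFAULT_THRESHOLDS,
    statistic: str = "mean",
    gap_exclusion: str = "pooled",
) -> list[CoreResult]:
    """``identify_core`` at each threshold of a positive, distinct grid."""
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds):
        raise AnalysisError("thresholds must be positive")
    if len(set(thresholds)) != len(thresholds):
        raise AnalysisError("thresholds must be distinct")
    return [
        identify_core(genus_table, metadata, t, statistic, gap_exclusion)
        for t in thresholds
    ]


def sweep_summary(results: list[CoreResult]) -> pd.DataFrame:
    """Retained-genus counts per group and core size across a sweep."""
    rows = []
    for res in results:
        row = {"threshold_percent": res.threshold, "core_size": len(res.core_genera)}
        for (site, habitat), genera in sorted(res.group_sets.sets.items()):
            row[f"{site}|{habitat}"] = len(genera)
        for site, genera in sorted(res.exclusive_understory.items()):
            row[f"{site}|exclusive_understory"] = len(genera)
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold_percent")


@dataclass
class VennPartition:
    """Disjoint decomposition of 4 named sets into label-combination regions."""

    labels: tuple[str, ...]
    regions: dict[frozenset, set] = field(default_factory=dict)

    @property
    def union(self) -> set:
        out: set = set()
        for region in self.regions.values():
            out |= region
        return out

    def counts(self) -> dict[frozenset, int]:
        return {combo: len(members) for combo, members in self.regions.items()}

    def percentages(self) -> dict[frozenset, float]:
        total = len(self.union)
        if total == 0:
            return {combo: 0.0 for combo in self.regions}
        return {combo: 100.0 * len(m) / total for combo, m in self.regions.items()}


def venn_partition(named_sets: dict[str, set]) -> VennPartition:
    """Partition the union of exactly 4 named sets into the 15 non-empty
    label combinations by direct membership testing."""
    labels = tuple(named_sets)
    if len(labels) != 4:
        raise AnalysisError(f"venn_partition requires exactly 4 sets, got {len(labels)}")
    if len(set(labels)) != 4:
        raise AnalysisError("duplicate set names")
    regions: dict[frozenset, set] = {}
    for r in range(1, 5):
        for combo in itertools.combinations(labels, r):
            regions[frozenset(combo)] = set()
    for element in set().union(*named_sets.values()):
        membership = frozenset(l for l in labels if element in named_sets[l])
        regions[membership].add(element)
    return VennPartition(labels=labels, regions=regions)
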