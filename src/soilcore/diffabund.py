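"""Negative-binomial differential abundance between microhabitats.

A deliberately simple NB Wald test: median-of-ratios size factors,
method-of-moments dispersion pooled across the two groups, a log2 fold
change of pseudo-counted normalized group means, and a delta-method
standard error from the NB variance function ``mu + alpha * mu^2``. The
sign convention is positive = more abundant in the understory. This is a
plain, simulation-validated test; it does not attempt empirical-Bayes
dispersion shrinkage, outlier filtering, or independent filtering.

Significant genera can be tallied against a user-supplied genus-to-
function mapping (e.g. an extract of FAPROTAX for prokaryotes or
FUNGuild for fungi), split by enrichment direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GAP, UNDERSTORY, FeatureTable, SampleMetadata
from .diversity import bh_adjust
from .exceptions import AnalysisError

DISPERSION_FLOOR = 1e-8
PSEUDO_COUNT = 0.5


def size_factors(table: FeatureTable) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    The reference profile is the per-feature geometric mean over features
    positive in every sample; when no such feature exists, a zero-tolerant
    variant takes geometric means over positive counts only and medians
    each sample's ratios over its positive entries.
    """
    if table.n_samples < 2:
        raise AnalysisError("size_factors requires at least 2 samples")
    counts = table.counts.to_numpy(dtype=float)
    empty = table.sample_ids[(counts > 0).sum(axis=0) == 0].tolist()
    if empty:
        raise AnalysisError(f"sample(s) with no positive counts: {empty}")

    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        log_ref = np.log(counts[all_positive]).mean(axis=1)
        ratios = np.log(counts[all_positive]) - log_ref[:, None]
        log_factors = np.median(ratios, axis=0)
    else:
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        log_ref = np.nanmean(logc, axis=1)
        ratios = logc - log_ref[:, None]
        log_factors = np.nanmedian(ratios, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=table.sample_ids, name="size_factor")


def estimate_dispersion(
    table: FeatureTable, factors: pd.Series, groups
) -> pd.Series:
    """Per-genus method-of-moments NB dispersion on normalized counts.

    After removing group means, ``alpha = max(0, (var - mean) / mean^2)``
    with the pooled within-group variance and the grand mean of normalized
    counts; floored at 1e-8.
    """
    groups = pd.Series(groups).reindex(table.sample_ids)
    levels = pd.unique(groups.dropna())
    counts = pd.Series(groups).value_counts()
    if (counts.reindex(levels) < 2).any():
        raise AnalysisError("estimate_dispersion requires >= 2 samples per group")
    norm = table.counts.div(factors.loc[table.sample_ids], axis=1)
    n = norm.shape[1]
    k = len(levels)
    ss = np.zeros(norm.shape[0])
    for g in levels:
        sub = norm.loc[:, groups == g]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1).to_numpy()
    var = ss / max(n - k, 1)
    mean = norm.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mean > 0, (var - mean) / mean**2, 0.0)
    alpha = np.clip(alpha, DISPERSION_FLOOR, None)
    return pd.Series(alpha, index=table.feature_ids, name="dispersion")


@dataclass
class DiffAbundResult:
    """Per-genus Wald test results for one two-group contrast."""

    results: pd.DataFrame  # baseMean, log2FoldChange, lfcSE, stat, pvalue, padj
    contrast: str
    alpha: float
    pseudo_count: float = PSEUDO_COUNT
    dropped: list[str] = field(default_factory=list)  # all-zero in both groups

    @property
    def significant(self) -> set[str]:
        mask = self.results["padj"] < self.alpha
        return set(self.results.index[mask])


def nb_wald(
    table: FeatureTable,
    factors: pd.Series,
    groups,
    dispersion: pd.Series | None = None,
    contrast: str = f"{UNDERSTORY} vs {GAP}",
) -> pd.DataFrame:
    """Per-genus NB Wald test between exactly two groups.

    Group means are taken on the normalized scale with a +0.5 pseudo-count;
    ``log2FC = log2(mean_understory / mean_gap)`` (first group in sorted
    order understory-first when labels are the microhabitats, otherwise
    the lexicographically later label is the reference). The SE comes from
    the delta method applied to the NB variance ``mu + alpha mu^2`` of
    each group mean; p-values are two-sided normal.
    """
    groups = pd.Series(groups).reindex(table.sample_ids)
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise AnalysisError(f"nb_wald requires exactly 2 groups, got {levels}")
    if UNDERSTORY in levels and GAP in levels:
        numerator, denominator = UNDERSTORY, GAP
    else:
        numerator, denominator = levels[0], levels[1]
    n_num = int((groups == numerator).sum())
    n_den = int((groups == denominator).sum())
    if n_num < 2 or n_den < 2:
        raise AnalysisError("nb_wald requires >= 2 samples in each group")

    if dispersion is None:
        dispersion = estimate_dispersion(table, factors, groups)
    norm = table.counts.div(factors.loc[table.sample_ids], axis=1)
    m_num = norm.loc[:, groups == numerator].mean(axis=1) + PSEUDO_COUNT
    m_den = norm.loc[:, groups == denominator].mean(axis=1) + PSEUDO_COUNT
    alpha = dispersion.loc[table.feature_ids]

    log2fc = np.log2(m_num / m_den)
    var_num = (m_num + alpha * m_num**2) / n_num
    var_den = (m_den + alpha * m_den**2) / n_den
    ln2 = np.log(2.0)
    se = np.sqrt(var_num / (m_num**2) + var_den / (m_den**2)) / ln2
    stat = log2fc / se
    pvalue = 2 * scipy.stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FoldChange": log2fc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pvalue,
        },
        index=table.feature_ids,
    )


def diff_abund(
    genus_table: FeatureTable,
    metadata: SampleMetadata,
    site: str | None = None,
    alpha: float = 0.05,
) -> DiffAbundResult:
    """Understory-vs-gap differential abundance, within one site or pooled.

    Pipeline: size factors -> MoM dispersion -> NB Wald -> BH adjustment.
    Genera with zero counts in both groups are dropped (undefined
    contrast) before testing.
    """
    samples = metadata.samples(site=site)
    if len(samples) == 0:
        raise AnalysisError(f"no samples for site {site!r}")
    sub = FeatureTable(genus_table.counts.loc[:, samples].copy(),
                       normalized=genus_table.normalized)
    groups = metadata.frame.loc[samples, "microhabitat"]

    nonzero = (sub.counts > 0).any(axis=1)
    dropped = sub.feature_ids[~nonzero].tolist()
    sub = FeatureTable(sub.counts.loc[nonzero], normalized=sub.normalized)

    factors = size_factors(sub)
    results = nb_wald(sub, factors, groups)
    results["padj"] = bh_adjust(results["pvalue"].to_numpy())
    label = f"{UNDERSTORY} vs {GAP}" + (f" ({site})" if site else " (pooled)")
    return DiffAbundResult(results=results, contrast=label, alpha=alpha, dropped=dropped)


def read_guild_map(path: str | Path) -> dict[str, list[str]]:
    """Read a genus -> functional-category mapping from TSV.

    Two columns (genus, category); a genus may appear on several rows, or
    carry several categories separated by ``|`` in one row. Matching is on
    the exact genus string after case-folding.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    if frame.shape[1] < 2:
        raise AnalysisError(f"{path}: guild map needs (genus, category) columns")
    mapping: dict[str, list[str]] = {}
    for genus, category in frame.iloc[:, :2].itertuples(index=False):
        if pd.isna(genus) or pd.isna(category):
            continue
        key = str(genus).strip().casefold()
        for cat in str(category).split("|"):
            cat = cat.strip()
            if cat and cat not in mapping.setdefault(key, []):
                mapping[key].append(cat)
    return mapping


def function_tally(
    result: DiffAbundResult, guilds: dict[str, list[str]]
) -> pd.DataFrame:
    """Counts of significant genera per functional category, by direction.

    Columns ``understory_enriched`` / ``gap_enriched`` (sign of the log2
    fold change); genera with no mapping are tallied under ``<unmapped>``.
    A genus with several categories contributes to each.
    """
    guilds = {k.casefold(): v for k, v in guilds.items()}
    tallies: dict[str, dict[str, int]] = {}

    def bump(category: str, direction: str) -> None:
        row = tallies.setdefault(category, {"understory_enriched": 0, "gap_enriched": 0})
        row[direction] += 1

    for genus in sorted(result.significant):
        lfc = result.results.at[genus, "log2FoldChange"]
        direction = "understory_enriched" if lfc > 0 else "gap_enriched"
        categories = guilds.get(genus.casefold())
        if not categories:
            bump("<unmapped>", direction)
        else:
            for cat in categories:
                bump(cat, direction)
    frame = pd.DataFrame.from_dict(tallies, orient="index").sort_index()
    if frame.empty:
        frame = pd.DataFrame(columns=["understory_enriched", "gap_enriched"])
    frame.index.name = "category"
    return frame
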