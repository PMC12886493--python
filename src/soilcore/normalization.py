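"""Relative abundance, prevalence filtering, and cumulative sum scaling (CSS).

CSS divides each sample's counts by the cumulative sum of its counts up
to a chosen quantile of the positive counts, then rescales by a global
constant so normalized magnitudes stay near raw-count scale. The quantile
is fixed (default 0.5) rather than chosen adaptively; it is computed over
positive counts only with the lower-interpolation rule, since zeros would
collapse the quantile for sparse samples.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .containers import FeatureTable, NormalizedTable
from .exceptions import AnalysisError


def relative_abundance(table: FeatureTable) -> NormalizedTable:
    """Scale each sample column to sum to 1."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise AnalysisError(f"all-zero sample(s): {zero}")
    rel = table.counts.div(totals, axis=1)
    return NormalizedTable(rel, method="relative")


def prevalence_filter(
    table: FeatureTable, min_fraction: float = 0.10
) -> tuple[FeatureTable, list[str]]:
    """Drop features present in fewer than ``min_fraction`` of samples.

    A feature is retained iff its presence count (samples with count > 0)
    is at least ``ceil(min_fraction * n_samples)``, i.e. the removed set is
    exactly the features whose presence fraction is below the threshold.
    Returns the filtered table and the removed feature ids.
    """
    if not (0 < min_fraction <= 1):
        raise AnalysisError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if table.n_samples == 0 or table.n_features == 0:
        raise AnalysisError("prevalence_filter requires a non-empty table")
    # tiny epsilon guards ceil against float artifacts like 0.1 * 20 = 2.0000000000000004
    needed = math.ceil(min_fraction * table.n_samples - 1e-9)
    presence = (table.counts > 0).sum(axis=1)
    keep = presence >= needed
    removed = table.feature_ids[~keep].tolist()
    filtered = FeatureTable(table.counts.loc[keep].copy(), normalized=table.normalized)
    return filtered, removed


def css_scaling_factors(
    table: FeatureTable, quantile: float = 0.5
) -> tuple[pd.Series, float]:
    """Per-sample CSS scaling factors.

    For sample *j*, ``q_j`` is the given quantile (lower interpolation) of
    the sample's positive counts, and the factor ``s_j`` is the sum of all
    counts ``c_ij <= q_j``.
    """
    if not (0 < quantile < 1):
        raise AnalysisError(f"quantile must be in (0, 1), got {quantile}")
    factors = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy(dtype=float)
        positive = np.sort(col[col > 0])
        if positive.size == 0:
            raise AnalysisError(f"sample {sample!r} has no positive counts")
        q = positive[int(math.floor(quantile * (positive.size - 1)))]
        factors[sample] = float(col[col <= q].sum())
    series = pd.Series(factors, name="css_factor").loc[table.sample_ids]
    return series, quantile


def css_normalize(
    table: FeatureTable,
    quantile: float = 0.5,
    scale_constant: float | None = None,
) -> NormalizedTable:
    """CSS-normalize a count table: ``c'_ij = c_ij / s_j * N``.

    ``N`` defaults to the median of the scaling factors, keeping the
    normalized values near the raw-count scale. Zero cells stay zero.
    """
    factors, q = css_scaling_factors(table, quantile)
    constant = float(np.median(factors)) if scale_constant is None else float(scale_constant)
    if constant <= 0:
        raise AnalysisError(f"scale constant must be positive, got {constant}")
    normalized = table.counts.div(factors, axis=1) * constant
    return NormalizedTable(
        normalized,
        method="css",
        quantile=q,
        scale_factors=factors,
        scale_constant=constant,
    )
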