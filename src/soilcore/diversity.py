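"""Alpha diversity, Bray-Curtis dissimilarity, PCoA, and PERMANOVA.

Alpha diversity is the Chao1 richness estimator, computed on integer
counts (after prevalence filtering, before CSS, since the estimator needs
true singleton/doubleton counts). Beta diversity is Bray-Curtis on the
CSS-normalized table, ordinated by classical scaling (PCoA) and tested
with one-way PERMANOVA on the 4-level site x microhabitat grouping plus
pairwise contrasts with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable
from .exceptions import AnalysisError


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from a single sample's count vector.

    With ``S_obs`` observed taxa, ``F1`` singletons and ``F2`` doubletons:
    bias-corrected ``S_obs + F1(F1-1)/(2(F2+1))``; classic
    ``S_obs + F1^2/(2 F2)``, falling back to the bias-corrected form when
    ``F2 = 0``. Returns ``S_obs`` when there are no singletons.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr % 1 != 0)):
        raise AnalysisError("chao1 requires non-negative integer counts")
    s_obs = float(np.count_nonzero(arr))
    f1 = float(np.count_nonzero(arr == 1))
    f2 = float(np.count_nonzero(arr == 2))
    if f1 == 0:
        return s_obs
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return s_obs + f1 * f1 / (2 * f2)


def chao1_per_sample(table: FeatureTable, bias_corrected: bool = True) -> pd.Series:
    """Chao1 estimate for every sample column of an integer count table."""
    if not table.is_integral():
        raise AnalysisError("chao1 is defined on raw counts, not normalized values")
    values = {s: chao1(table.counts[s], bias_corrected) for s in table.sample_ids}
    return pd.Series(values, name="chao1").loc[table.sample_ids]


@dataclass
class KruskalResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def kruskal_wallis(values, groups) -> KruskalResult:
    """Kruskal-Wallis rank test of a numeric vector across >= 2 groups.

    Tie-corrected H with a chi-square reference on k-1 degrees of freedom.
    A fully tied vector is degenerate (H = 0, p = 1) and flagged as such.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise AnalysisError("kruskal_wallis requires at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise AnalysisError("kruskal_wallis groups must be non-empty")
    if np.all(values == values[0]):
        return KruskalResult(0.0, 1.0, degenerate=True)
    stat, p = scipy.stats.kruskal(*samples)
    return KruskalResult(float(stat), float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise AnalysisError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bray_curtis_matrix(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    ``d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``, bounded in [0, 1].
    """
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise AnalysisError(f"all-zero sample(s): {zero}")
    data = table.counts.to_numpy(dtype=float).T  # samples x features
    condensed = pdist(data, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.sample_ids))


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) ordination of a distance matrix."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues
    negative_eigenvalues: np.ndarray  # the negative part, for reporting


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal-coordinates analysis by classical scaling.

    Double-centers ``-D^2/2``, eigendecomposes, and returns coordinates
    ``eigenvector * sqrt(eigenvalue)`` for positive eigenvalues only.
    Negative eigenvalues (from non-Euclidean dissimilarities) are reported
    and their axes dropped; no Cailliez/Lingoes correction is applied.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if not (1 <= n_axes <= n - 1):
        raise AnalysisError(f"n_axes must be in [1, {n - 1}], got {n_axes}")
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ (d**2) @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = np.abs(eigvals).max() * 1e-12 if eigvals.size else 0.0
    positive = eigvals > tol
    negative = eigvals[eigvals < -tol]
    n_keep = min(n_axes, int(positive.sum()))
    coords = eigvecs[:, :n_keep] * np.sqrt(eigvals[:n_keep])
    pos_sum = eigvals[positive].sum()
    prop = eigvals[:n_keep] / pos_sum if pos_sum > 0 else np.zeros(n_keep)
    frame = pd.DataFrame(
        coords, index=list(dist.ids), columns=[f"PC{i + 1}" for i in range(n_keep)]
    )
    return OrdinationResult(frame, eigvals, prop, negative)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int
    grouping: str
    adjusted_p: float | None = None


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in levels:
        idx = np.flatnonzero(labels == g)
        if idx.size:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    k = len(levels)
    ss_total, ss_within = _permanova_ss(d2, labels, levels)
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    grouping: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The total sum of squares is ``sum(d^2)/N`` over all pairs, the within
    sum the analogous per-group quantity, and
    ``F = (SS_between/(k-1)) / (SS_within/(N-k))``. The p-value counts
    label permutations with ``F >= F_obs`` under the add-one convention
    ``(hits + 1)/(n_permutations + 1)``, so it is never zero.
    """
    labels = np.asarray(pd.Series(groups).reindex(list(dist.ids)).to_numpy()
                        if isinstance(groups, (pd.Series, dict)) else groups)
    if labels.shape[0] != len(dist.ids):
        raise AnalysisError("groups must cover every sample in the distance matrix")
    if pd.isna(labels).any():
        raise AnalysisError("groups contain missing labels for some samples")
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise AnalysisError("permanova requires at least 2 groups")
    counts = pd.Series(labels).value_counts()
    if (counts < 1).any() or labels.shape[0] - len(levels) < 1:
        raise AnalysisError("permanova requires more samples than groups")

    d2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs, r2 = _pseudo_f(d2, labels, levels)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        f_perm, _ = _pseudo_f(d2, perm, levels)
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        grouping=grouping,
    )


def pairwise_permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[PermanovaResult]:
    """One PERMANOVA per unordered group pair, BH-adjusted across pairs.

    Per-pair seeds are spawned deterministically from ``seed`` via
    ``numpy.random.SeedSequence`` in sorted pair order.
    """
    groups = pd.Series(groups)
    groups = groups.reindex(list(dist.ids))
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) < 2:
        raise AnalysisError("pairwise_permanova requires at least 2 groups")
    pairs = list(itertools.combinations(levels, 2))
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    results = []
    for (a, b), child in zip(pairs, children):
        ids = [s for s in dist.ids if groups[s] in (a, b)]
        sub = dist.filter(ids)
        pair_seed = int(child.generate_state(1)[0] % (2**31))
        res = permanova(
            sub,
            groups.loc[ids].to_numpy(),
            n_permutations=n_permutations,
            seed=pair_seed,
            grouping=f"{a} vs {b}",
        )
        results.append(res)
    adjusted = bh_adjust([r.p_value for r in results])
    for res, adj in zip(results, adjusted):
        res.adjusted_p = float(adj)
    return results
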