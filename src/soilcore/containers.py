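"""In-memory containers for the three tabular inputs of the pipeline.

A study bundle consists of a feature-by-sample count table
(:class:`FeatureTable`), a per-feature ranked taxonomy
(:class:`TaxonomyMap`), and per-sample metadata (:class:`SampleMetadata`)
describing the two-site, two-microhabitat (understory vs gap) design.
All three wrap a :class:`pandas.DataFrame` and validate their invariants
on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import TableValidationError

#: Taxonomic ranks carried by a :class:`TaxonomyMap`, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: The two microhabitat levels of the paired sampling design.
MICROHABITATS = ("understory", "gap")

UNDERSTORY = "understory"
GAP = "gap"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = sorted(index[index.duplicated()].unique().tolist())
        raise TableValidationError(f"duplicate {what} ids: {dupes}")


@dataclass
class FeatureTable:
    """A feature-by-sample abundance matrix.

    Parameters
    ----------
    counts
        DataFrame with features on rows and samples on columns. Cells are
        non-negative and never missing; integers for raw count tables,
        reals after normalization.
    normalized
        True once the values are on a normalized (real-valued) scale.
    """

    counts: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise TableValidationError("counts must be a pandas DataFrame")
        _check_unique(self.counts.index, "feature")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise TableValidationError("counts must be numeric")
        if np.isnan(values).any():
            raise TableValidationError("counts contain missing cells")
        if values.size and values.min() < 0:
            bad = self.counts.index[(self.counts < 0).any(axis=1)].tolist()
            raise TableValidationError(f"negative counts in features: {bad}")
        self.counts.index.name = self.counts.index.name or "feature_id"

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.counts.copy(), normalized=self.normalized)

    def is_integral(self) -> bool:
        """True when every cell is a whole number (raw counts)."""
        values = self.counts.to_numpy()
        return bool(np.all(np.equal(np.mod(values, 1), 0)))


@dataclass
class NormalizedTable(FeatureTable):
    """A :class:`FeatureTable` carrying normalization provenance.

    ``method`` is ``"relative"`` or ``"css"``; for CSS the per-sample
    quantile, scaling factors and the global scale constant are recorded.
    """

    method: str = "relative"
    quantile: float | None = None
    scale_factors: pd.Series | None = None
    scale_constant: float | None = None

    def __post_init__(self) -> None:
        self.normalized = True
        super().__post_init__()
        if self.scale_factors is not None and (self.scale_factors <= 0).any():
            raise TableValidationError("scaling factors must be strictly positive")


@dataclass
class TaxonomyMap:
    """Per-feature ranked lineages (domain through genus).

    ``ranks`` is indexed by feature id with one column per entry of
    :data:`RANKS`; missing ranks are ``None``/NaN.
    """

    ranks: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.ranks.index, "feature")
        missing_cols = [r for r in RANKS if r not in self.ranks.columns]
        if missing_cols:
            raise TableValidationError(f"taxonomy missing rank columns: {missing_cols}")
        self.ranks = self.ranks.loc[:, list(RANKS)].astype(object)
        self.ranks = self.ranks.where(pd.notna(self.ranks), None)
        self.ranks.index.name = self.ranks.index.name or "feature_id"

    @property
    def feature_ids(self) -> pd.Index:
        return self.ranks.index

    def genus(self, feature_id: str) -> str | None:
        return self.ranks.at[feature_id, "genus"]

    def has_rank(self, rank: str) -> pd.Series:
        """Boolean mask over features with a named (non-missing) value at ``rank``."""
        return self.ranks[rank].notna()

    def lowest_named_rank(self, feature_id: str) -> tuple[str, str] | None:
        """The most specific assigned (rank, name) pair, or None if unclassified."""
        row = self.ranks.loc[feature_id]
        for rank in reversed(RANKS):
            if row[rank] is not None:
                return rank, row[rank]
        return None


@dataclass
class SampleMetadata:
    """Per-sample study design: site, microhabitat, replicate.

    Microhabitat is the two-level factor {understory, gap} contrasting
    soil beneath the shrub canopy with open soil nearby.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample")
        for col in ("site", "microhabitat"):
            if col not in self.frame.columns:
                raise TableValidationError(f"metadata missing required column {col!r}")
        if "replicate" not in self.frame.columns:
            self.frame = self.frame.assign(replicate=[str(i) for i in range(len(self.frame))])
        bad = sorted(set(self.frame["microhabitat"]) - set(MICROHABITATS))
        if bad:
            raise TableValidationError(
                f"unknown microhabitat value(s) {bad!r}; expected one of {MICROHABITATS}"
            )
        self.frame.index.name = self.frame.index.name or "sample_id"

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def sites(self) -> list[str]:
        return sorted(self.frame["site"].unique().tolist())

    def samples(self, site: str | None = None, microhabitat: str | None = None) -> pd.Index:
        """Sample ids matching the given site and/or microhabitat."""
        mask = pd.Series(True, index=self.frame.index)
        if site is not None:
            mask &= self.frame["site"] == site
        if microhabitat is not None:
            mask &= self.frame["microhabitat"] == microhabitat
        return self.frame.index[mask]

    def groups(self) -> list[tuple[str, str]]:
        """All observed (site, microhabitat) combinations, sorted."""
        pairs = self.frame[["site", "microhabitat"]].drop_duplicates()
        return sorted(map(tuple, pairs.to_numpy().tolist()))

    def group_labels(self) -> pd.Series:
        """Per-sample ``site|microhabitat`` labels (the 4-level grouping)."""
        return self.frame["site"].str.cat(self.frame["microhabitat"], sep="|")

    def copy(self) -> "SampleMetadata":
        return SampleMetadata(self.frame.copy())


@dataclass
class Bundle:
    """An aligned (table, taxonomy, metadata) triple."""

    table: FeatureTable
    taxonomy: TaxonomyMap
    metadata: SampleMetadata
    report: dict = field(default_factory=dict)
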