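"""Reading, writing and aligning the tabular inputs.

Supported dialects are plain TSV and the classic BIOM TSV export
(``#OTU ID`` header, optional ``# Constructed from biom file`` comment
line, optional trailing ``taxonomy`` column). Numeric parsing is strict:
a non-numeric cell raises rather than silently becoming zero, because a
silent zero would corrupt presence/absence (occupancy) logic downstream.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RANKS, Bundle, FeatureTable, SampleMetadata, TaxonomyMap
from .exceptions import TableParseError, TableValidationError

logger = logging.getLogger(__name__)

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")
_TAXONOMY_COLUMN_NAMES = {"taxonomy", "taxon", "lineage"}
_SAMPLE_ROW_HINTS = {"sample-id", "sampleid", "sample id", "sample", "#sampleid"}


def parse_lineage(lineage: str | None) -> dict[str, str | None]:
    """Parse a ``;``-separated lineage string into named ranks.

    Handles the QIIME2/SILVA/UNITE dialect (``k__Fungi; p__Basidiomycota;
    ...``) as well as bare rank names without prefixes. Ranks are assigned
    positionally, domain first; empty or absent trailing ranks map to
    ``None``. Total on strings: never raises.
    """
    ranks: dict[str, str | None] = {r: None for r in RANKS}
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return ranks
    parts = str(lineage).split(";")
    for rank, part in zip(RANKS, parts):
        name = _RANK_PREFIX.sub("", part.strip()).strip()
        ranks[rank] = name or None
    return ranks


def _read_tsv_lines(path: Path) -> tuple[list[str], list[list[str]]]:
    """Split a TSV file into header cells and data rows, checking raggedness."""
    with open(path, "rt", encoding="utf-8") as handle:
        raw = [line.rstrip("\n") for line in handle if line.strip()]
    # classic BIOM exports open with a comment line before the #OTU ID header
    while raw and raw[0].startswith("#") and not raw[0].lower().startswith("#otu id") \
            and not raw[0].lower().lstrip("#").strip().startswith("sample"):
        raw.pop(0)
    if not raw:
        raise TableParseError(f"{path}: empty file")
    header = raw[0].split("\t")
    rows = []
    for lineno, line in enumerate(raw[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TableParseError(
                f"{path}:{lineno}: ragged row has {len(cells)} cells, header has {len(header)}"
            )
        rows.append(cells)
    return header, rows


def _to_numeric_strict(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    try:
        return frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableParseError(f"{path}: non-numeric cell in count table ({exc})") from exc


def read_feature_table(
    path: str | Path, orientation: str = "auto"
) -> tuple[FeatureTable, pd.Series | None]:
    """Read a count table; returns the table and any split-off taxonomy column.

    ``orientation`` is one of ``"features"`` (features on rows, the classic
    BIOM layout), ``"samples"`` (samples on rows), or ``"auto"`` which
    assumes features on rows unless the header's first cell names a sample
    id column.
    """
    path = Path(path)
    header, rows = _read_tsv_lines(path)
    if orientation not in {"auto", "features", "samples"}:
        raise ValueError(f"unknown orientation hint {orientation!r}")
    if orientation == "auto":
        first = header[0].lower().lstrip("#").strip()
        orientation = "samples" if first in _SAMPLE_ROW_HINTS else "features"

    ids = [r[0] for r in rows]
    frame = pd.DataFrame([r[1:] for r in rows], index=ids, columns=header[1:])

    taxonomy_col: pd.Series | None = None
    if orientation == "features":
        tax_cols = [c for c in frame.columns if c.strip().lower() in _TAXONOMY_COLUMN_NAMES]
        if tax_cols:
            taxonomy_col = frame[tax_cols[0]].rename("taxonomy")
            frame = frame.drop(columns=tax_cols)

    frame = _to_numeric_strict(frame, path)
    if orientation == "samples":
        frame = frame.T
    frame.index.name = "feature_id"
    return FeatureTable(frame), taxonomy_col


def write_feature_table(table: FeatureTable, path: str | Path, biom_header: bool = True) -> None:
    """Write a table as TSV, features on rows (``#OTU ID`` leading cell)."""
    path = Path(path)
    frame = table.counts
    if not table.normalized and table.is_integral():
        frame = frame.astype(np.int64)
    out = frame.copy()
    out.index.name = "#OTU ID" if biom_header else "feature_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a taxonomy table: either (id, lineage string) or per-rank columns."""
    path = Path(path)
    header, rows = _read_tsv_lines(path)
    ids = [r[0] for r in rows]
    frame = pd.DataFrame([r[1:] for r in rows], index=ids, columns=header[1:])
    lower = {c.strip().lower(): c for c in frame.columns}
    if set(RANKS) <= set(lower):
        ranks = frame[[lower[r] for r in RANKS]]
        ranks.columns = list(RANKS)
        ranks = ranks.replace("", None)
        return TaxonomyMap(ranks)
    lineage_cols = [lower[c] for c in _TAXONOMY_COLUMN_NAMES if c in lower]
    if not lineage_cols:
        raise TableParseError(
            f"{path}: expected either rank columns {RANKS} or a lineage column "
            f"named one of {sorted(_TAXONOMY_COLUMN_NAMES)}"
        )
    parsed = pd.DataFrame(
        [parse_lineage(s) for s in frame[lineage_cols[0]]], index=frame.index
    )
    return TaxonomyMap(parsed)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    """Write taxonomy as a QIIME2-style lineage string per feature."""
    prefixes = ("k__", "p__", "c__", "o__", "f__", "g__")
    lines = []
    for fid, row in taxonomy.ranks.iterrows():
        parts = [p + (row[r] or "") for p, r in zip(prefixes, RANKS)]
        lines.append((fid, "; ".join(parts)))
    frame = pd.DataFrame(lines, columns=["Feature ID", "Taxon"]).set_index("Feature ID")
    frame.to_csv(path, sep="\t")


def read_metadata(
    path: str | Path,
    sample_column: str = "sample_id",
    site_column: str = "site",
    microhabitat_column: str = "microhabitat",
    replicate_column: str = "replicate",
) -> SampleMetadata:
    """Read sample metadata and normalize microhabitat labels.

    Microhabitat strings are matched case-insensitively onto
    {understory, gap}; anything else raises quoting the offending value.
    """
    path = Path(path)
    header, rows = _read_tsv_lines(path)
    header = [h.lstrip("#").strip() for h in header]
    frame = pd.DataFrame(rows, columns=header)
    for col in (sample_column, site_column, microhabitat_column):
        if col not in frame.columns:
            raise TableValidationError(f"{path}: missing required metadata column {col!r}")
    frame = frame.set_index(sample_column)
    habitat = frame[microhabitat_column].str.strip().str.lower()
    bad = sorted(set(habitat) - {"understory", "gap"})
    if bad:
        raise TableValidationError(
            f"{path}: unknown microhabitat value(s) {bad!r}; expected understory/gap"
        )
    out = pd.DataFrame(
        {
            "site": frame[site_column].str.strip(),
            "microhabitat": habitat,
        },
        index=frame.index,
    )
    if replicate_column in frame.columns:
        out["replicate"] = frame[replicate_column]
    out.index.name = "sample_id"
    return SampleMetadata(out)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t")


def align_bundle(
    table: FeatureTable, taxonomy: TaxonomyMap, metadata: SampleMetadata
) -> Bundle:
    """Restrict to shared samples and order everything deterministically.

    Samples are the intersection of table and metadata ids (dropped ids
    reported and logged); features lacking taxonomy are retained with an
    all-missing lineage; feature and sample order is lexicographic. The
    operation is idempotent.
    """
    shared = sorted(set(table.sample_ids) & set(metadata.sample_ids))
    if not shared:
        raise TableValidationError("no samples shared between table and metadata")
    dropped_table = sorted(set(table.sample_ids) - set(shared))
    dropped_meta = sorted(set(metadata.sample_ids) - set(shared))
    features = sorted(table.feature_ids)

    counts = table.counts.loc[features, shared]
    meta = SampleMetadata(metadata.frame.loc[shared].copy())

    missing_tax = sorted(set(features) - set(taxonomy.feature_ids))
    ranks = taxonomy.ranks.reindex(features)
    tax = TaxonomyMap(ranks)

    report = {
        "dropped_table_samples": dropped_table,
        "dropped_metadata_samples": dropped_meta,
        "features_without_taxonomy": missing_tax,
    }
    for key, ids in report.items():
        if ids:
            logger.info("align_bundle: %s = %s", key, ids)
    return Bundle(FeatureTable(counts, normalized=table.normalized), tax, meta, report)
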