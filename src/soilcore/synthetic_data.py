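"""Synthetic two-site, two-microhabitat community generator with planted truth.

The generator emulates a paired shrub-soil survey: two sites, each with
understory (beneath-canopy) and gap (open soil) samples, overdispersed
genus counts at variable sequencing depth, and three kinds of planted
structure that downstream stages must recover:

* **core genera** - present in every understory sample at both sites and
  structurally absent (exact zeros) from every gap sample;
* **site-specific genera** - present at one site only (both microhabitats);
* **differential genera** - shared by both microhabitats with a planted
  log2 fold-change between understory and gap.

Counts are Dirichlet-multinomial: per sample the mixing proportions are
drawn as Dirichlet(concentration x group proportions), then counts as
Multinomial(depth, mixing), which reproduces the overdispersion typical
of amplicon data. Background genus abundances follow a log-normal
rank-abundance curve (sigma = 1.5 decades).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    GAP,
    RANKS,
    UNDERSTORY,
    Bundle,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
)
from .exceptions import ConfigurationError
from . import tabular_io

_PROK_PHYLA = (
    "Pseudomonadota",
    "Actinomycetota",
    "Acidobacteriota",
    "Bacteroidota",
    "Planctomycetota",
    "Verrucomicrobiota",
)
_FUNGAL_PHYLA = ("Ascomycota", "Basidiomycota", "Mortierellomycota")

FORMAT_VERSION = "1"


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study; defaults mirror the field design
    of ~10 replicate soil samples per site x microhabitat group."""

    sites: tuple[str, str] = ("SiteA", "SiteB")
    n_samples_per_group: int = 10
    n_background_genera: int = 200
    n_core_prokaryote: int = 3
    n_core_fungal: int = 2
    n_site_specific_genera: int = 5
    n_diff_abund_genera: int = 10
    diff_log2_fold_change: float = 2.0
    core_rel_abundance: float = 0.01
    depth_range: tuple[int, int] = (20_000, 60_000)
    overdispersion: float = 200.0  # Dirichlet concentration scalar
    background_sigma_decades: float = 1.5
    seed: int | None = None  # None lets the pipeline derive it from its master seed

    def validate(self) -> None:
        if len(self.sites) != 2 or len(set(self.sites)) != 2:
            raise ConfigurationError("sites must be two distinct labels")
        if self.n_samples_per_group < 2:
            raise ConfigurationError("n_samples_per_group must be >= 2")
        for name in (
            "n_background_genera",
            "n_core_prokaryote",
            "n_core_fungal",
            "n_site_specific_genera",
            "n_diff_abund_genera",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_background_genera < 1:
            raise ConfigurationError("n_background_genera must be >= 1")
        if not (0 <= self.core_rel_abundance < 1):
            raise ConfigurationError("core_rel_abundance must be in [0, 1)")
        n_core = self.n_core_prokaryote + self.n_core_fungal
        if n_core * self.core_rel_abundance >= 1:
            raise ConfigurationError("core_rel_abundance: total planted core mass must be < 1")
        lo, hi = self.depth_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("depth_range must satisfy 0 <= low <= high")
        if self.overdispersion <= 0:
            raise ConfigurationError("overdispersion concentration must be > 0")
        if self.background_sigma_decades <= 0:
            raise ConfigurationError("background_sigma_decades must be > 0")

    @property
    def n_core_genera(self) -> int:
        return self.n_core_prokaryote + self.n_core_fungal


@dataclass
class SyntheticTruth:
    """Planted structure of a generated dataset, for recovery testing."""

    core_genera: set[str]
    site_specific: dict[str, set[str]]  # site -> genus set
    diff_abund: dict[str, float]  # genus -> true log2FC (understory vs gap)
    group_mean_proportions: pd.DataFrame  # genus x "site|microhabitat"
    config: GeneratorConfig


def sample_counts(proportions, depth: int, concentration: float, rng) -> np.ndarray:
    """One Dirichlet-multinomial draw of ``depth`` reads.

    Mixing proportions ~ Dirichlet(concentration x proportions) over the
    positive-probability support (structural zeros stay exactly zero),
    counts ~ Multinomial(depth, mixing); the result sums to ``depth``.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ConfigurationError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"proportions must sum to 1, got {p.sum()!r}")
    if depth < 0:
        raise ConfigurationError("depth must be >= 0")
    if concentration <= 0:
        raise ConfigurationError("concentration must be > 0")
    counts = np.zeros(p.shape[0], dtype=np.int64)
    if depth == 0:
        return counts
    support = p > 0
    mixing = rng.dirichlet(concentration * p[support])
    counts[support] = rng.multinomial(depth, mixing)
    return counts


def _genus_names(config: GeneratorConfig) -> dict[str, list[str]]:
    names = {
        "background": [f"Genus{i:04d}" for i in range(1, config.n_background_genera + 1)],
        "core": (
            [f"CoreProk{i}" for i in range(1, config.n_core_prokaryote + 1)]
            + [f"CoreFungi{i}" for i in range(1, config.n_core_fungal + 1)]
        ),
        "diff": [f"DiffGenus{i:02d}" for i in range(1, config.n_diff_abund_genera + 1)],
    }
    for site in config.sites:
        names[f"specific:{site}"] = [
            f"{site}Only{i:02d}" for i in range(1, config.n_site_specific_genera + 1)
        ]
    return names


def _group_proportions(config: GeneratorConfig, rng) -> tuple[pd.DataFrame, dict]:
    """Mean proportion vector for each of the 4 groups, plus name roles."""
    names = _genus_names(config)
    non_core = (
        names["background"]
        + names["diff"]
        + [g for site in config.sites for g in names[f"specific:{site}"]]
    )
    all_genera = non_core + names["core"]
    # log-normal rank-abundance weights (sigma in log10 decades)
    sigma_ln = config.background_sigma_decades * np.log(10)
    weights = pd.Series(
        np.exp(rng.normal(0.0, sigma_ln, size=len(non_core))), index=non_core
    )
    fc = 2.0 ** config.diff_log2_fold_change
    core_mass = config.n_core_genera * config.core_rel_abundance

    columns = {}
    for site in config.sites:
        other = [s for s in config.sites if s != site][0]
        for habitat in (UNDERSTORY, GAP):
            w = weights.copy()
            w[names[f"specific:{other}"]] = 0.0
            if habitat == UNDERSTORY:
                w[names["diff"]] *= fc
            p = pd.Series(0.0, index=all_genera)
            if habitat == UNDERSTORY:
                p[non_core] = w / w.sum() * (1.0 - core_mass)
                p[names["core"]] = config.core_rel_abundance
            else:
                p[non_core] = w / w.sum()
            columns[f"{site}|{habitat}"] = p
    props = pd.DataFrame(columns)
    props.index.name = "genus"
    return props, names


def _taxonomy(config: GeneratorConfig, names: dict, rng) -> TaxonomyMap:
    rows = {}

    def lineage(genus: str, fungal: bool) -> dict:
        phyla = _FUNGAL_PHYLA if fungal else _PROK_PHYLA
        phylum = phyla[rng.integers(len(phyla))]
        domain = "Fungi" if fungal else "Bacteria"
        return dict(
            zip(
                RANKS,
                (domain, phylum, f"{phylum}_c", f"{phylum}_o", f"{genus}_f", genus),
            )
        )

    for genus in names["core"]:
        rows[genus] = lineage(genus, fungal=genus.startswith("CoreFungi"))
    other = (
        names["background"]
        + names["diff"]
        + [g for site in config.sites for g in names[f"specific:{site}"]]
    )
    for genus in other:
        rows[genus] = lineage(genus, fungal=bool(rng.random() < 0.3))
    frame = pd.DataFrame.from_dict(rows, orient="index").loc[sorted(rows)]
    frame.index.name = "feature_id"
    return TaxonomyMap(frame)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[FeatureTable, TaxonomyMap, SampleMetadata, SyntheticTruth]:
    """Generate one seeded dataset bundle with planted ground truth.

    Every planted core genus has count > 0 in every understory sample
    (a sample whose Dirichlet-multinomial draw happens to zero a core
    genus is redrawn) and exact zeros in every gap sample. Column sums
    equal the drawn per-sample depths exactly.
    """
    config.validate()
    rng = np.random.default_rng(0 if config.seed is None else config.seed)
    props, names = _group_proportions(config, rng)
    genera = props.index

    sample_ids, sites_col, habitat_col, replicate_col = [], [], [], []
    columns = {}
    core_idx = genera.get_indexer(names["core"])
    for site in config.sites:
        for habitat in (UNDERSTORY, GAP):
            p = props[f"{site}|{habitat}"].to_numpy()
            for i in range(1, config.n_samples_per_group + 1):
                sid = f"{site}_{habitat}_{i:02d}"
                depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
                for _attempt in range(1000):
                    counts = sample_counts(p, depth, config.overdispersion, rng)
                    if habitat == GAP or depth == 0 or len(core_idx) == 0 \
                            or (counts[core_idx] > 0).all():
                        break
                else:  # pragma: no cover - p(reach) vanishes at sane configs
                    raise RuntimeError("could not draw a sample containing all core genera")
                columns[sid] = counts
                sample_ids.append(sid)
                sites_col.append(site)
                habitat_col.append(habitat)
                replicate_col.append(str(i))

    table = FeatureTable(pd.DataFrame(columns, index=genera))
    metadata = SampleMetadata(
        pd.DataFrame(
            {"site": sites_col, "microhabitat": habitat_col, "replicate": replicate_col},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    taxonomy = _taxonomy(config, names, rng)
    truth = SyntheticTruth(
        core_genera=set(names["core"]),
        site_specific={s: set(names[f"specific:{s}"]) for s in config.sites},
        diff_abund={g: config.diff_log2_fold_change for g in names["diff"]},
        group_mean_proportions=props,
        config=config,
    )
    return table, taxonomy, metadata, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    metadata: SampleMetadata,
    truth: SyntheticTruth,
    directory: str | Path,
) -> dict:
    """Write the bundle as TSV files plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "feature_table": directory / "feature_table.tsv",
        "taxonomy": directory / "taxonomy.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.tsv",
        "group_mean_proportions": directory / "group_mean_proportions.tsv",
    }
    tabular_io.write_feature_table(table, paths["feature_table"])
    tabular_io.write_taxonomy(taxonomy, paths["taxonomy"])
    tabular_io.write_metadata(metadata, paths["metadata"])

    rows = []
    for genus in sorted(truth.core_genera):
        rows.append({"genus": genus, "role": "core", "site": "", "log2_fold_change": ""})
    for site, genera in sorted(truth.site_specific.items()):
        for genus in sorted(genera):
            rows.append({"genus": genus, "role": "site_specific", "site": site,
                         "log2_fold_change": ""})
    for genus, lfc in sorted(truth.diff_abund.items()):
        rows.append({"genus": genus, "role": "diff_abund", "site": "",
                     "log2_fold_change": lfc})
    pd.DataFrame(rows, columns=["genus", "role", "site", "log2_fold_change"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    truth.group_mean_proportions.to_csv(
        paths["group_mean_proportions"], sep="\t", float_format="%.12g"
    )

    manifest = {
        "format_version": FORMAT_VERSION,
        "seed": truth.config.seed,
        "config": asdict(truth.config),
        "files": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in paths.items()},
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=list)
    return manifest


def load_fixture_bundle(directory: str | Path) -> Bundle:
    """Read back a written bundle (table, taxonomy, metadata), aligned."""
    directory = Path(directory)
    table, _ = tabular_io.read_feature_table(directory / "feature_table.tsv")
    taxonomy = tabular_io.read_taxonomy(directory / "taxonomy.tsv")
    metadata = tabular_io.read_metadata(directory / "metadata.tsv")
    return tabular_io.align_bundle(table, taxonomy, metadata)


def read_truth_table(directory: str | Path) -> pd.DataFrame:
    """The planted-truth table of a written bundle as a DataFrame."""
    return pd.read_csv(Path(directory) / "truth.tsv", sep="\t", dtype=str)
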