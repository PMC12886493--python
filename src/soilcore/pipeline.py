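"""End-to-end orchestration: input bundle to report directory.

Stages: taxonomy cleanup -> genus agglomeration -> prevalence filter ->
{Chao alpha diversity + Kruskal-Wallis} and {CSS -> Bray-Curtis -> PCoA ->
PERMANOVA + pairwise} and {per-site differential abundance (+ optional
functional tally)} and {threshold sweep -> core sets + Venn partitions}.

All outputs are plain TSV plus a JSON manifest (parameters, derived stage
seeds, sha256 checksums), and a fixed master seed makes the TSV outputs
byte-identical across runs. Stage seeds are derived as
``SeedSequence([master_seed, stage_index]).generate_state(1)[0] % 2**31``
with a fixed stage-index table, so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core as core_mod
from . import diffabund as da
from . import diversity as div
from . import normalization as norm
from . import synthetic_data as synth
from . import tabular_io
from .containers import Bundle
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

_STAGE_INDEX = {"generator": 0, "permanova": 1, "pairwise_permanova": 2}

_FLOAT_FORMAT = "%.10g"


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed from the master seed."""
    idx = _STAGE_INDEX[stage]
    state = np.random.SeedSequence([int(master_seed), idx]).generate_state(1)[0]
    return int(state % (2**31))


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults follow the study settings
    (10% prevalence filter, CSS quantile 0.5, thresholds 0.2/0.5/1/5%,
    999 permutations, adjusted-p significance at 0.05)."""

    output_dir: str | Path = "soilcore_output"
    table_path: str | Path | None = None
    taxonomy_path: str | Path | None = None
    metadata_path: str | Path | None = None
    generator: synth.GeneratorConfig | None = None
    guild_map_path: str | Path | None = None
    css_quantile: float = 0.5
    prevalence_fraction: float = 0.10
    thresholds: tuple = core_mod.DEFAULT_THRESHOLDS
    statistic: str = "mean"
    gap_exclusion: str = "pooled"
    n_permutations: int = 999
    n_axes: int = 2
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        have_paths = self.table_path and self.metadata_path
        if not have_paths and self.generator is None:
            raise ConfigurationError(
                "either table_path+metadata_path or a generator config is required"
            )


def _load_inputs(config: PipelineConfig, outdir: Path) -> Bundle:
    if config.generator is not None:
        gen = config.generator
        gen.seed = derive_seed(config.seed, "generator") if gen.seed is None else gen.seed
        table, taxonomy, metadata, truth = synth.generate_dataset(gen)
        synth.write_fixture_bundle(table, taxonomy, metadata, truth, outdir / "inputs")
        return tabular_io.align_bundle(table, taxonomy, metadata)
    table, tax_col = tabular_io.read_feature_table(config.table_path)
    if config.taxonomy_path:
        taxonomy = tabular_io.read_taxonomy(config.taxonomy_path)
    elif tax_col is not None:
        parsed = pd.DataFrame(
            [tabular_io.parse_lineage(s) for s in tax_col], index=tax_col.index
        )
        taxonomy = tabular_io.TaxonomyMap(parsed)
    else:
        raise ConfigurationError("no taxonomy: provide taxonomy_path or an embedded column")
    metadata = tabular_io.read_metadata(config.metadata_path)
    return tabular_io.align_bundle(table, taxonomy, metadata)


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages_done = []

    def stage(name):
        logger.info("stage: %s", name)
        stages_done.append(name)

    bundle = _load_inputs(config, outdir)
    table, taxonomy, metadata = bundle.table, bundle.taxonomy, bundle.metadata

    stage("clean_taxa")
    table, removed_unclassified = core_mod.clean_taxa(table, taxonomy)

    stage("agglomerate_to_genus")
    genus_table = core_mod.agglomerate_to_genus(table, taxonomy)

    stage("prevalence_filter")
    filtered, removed_rare = norm.prevalence_filter(genus_table, config.prevalence_fraction)

    groups = metadata.group_labels()

    stage("alpha_diversity")
    chao = div.chao1_per_sample(filtered)
    alpha_frame = pd.DataFrame(
        {
            "chao1": chao,
            "site": metadata.frame["site"],
            "microhabitat": metadata.frame["microhabitat"],
        }
    )
    alpha_frame.index.name = "sample_id"
    _write(alpha_frame, outdir / "alpha_diversity.tsv")

    kw = div.kruskal_wallis(chao.to_numpy(), groups.loc[chao.index].to_numpy())
    levels = sorted(groups.unique())
    pair_rows = []
    import itertools as _it

    for a, b in _it.combinations(levels, 2):
        mask = groups.isin([a, b])
        res = div.kruskal_wallis(chao[mask].to_numpy(), groups[mask].to_numpy())
        pair_rows.append({"contrast": f"{a} vs {b}", "H": res.statistic, "p": res.p_value})
    pair_frame = pd.DataFrame(pair_rows)
    pair_frame["p_adjusted"] = div.bh_adjust(pair_frame["p"].to_numpy())
    tests = pd.concat(
        [
            pd.DataFrame(
                [{"contrast": "overall", "H": kw.statistic, "p": kw.p_value,
                  "p_adjusted": kw.p_value}]
            ),
            pair_frame,
        ],
        ignore_index=True,
    ).set_index("contrast")
    _write(tests, outdir / "alpha_tests.tsv")

    stage("css_normalize")
    css = norm.css_normalize(filtered, quantile=config.css_quantile)

    stage("bray_curtis")
    dist = div.bray_curtis_matrix(css)
    dist_frame = pd.DataFrame(dist.data, index=list(dist.ids), columns=list(dist.ids))
    dist_frame.index.name = "sample_id"
    _write(dist_frame, outdir / "bray_curtis.tsv")

    stage("pcoa")
    ordination = div.pcoa(dist, n_axes=config.n_axes)
    coords = ordination.coordinates.join(metadata.frame[["site", "microhabitat"]])
    coords.index.name = "sample_id"
    _write(coords, outdir / "pcoa_coordinates.tsv")
    eig = pd.DataFrame(
        {
            "eigenvalue": ordination.eigenvalues,
            "axis": [f"axis{i + 1}" for i in range(len(ordination.eigenvalues))],
        }
    ).set_index("axis")
    _write(eig, outdir / "pcoa_eigenvalues.tsv")

    stage("permanova")
    seed_perm = derive_seed(config.seed, "permanova")
    overall = div.permanova(
        dist, groups, n_permutations=config.n_permutations, seed=seed_perm,
        grouping="site|microhabitat",
    )
    seed_pair = derive_seed(config.seed, "pairwise_permanova")
    pairwise = div.pairwise_permanova(
        dist, groups, n_permutations=config.n_permutations, seed=seed_pair
    )
    perm_rows = [
        {
            "contrast": r.grouping,
            "pseudo_F": r.pseudo_F,
            "R2": r.R2,
            "p": r.p_value,
            "p_adjusted": r.adjusted_p if r.adjusted_p is not None else r.p_value,
            "n_permutations": r.n_permutations,
            "seed": r.seed,
        }
        for r in [overall, *pairwise]
    ]
    _write(pd.DataFrame(perm_rows).set_index("contrast"), outdir / "permanova.tsv")

    stage("diff_abund")
    guilds = da.read_guild_map(config.guild_map_path) if config.guild_map_path else None
    for site in metadata.sites:
        result = da.diff_abund(genus_table, metadata, site=site, alpha=config.alpha)
        frame = result.results.sort_index()
        frame.index.name = "genus"
        _write(frame, outdir / f"diffabund_{site}.tsv")
        if guilds is not None:
            tally = da.function_tally(result, guilds)
            _write(tally, outdir / f"function_tally_{site}.tsv")

    stage("core_sweep")
    sweep = core_mod.threshold_sweep(
        genus_table,
        metadata,
        thresholds=config.thresholds,
        statistic=config.statistic,
        gap_exclusion=config.gap_exclusion,
    )
    _write(core_mod.sweep_summary(sweep), outdir / "core_summary.tsv")
    for res in sweep:
        tag = ("%g" % res.threshold).replace(".", "_")
        rows = []
        for genus in sorted(res.occupancy):
            und, gap = res.occupancy[genus]
            rows.append(
                {
                    "genus": genus,
                    "understory_occupancy": und,
                    "gap_occupancy": gap,
                    "is_core": genus in res.core_genera,
                }
            )
        frame = pd.DataFrame(rows, columns=["genus", "understory_occupancy",
                                            "gap_occupancy", "is_core"])
        _write(frame.set_index("genus"), outdir / f"core_threshold_{tag}.tsv")

        named = {
            f"{site}|{hab}": genera for (site, hab), genera in res.group_sets.sets.items()
        }
        venn = core_mod.venn_partition(named)
        venn_rows = [
            {
                "region": "&".join(sorted(combo)),
                "count": len(members),
                "percent_of_union": 100.0 * len(members) / max(len(venn.union), 1),
            }
            for combo, members in sorted(
                venn.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        _write(pd.DataFrame(venn_rows).set_index("region"), outdir / f"venn_{tag}.tsv")

    stage("manifest")
    outputs = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "soilcore_version": "0.1.0",
        "master_seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in _STAGE_INDEX},
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
            if k != "generator"
        },
        "generator": asdict(config.generator) if config.generator else None,
        "stages": stages_done,
        "n_features_removed_no_phylum": len(removed_unclassified),
        "n_genera_removed_rare": len(removed_rare),
        "alignment_report": bundle.report,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in outputs
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=list)
    return manifest
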