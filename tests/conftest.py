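"""Shared fixtures: small hand-built tables and a seeded synthetic bundle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import soilcore as sc


@pytest.fixture(scope="session")
def default_bundle():
    """One generated dataset at default study conditions (seeded)."""
    config = sc.GeneratorConfig(seed=11)
    table, taxonomy, metadata, truth = sc.generate_dataset(config)
    return table, taxonomy, metadata, truth


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[5, 0, 2], [1, 3, 0], [4, 4, 4]],
        index=["GenusA", "GenusB", "GenusC"],
        columns=["S1", "S2", "S3"],
    )
    return sc.FeatureTable(counts)


@pytest.fixture
def two_site_metadata():
    """2 sites x 2 microhabitats x 3 replicates = 12 samples."""
    rows = []
    for site in ("SiteA", "SiteB"):
        for habitat in ("understory", "gap"):
            for i in range(1, 4):
                rows.append((f"{site}_{habitat}_{i}", site, habitat, str(i)))
    frame = pd.DataFrame(rows, columns=["sample_id", "site", "microhabitat", "replicate"])
    return sc.SampleMetadata(frame.set_index("sample_id"))


def random_community_table(rng: np.random.Generator, n_genera: int, sample_ids) -> sc.FeatureTable:
    """A sparse random count table with no all-zero samples."""
    lam = np.exp(rng.normal(1.0, 2.0, size=n_genera))
    counts = rng.poisson(lam[:, None], size=(n_genera, len(sample_ids)))
    counts *= rng.random(counts.shape) > 0.3  # zero-inflate
    counts[0, :] += 1  # guard against all-zero samples
    frame = pd.DataFrame(
        counts, index=[f"Genus{i:03d}" for i in range(n_genera)], columns=list(sample_ids)
    )
    return sc.FeatureTable(frame)
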