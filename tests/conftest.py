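"""Shared fixtures: a small ground-truthed WT/KO library pair, processed
through the full pipeline once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from pirnapipe import SimulationConfig, build_reference, simulate_library
from pirnapipe.cli import process_reads
from pirnapipe.mapping import ReferenceBundle


SMALL_DEPTH = 20_000


def make_config(**overrides) -> SimulationConfig:
    base = dict(seed=7, depth=SMALL_DEPTH)
    base.update(overrides)
    return SimulationConfig(**base)


def bundle_for(ref) -> ReferenceBundle:
    return ReferenceBundle(
        mirnas=ref.mirnas,
        genome=[(ref.chrom, ref.genome)],
        clusters=ref.clusters,
        consensus_set=ref.consensus,
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return make_config()


@pytest.fixture(scope="session")
def small_ref(small_config):
    return build_reference(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_ref):
    return bundle_for(small_ref)


@pytest.fixture(scope="session")
def small_pair(small_config, small_ref):
    """(reads, truth) per genotype for the default depletion preset."""
    return {
        g: simulate_library(small_ref, small_config, g) for g in ("WT", "KO")
    }


@pytest.fixture(scope="session")
def small_assignments(small_pair, small_bundle) -> dict[str, pd.DataFrame]:
    """Processed assignment tables with the true class joined on."""
    out = {}
    for genotype, (reads, truth) in small_pair.items():
        df = process_reads(reads, small_bundle, genotype)
        tmap = {t.read_id: t.true_class for t in truth}
        gmap = {t.read_id: t.guide_length for t in truth}
        df["true_class"] = df["read_id"].map(tmap)
        df["true_guide_length"] = df["read_id"].map(gmap)
        out[genotype] = df
    return out
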