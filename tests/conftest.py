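"""Shared fixtures: a small simulated discovery run used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dsbtag import alignment
from dsbtag.seqio import Sample, SampleManifest, demultiplex, extract_umi
from dsbtag.simulate import SimConfig, simulate_discovery_library, simulate_genome
from dsbtag.sitecall import GuideSpec
from dsbtag.tagscan import DEFAULT_DSODNS, DsODNSpec

PROTOSPACER = "GACGTTAACCGGATCCATGC"


@pytest.fixture(scope="session")
def guide() -> GuideSpec:
    return GuideSpec("g_test", PROTOSPACER, pam="NGG")


@pytest.fixture(scope="session")
def dsodn() -> DsODNSpec:
    return DsODNSpec("dsodn_39", DEFAULT_DSODNS["dsodn_39"])


@pytest.fixture(scope="session")
def sim_cfg(guide, dsodn) -> SimConfig:
    # 1 on-target + 10 off-targets, moderate depth, 0.5% error
    return SimConfig(
        seed=29,
        guide=guide,
        dsodn=dsodn,
        genome_length=60_000,
        offtarget_plan=[((i % 7) + 1, 18 + 2 * i) for i in range(10)],
        on_target_molecules=60,
    )


@pytest.fixture(scope="session")
def sim_genome(sim_cfg):
    return simulate_genome(sim_cfg)


@pytest.fixture(scope="session")
def sim_library(sim_cfg, sim_genome):
    genome, truth = sim_genome
    return simulate_discovery_library(genome, truth, sim_cfg)


@pytest.fixture(scope="session")
def ref_index(sim_genome):
    genome, _ = sim_genome
    return alignment.build_index(genome, k=20)


@pytest.fixture(scope="session")
def umi_reads(sim_cfg, sim_library):
    """UMI-tagged reads of the single simulated sample, demultiplexed."""
    pairs, _ = sim_library
    manifest = SampleManifest([Sample("s1", sim_cfg.barcode)])
    assigned, _, _ = demultiplex(iter(pairs), manifest)
    return [u for u in (extract_umi(p) for p in assigned["s1"]) if u is not None]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
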