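"""Shared fixtures: small seeded genomes and simulated read sets."""

import numpy as np
import pytest

import saltosites as ss


@pytest.fixture(scope="session")
def small_host() -> ss.Genome:
    """50 kb circular host, 65% GC, one low-GC island, no motifs."""
    return ss.make_host_genome(50_000, 0.65,
                               low_gc_islands=((20_001, 1530, 0.42),),
                               seed=11)


@pytest.fixture(scope="session")
def toy_phage() -> ss.Genome:
    """10 kb phage with the rescaled enzyme-site layout (181 bp right end)."""
    return ss.make_phage_genome(ss.scaled_phage_spec(10_000), seed=12)


@pytest.fixture(scope="session")
def full_phage() -> ss.Genome:
    """Default 37,205 bp phage layout."""
    return ss.make_phage_genome(seed=13)


@pytest.fixture(scope="session")
def enriched_readset(small_host, toy_phage):
    """2,000 events packaged in enriched-right mode, with truth."""
    model = ss.SiteModel(immunity_leak=0.004)
    events = ss.sample_insertions(2000, small_host, toy_phage, model, seed=21)
    reads = ss.package_reads(events, small_host, toy_phage,
                             mode="enriched-right", seed=22)
    return events, reads


@pytest.fixture(scope="session")
def virion_readset(small_host, toy_phage):
    """800 events packaged in whole-virion mode, with truth."""
    model = ss.SiteModel(immunity_leak=0.0)
    events = ss.sample_insertions(800, small_host, toy_phage, model, seed=31)
    reads = ss.package_reads(events, small_host, toy_phage,
                             mode="whole-virion", seed=32)
    return events, reads


def right_end_seq(phage: ss.Genome) -> str:
    cut = ss.find_enzyme_cut_sites(phage)[-1]
    return phage.seq[cut:]
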