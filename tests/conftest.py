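"""Shared fixtures: one session-scoped synthetic dataset plus the analysis
objects derived from it, so expensive generation happens once."""

import pytest

from clipsplice.annotation import Annotation
from clipsplice.io import read_fasta
from clipsplice.parclip import (
    annotate_clusters,
    build_conversion_profile,
    call_clusters,
    read_alignments,
)
from clipsplice.simulate import SimConfig, Simulator
from clipsplice.splicing import (
    discover_events,
    extract_junctions,
    merge_junctions,
    test_differential,
)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    cfg = SimConfig(seed=7)
    sim = Simulator(cfg)
    truth = sim.make_genome()
    outdir = tmp_path_factory.mktemp("simdata")
    files = sim.write_all(outdir)
    return {"config": cfg, "sim": sim, "truth": truth, "files": files}


@pytest.fixture(scope="session")
def genome(sim_bundle):
    return read_fasta(sim_bundle["files"]["fasta"])


@pytest.fixture(scope="session")
def annotation(sim_bundle):
    return Annotation.from_gtf(sim_bundle["files"]["gtf"])


@pytest.fixture(scope="session")
def parclip_reads(sim_bundle, genome):
    return [
        read_alignments(p, genome) for p in sim_bundle["files"]["parclip"]
    ]


@pytest.fixture(scope="session")
def called_clusters(sim_bundle, genome, annotation, parclip_reads):
    pooled = [r for rep in parclip_reads for r in rep]
    profile = build_conversion_profile(pooled)
    clusters = call_clusters(profile, pooled)
    clusters, fractions = annotate_clusters(clusters, annotation, genome)
    return {"clusters": clusters, "fractions": fractions, "profile": profile}


@pytest.fixture(scope="session")
def rnaseq_samples(sim_bundle):
    files = sim_bundle["files"]
    n = sim_bundle["config"].n_replicates_per_condition
    names = [f"{c}{r}" for c in ("wt", "ko") for r in range(1, n + 1)]
    return {name: str(path) for name, path in zip(names, files["sam"])}


@pytest.fixture(scope="session")
def condition_map(rnaseq_samples):
    return {n: ("ko" if n.startswith("ko") else "wt") for n in rnaseq_samples}


@pytest.fixture(scope="session")
def tested_events(rnaseq_samples, annotation, genome, condition_map):
    junctions = merge_junctions(
        {n: extract_junctions(p) for n, p in rnaseq_samples.items()}, annotation
    )
    events = discover_events(junctions, annotation, genome, samples=rnaseq_samples)
    return test_differential(events, condition_map), junctions
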