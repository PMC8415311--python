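"""Shared fixtures: tiny hand-built genomes and a small simulated genome."""

import numpy as np
import pytest

from retrocall import SimConfig, simulate_genome
from retrocall.homology_search import AlignmentHit


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated genome with planted events of every class."""
    cfg = SimConfig(
        seed=5,
        n_chromosomes=1,
        chrom_length=150_000,
        n_genes=15,
        n_retrocopies=6,
        n_dna_duplication_decoys=2,
    )
    genome, genes, truth = simulate_genome(cfg)
    return cfg, genome, genes, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_hit(
    query_id="gX",
    chrom="chr1",
    g_start=0,
    g_end=300,
    strand="+",
    q_start=0,
    q_end=100,
    identity=95.0,
    score=200,
    q_len=100,
    blocks=None,
):
    if blocks is None:
        blocks = [((q_start, q_end), (g_start, g_end))]
    return AlignmentHit(
        query_id=query_id,
        chrom=chrom,
        g_start=g_start,
        g_end=g_end,
        strand=strand,
        q_start=q_start,
        q_end=q_end,
        identity=identity,
        aligned_columns=q_end - q_start,
        score=score,
        q_len=q_len,
        blocks=blocks,
    )


def write_toy_gff(path, body):
    path.write_text("##gff-version 3\n" + body)
    return path
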