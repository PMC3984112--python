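"""Shared fixtures: tiny deterministic genomes and hand-built gene models."""

from __future__ import annotations

import numpy as np
import pytest

from gfuse.align import Read
from gfuse.genome_model import GeneModel, Genome

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(BASES[rng.integers(0, 4, n, dtype=np.uint8)]).decode()


def make_gene(symbol: str, chrom: str, strand: str,
              exons: list[tuple[int, int]],
              cds: tuple[int, int] | None = None,
              name: str | None = None) -> GeneModel:
    return GeneModel(
        name=name or f"NM_{symbol}", symbol=symbol, chrom=chrom, strand=strand,
        tx_start=exons[0][0], tx_end=exons[-1][1],
        cds_start=cds[0] if cds else None, cds_end=cds[1] if cds else None,
        exons=exons,
    )


def make_read(seq: str, rid: str = "r1", q: int = 35) -> Read:
    return Read(rid, seq, np.full(len(seq), q, dtype=np.uint8))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def tiny_genome() -> Genome:
    """Two ~10 kb chromosomes of fixed random sequence."""
    r = np.random.default_rng(11)
    return Genome({"chr1": random_seq(r, 10_000), "chr2": random_seq(r, 8_000)})
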