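"""Shared fixtures: tiny references, simulated experiments, and records."""

from __future__ import annotations

import numpy as np
import pytest

from rapidseq.index import IndexParams, build_index
from rapidseq.mapper import Read
from rapidseq.reference import ReferenceGenome


def make_seq(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=n))


def make_read(seq: str, name: str = "r", q: int = 30) -> Read:
    return Read(name, seq, np.full(len(seq), q, dtype=np.uint8))


@pytest.fixture(scope="session")
def toy_ref() -> ReferenceGenome:
    """2-kb single-contig random reference (21-mers effectively unique)."""
    return ReferenceGenome({"chr1": make_seq(2000, seed=1)})


@pytest.fixture(scope="session")
def toy_index(toy_ref):
    return build_index(toy_ref, IndexParams())


@pytest.fixture(scope="session")
def small_params() -> IndexParams:
    """Seeding parameters scaled for tiny test references."""
    return IndexParams(primary_seed_len=5, max_hits=3, max_ext_per_side=6,
                       ext_increment=2, seed_stride=2)
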