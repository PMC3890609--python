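from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from gliascan.cluster import Dereplicate
from gliascan.demux import TrimmedFragment
from gliascan.reference import (
    load_epitope_catalog,
    load_expression_profiles,
    load_subgenome_motifs,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return load_epitope_catalog()


@pytest.fixture(scope="session")
def motif_table():
    return load_subgenome_motifs()


@pytest.fixture(scope="session")
def profile_table():
    return load_expression_profiles()


def make_fragments(nt: str, count: int, sample: str = "S1") -> list[TrimmedFragment]:
    """count identical trimmed fragments for one sample."""
    return [TrimmedFragment(f"{sample}_{nt[:4]}_{i}", sample, nt, True) for i in range(count)]


def derep(nt: str, **sample_counts: int) -> Dereplicate:
    return Dereplicate(nt, dict(sample_counts))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
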