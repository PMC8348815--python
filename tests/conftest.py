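import numpy as np
import pytest

from tdnarray.detection import PipelineConfig, ReferenceCatalog
from tdnarray.records import SeqRecord


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, sub=0.04, ins=0.03, dele=0.04) -> str:
    """ONT-like i.i.d. corruption of a sequence."""
    out = []
    for ch in seq:
        r = rng.random()
        if r < dele:
            continue
        out.append(
            "ACGT"[(("ACGT".index(ch)) + int(rng.integers(1, 4))) % 4]
            if dele <= r < dele + sub
            else ch
        )
        if rng.random() < ins:
            out.append("ACGT"[int(rng.integers(0, 4))])
    return "".join(out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mini_catalog(rng):
    """A small catalog: one 20 kbp chromosome, 4 kbp T-DNA, 1.5 kbp BVB,
    3 kbp plastome."""
    records = [
        SeqRecord("chrA", random_seq(rng, 20_000), "nuclear"),
        SeqRecord("plastome", random_seq(rng, 3_000), "plastid"),
        SeqRecord("tdna", random_seq(rng, 4_000), "T-DNA"),
        SeqRecord("bvb", random_seq(rng, 1_500), "backbone"),
    ]
    return ReferenceCatalog(
        records,
        {
            "chrA": "NUCLEAR",
            "plastome": "PLASTOME",
            "tdna": "TDNA",
            "bvb": "BVB",
        },
    )


@pytest.fixture()
def config():
    return PipelineConfig()
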