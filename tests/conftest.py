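from __future__ import annotations

import random
from importlib import resources
from pathlib import Path

import pytest

from cnvrmap.io import read_cnvr_breeds, read_cnvrs
from cnvrmap.model import CnvCall, GenomicInterval


def fixture_table_path() -> Path:
    return Path(resources.files("cnvrmap.data") / "f0_unique_cnvrs.tsv")


@pytest.fixture(scope="session")
def f0_unique_table_path() -> Path:
    """The 60-row published F0-unique CNVR table shipped as package data."""
    return fixture_table_path()


@pytest.fixture(scope="session")
def f0_unique_cnvrs(f0_unique_table_path):
    return read_cnvrs(f0_unique_table_path)


@pytest.fixture(scope="session")
def f0_unique_breeds(f0_unique_table_path):
    return read_cnvr_breeds(f0_unique_table_path)


def make_call(
    sample="S1",
    algorithm="gada",
    chrom="1",
    start=100,
    end=200,
    state="gain",
    n_snps=5,
) -> CnvCall:
    return CnvCall(sample, algorithm, GenomicInterval(chrom, start, end), state, n_snps)


def random_calls(
    rng: random.Random,
    n: int,
    algorithm="gada",
    n_samples=10,
    chrom_size=10_000,
    n_chroms=2,
    max_len=400,
):
    """Small-coordinate random call sets sized for per-base-mask oracles."""
    calls = []
    for _ in range(n):
        chrom = str(rng.randint(1, n_chroms))
        start = rng.randint(1, chrom_size - max_len)
        end = start + rng.randint(0, max_len - 1)
        calls.append(
            CnvCall(
                sample_id=f"S{rng.randint(1, n_samples)}",
                algorithm_id=algorithm,
                interval=GenomicInterval(chrom, start, end),
                state=rng.choice(["gain", "loss"]),
                n_snps=rng.randint(1, 12),
            )
        )
    return calls
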