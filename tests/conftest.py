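from __future__ import annotations

import numpy as np
import pytest

from proberemap.io import load_config
from proberemap.models import AlignmentPolicy, ProbeRecord, ReferenceDB
from proberemap.pipeline import run_pipeline
from proberemap.synthetic import FixtureSpec, generate_fixture


def make_db(sequences: dict[str, str], name: str = "db", rank: int = 1,
            db_type: str = "transcript",
            policy: AlignmentPolicy | None = None,
            symbols: dict[str, str] | None = None) -> ReferenceDB:
    if policy is None:
        policy = AlignmentPolicy(2, db_type == "genomic")
    return ReferenceDB(name, rank, db_type, sequences, policy, symbols or {})


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def probe(seq: str, pid: str = "p1", psid: str = "ps1") -> ProbeRecord:
    return ProbeRecord(pid, psid, seq)


SMALL_SPEC = FixtureSpec(seed=11, n_probesets=24, chromosome_length=55_000)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact mixed platform shared by the integration tests."""
    out = tmp_path_factory.mktemp("fixture") / "small"
    return generate_fixture(SMALL_SPEC, out)


@pytest.fixture(scope="session")
def small_run(small_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("run") / "out"
    cfg = load_config(small_fixture.config_path)
    result = run_pipeline(cfg, out_dir=out)
    return small_fixture, result, out
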