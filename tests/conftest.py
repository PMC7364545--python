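"""Shared fixtures: toy germline DB, engineered filter reads, small repertoires.

Everything is generated programmatically and deterministically; expensive
artifacts (simulated repertoires, pipeline runs) are session-scoped so the
suite pays for them once.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from vdjflow import (
    FilterConfig,
    SimParams,
    load_toy_db,
    make_filter_fixture,
    simulate_repertoire,
)
from vdjflow.engine import RunConfig, run
from vdjflow.fastx_io import write_fastx


@pytest.fixture(scope="session")
def toy_db():
    return load_toy_db()


@pytest.fixture(scope="session")
def filter_reads(toy_db):
    """The six engineered reads plus their expected failure reasons."""
    return make_filter_fixture(toy_db)


@pytest.fixture(scope="session")
def filter_fastq(filter_reads, tmp_path_factory) -> Path:
    reads, _expected = filter_reads
    path = tmp_path_factory.mktemp("fixture") / "filter_fixture.fastq"
    write_fastx(reads, path, "fastq")
    return path


@pytest.fixture(scope="session")
def clean_sim(toy_db, tmp_path_factory):
    """200 mutation-free reads: exact germline recombinants with truth."""
    out = tmp_path_factory.mktemp("sim_clean")
    params = SimParams(
        n_reads=200, mutation_rate=0.0, error_rate=0.0, seed=101
    )
    fastq, truth = simulate_repertoire(toy_db, params, out / "clean.fastq")
    return fastq, truth, params


@pytest.fixture(scope="session")
def mutated_sim(toy_db, tmp_path_factory):
    """300 reads at the standard simulation conditions (2% SHM, 0.5% error)."""
    out = tmp_path_factory.mktemp("sim_mut")
    params = SimParams(n_reads=300, mutation_rate=0.02, error_rate=0.005, seed=202)
    fastq, truth = simulate_repertoire(toy_db, params, out / "mut.fastq")
    return fastq, truth, params


@pytest.fixture(scope="session")
def mutated_run(mutated_sim, tmp_path_factory):
    """A full default-options pipeline run over the 300-read repertoire."""
    fastq, truth, _params = mutated_sim
    out_dir = tmp_path_factory.mktemp("run_mut")
    out = out_dir / "out.airr.json.gz"
    _path, stats, records = run(
        RunConfig(input_path=fastq, out_path=out), collect=True
    )
    return fastq, truth, out, stats, records
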