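"""Shared fixtures: one session-scoped synthetic source plus its two star loads."""

from __future__ import annotations

import sqlite3
from pathlib import Path

import pytest

from txstar import pipeline, star, synth
from txstar.eav import InstanceMode


@pytest.fixture(scope="session")
def workdir(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("etl")


@pytest.fixture(scope="session")
def default_config() -> synth.GeneratorConfig:
    """The default study conditions: 200 patients, ~50k value cells."""
    return synth.GeneratorConfig()


@pytest.fixture(scope="session")
def source(workdir, default_config):
    """(path, truth) of the default generated source database."""
    path, truth = synth.generate(default_config, workdir / "source.db")
    return path, truth


@pytest.fixture(scope="session")
def source_conn(source):
    conn = sqlite3.connect(str(source[0]))
    yield conn
    conn.close()


@pytest.fixture(scope="session")
def schema_config() -> dict:
    return synth.default_schema_config()


def _etl(source_path, workdir, schema_config, mode: InstanceMode, name: str):
    target = workdir / name
    report = pipeline.run_etl(
        pipeline.RunConfig(
            source=source_path,
            schema=schema_config,
            target=target,
            instance_mode=mode,
        )
    )
    return target, report


@pytest.fixture(scope="session")
def etl_grouped(source, workdir, schema_config):
    """(star path, run report) for the default GROUPED-mode load."""
    return _etl(source[0], workdir, schema_config, InstanceMode.GROUPED, "star_grouped.db")


@pytest.fixture(scope="session")
def etl_idrt(source, workdir, schema_config):
    """(star path, run report) for the legacy incrementing-instance load."""
    return _etl(source[0], workdir, schema_config, InstanceMode.IDRT_COMPAT, "star_idrt.db")


@pytest.fixture()
def star_grouped(etl_grouped):
    path, _ = etl_grouped
    db = star.StarDatabase(path=path, conn=sqlite3.connect(str(path)),
                           instance_mode=InstanceMode.GROUPED)
    yield db
    db.close()


@pytest.fixture()
def star_idrt(etl_idrt):
    path, _ = etl_idrt
    db = star.StarDatabase(path=path, conn=sqlite3.connect(str(path)),
                           instance_mode=InstanceMode.IDRT_COMPAT)
    yield db
    db.close()
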