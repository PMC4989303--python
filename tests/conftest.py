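"""Shared fixtures: pipeline runs are expensive, so the three study
configurations are built once per session and reused read-only."""
from __future__ import annotations

import pytest

from befpipe.pipeline import RunConfig, run


@pytest.fixture(scope="session")
def paper_run():
    """Full pipeline on the canonical 93-microcosm configuration."""
    return run(RunConfig(scenario="paper_default", seed=1, sensitivity=True))


@pytest.fixture(scope="session")
def neutral_run():
    """Pipeline on the no-interaction null control."""
    return run(RunConfig(scenario="neutral", seed=1, sensitivity=False))


@pytest.fixture(scope="session")
def tiny_run():
    """Fast 4-isolate configuration for smoke checks."""
    return run(RunConfig(scenario="tiny", seed=1, sensitivity=True))
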