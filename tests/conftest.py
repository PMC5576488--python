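"""Shared fixtures: one small and one full-scale synthetic session.

The full session/pipeline run is session-scoped because several
acceptance criteria evaluate different aspects of the same default
configuration run.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from swrpipe.config import load_config
from swrpipe.pipeline import run_pipeline
from swrpipe.synth import GeneratorConfig, generate_session

FULL_SEED = 11


def small_generator_config(**overrides) -> GeneratorConfig:
    """A fast-to-generate session config for unit/CLI tests."""
    base = dict(
        session_length_s=240.0,
        n_map=6,
        n_iap=4,
        n_interneuron=1,
        n_pfc=8,
        pfc_group_counts={"IAP-locked": 2, "MAP-locked": 2, "inhibited": 2, "flat": 2},
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_session():
    return generate_session(small_generator_config(), 5)


@pytest.fixture(scope="session")
def full_run():
    """Default-configuration session plus a complete pipeline run."""
    t0 = time.monotonic()
    session, truth = generate_session(GeneratorConfig(), FULL_SEED)
    gen_elapsed = time.monotonic() - t0
    cfg = load_config(None)
    t1 = time.monotonic()
    report = run_pipeline(session, cfg, seed=FULL_SEED)
    pipeline_elapsed = time.monotonic() - t1
    return {
        "session": session,
        "truth": truth,
        "config": cfg,
        "report": report,
        "gen_elapsed_s": gen_elapsed,
        "pipeline_elapsed_s": pipeline_elapsed,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
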