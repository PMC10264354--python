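"""Shared fixtures: scaled-down synthetic sessions.

Test sessions use shorter blocks and fewer vibrations than the full
protocol so the suite stays fast; effect parameters are the generator
defaults unless a test overrides them.
"""

from __future__ import annotations

import numpy as np
import pytest

from gutwave.synth import EffectParams, ResponderParams, SessionConfig, simulate_session


def scaled_config(seed: int = 7, **overrides) -> SessionConfig:
    kw = dict(
        block_plan=[("baseline", 320.0), ("normal", 240.0), ("enhanced", 240.0)],
        n_stims={"normal": 12, "enhanced": 12},
        seed=seed,
    )
    kw.update(overrides)
    return SessionConfig(**kw)


@pytest.fixture(scope="session")
def session():
    """One scaled multi-channel session shared across read-only tests."""
    cfg = scaled_config(seed=7)
    rec, events, presses, gt = simulate_session(cfg)
    return {"cfg": cfg, "rec": rec, "events": events, "presses": presses, "gt": gt}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
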