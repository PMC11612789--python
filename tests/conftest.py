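"""Shared fixtures: synthetic datasets generated at test time."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

import shrewvoc as sv

SR = 200_000


@pytest.fixture(scope="session")
def pipeline600():
    """Full pipeline run on the default 600-call synthetic campaign.

    Session-scoped: the end-to-end repertoire recovery checks all read from
    this single seeded run.
    """
    cfg = sv.PipelineConfig(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sv.run_pipeline(cfg)


@pytest.fixture(scope="session")
def calls200():
    """200 randomized synthetic calls (waveform, spec, truth) across the
    four call types, synthesized standalone for feature-accuracy checks."""
    from shrewvoc.synth import _randomized_spec, ExperimentConfig

    rng = np.random.default_rng(42)
    cfg = ExperimentConfig()
    counts = {"scream": 60, "screech": 60, "screech_scream": 40, "chirp": 40}
    out = []
    for ctype, n in counts.items():
        for _ in range(n):
            spec = _randomized_spec(ctype, "adult", cfg, rng)
            wave = sv.synth_call(spec, SR, rng)
            out.append((spec, wave))
    return out


@pytest.fixture()
def tone():
    """Clean 20 kHz sine, 0.1 s at 200 kHz."""
    t = np.arange(int(0.1 * SR)) / SR
    return np.sin(2 * np.pi * 20_000.0 * t)


@pytest.fixture()
def white_noise():
    rng = np.random.default_rng(7)
    return 0.3 * rng.standard_normal(int(0.1 * SR))
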