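"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import squeezecall as sq


# ---------------------------------------------------------------------------
# independent CTC oracle: brute-force path enumeration

def collapse_path(path, blank: int = 4) -> tuple:
    """Collapse a frame-level path: merge repeats, drop blanks."""
    out, prev = [], -1
    for c in path:
        if c != blank and c != prev:
            out.append(c)
        prev = c
    return tuple(out)


def brute_force_ctc_loglik(logp: np.ndarray, label: str) -> float:
    """Sum P over every frame string that collapses to the label (T <= ~7)."""
    ids = tuple("ACGT".index(b) for b in label)
    T, K = logp.shape
    total = -np.inf
    for path in itertools.product(range(K), repeat=T):
        if collapse_path(path) == ids:
            total = np.logaddexp(total, sum(logp[t, c] for t, c in enumerate(path)))
    return float(total)


def random_posteriorgram(rng: np.random.Generator, T: int, K: int = 5) -> np.ndarray:
    logits = rng.normal(size=(T, K))
    return logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def tiny_config() -> sq.EncoderConfig:
    return sq.EncoderConfig.preset("tiny")


@pytest.fixture(scope="session")
def tiny_model(tiny_config) -> sq.SqueezeCallModel:
    return sq.SqueezeCallModel(tiny_config, seed=1234)


@pytest.fixture(scope="session")
def clean_pore_model() -> sq.PoreModel:
    return sq.make_pore_model(k=1, seed=7, noise_sd=0.1, dwell_min=5, dwell_max=10)


@pytest.fixture(scope="session")
def small_dataset(clean_pore_model) -> sq.SquiggleDataset:
    return sq.make_dataset(6, 300, clean_pore_model, seed=21)
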