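"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gvhd_gmb as g

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=150,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def pair_enumeration_auc(scores, labels) -> float:
    """Brute-force Mann–Whitney AUC: enumerate every case-control pair."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def planted_cohort():
    """Planted-signal cohort: 30 informative genes at log2FC=2, n=160."""
    cfg = g.SyntheticConfig(
        n_samples=160, n_genes=1408, n_informative=30, effect_log2fc=2.0, seed=1
    )
    return g.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort for pipeline-level tests."""
    cfg = g.SyntheticConfig(
        n_samples=90, n_genes=300, n_informative=20, effect_log2fc=2.0, seed=7
    )
    return g.generate_cohort(cfg)


@pytest.fixture(scope="session")
def fast_selection():
    """Selection config with fewer resamples for pipeline-level tests."""
    return g.SelectionConfig(n_resamples=25, seed=0)
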