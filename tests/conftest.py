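"""Shared fixtures.

The expensive trained models are session-scoped and shared across the
classifier, interpretability, pipeline, and acceptance tests; everything
else is generated per test at small scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from decent import benchmark, simgen


@pytest.fixture(scope="session")
def small_genome():
    cfg = simgen.default_genome_config(n_autosomes=4, autosome_length=500_000, seed=101)
    return simgen.generate_genome(cfg)


@pytest.fixture(scope="session")
def default_profiles(small_genome):
    return benchmark.benchmark_profiles(small_genome, separable=False, seed=102)


@pytest.fixture(scope="session")
def bench(small_genome, default_profiles):
    """Default (overlapping-class) benchmark classifier plus held-out data."""
    clf, genome, profiles = benchmark.train_benchmark_classifier(
        seed=11,
        n_per_class=6_000,
        separable=False,
        epochs=8,
        genome=small_genome,
        profiles=default_profiles,
    )
    X_hold, y_hold = benchmark.training_data(small_genome, default_profiles, 3_000, seed=991)
    return {
        "clf": clf,
        "genome": genome,
        "profiles": profiles,
        "X_holdout": X_hold,
        "y_holdout": y_hold,
    }


@pytest.fixture(scope="session")
def e2e():
    """Separable-benchmark model on a 22-autosome genome, for the
    contaminated-aneuploidy reconstruction scenario."""
    genome = benchmark.benchmark_genome(seed=1, n_autosomes=22)
    profiles = benchmark.benchmark_profiles(genome, separable=True, seed=2)
    clf, _, _ = benchmark.train_benchmark_classifier(
        seed=1, n_per_class=8_000, separable=True, epochs=8, genome=genome, profiles=profiles
    )
    return {"clf": clf, "genome": genome, "profiles": profiles}
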