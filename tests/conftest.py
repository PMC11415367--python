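"""Shared fixtures: transcripts and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import cave
from cave.simulate import SimulationConfig, make_transcript


@pytest.fixture(scope="session")
def gene_model():
    """Default TP53-sized synthetic transcript (394 codons, 6 exons)."""
    return make_transcript()


@pytest.fixture(scope="session")
def toy_model():
    """Small 30-codon, 2-exon transcript for exhaustive checks."""
    return make_transcript(seed=11, n_codons=30, n_exons=2, intron_len=50)


def simulate_study(config: SimulationConfig, model=None):
    """Run repository + cohort generation with one seeded stream."""
    if model is None:
        model = make_transcript()
    rng = np.random.default_rng(config.seed)
    fmap, csd, labels = cave.simulate_repository(config, model, rng)
    callset, truth = cave.simulate_cohort(config, model, fmap, rng)
    return model, fmap, csd, labels, callset, truth


@pytest.fixture(scope="session")
def small_study(gene_model):
    """A fast 12-sample cohort with drivers, shared across read-only tests."""
    cfg = SimulationConfig(
        n_samples=12, noise_calls_per_sample=200.0, drivers_per_sample_mean=2.0, seed=42
    )
    return simulate_study(cfg, gene_model)
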