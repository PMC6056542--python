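from __future__ import annotations

import numpy as np
import pytest

from sigiscan import (
    DEFAULT_GENERATORS,
    MotifSpec,
    SyntheticSpec,
    build_profile,
    sample_promoter_set,
    simulate,
    stack_promoters,
)


@pytest.fixture(scope="session")
def motif_spec() -> MotifSpec:
    return MotifSpec()


@pytest.fixture(scope="session")
def small_benchmark():
    """A 60 kb planted benchmark shared by the slower integration tests."""
    sspec = SyntheticSpec(seed=11, genome_length=60_000)
    genome, annotations, truth = simulate(sspec)
    return sspec, genome, annotations, truth


@pytest.fixture(scope="session")
def default_profiles(motif_spec):
    """Per-sigma profiles rebuilt from 50 sampled promoters each."""
    rng = np.random.default_rng(2024)
    profiles = {}
    rules = {}
    for label, gen in DEFAULT_GENERATORS.items():
        pset = sample_promoter_set(gen, 50, rng, motif_spec)
        profiles[label] = build_profile(stack_promoters(pset, motif_spec), pseudocount=0.5)
        rules[label] = gen.rule()
    return profiles, rules


@pytest.fixture(scope="session")
def sig3_profile(motif_spec):
    """sigma-I3 profile rebuilt from 50 sampled promoters (pseudocount 0.01)."""
    pset = sample_promoter_set(DEFAULT_GENERATORS["sigI3"], 50, 23, motif_spec)
    return build_profile(stack_promoters(pset, motif_spec), pseudocount=0.01)


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    at = (1 - gc) / 2
    return "".join(rng.choice(list("ACGT"), size=length, p=[at, gc / 2, gc / 2, at]))
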