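"""Shared fixtures and independent oracles for the test suite."""

from itertools import product

import pytest
from hypothesis import settings

from breederinvest import ModelParams, SpeciesRecord

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


def make_record(s: float, n: float, name: str = "sp", taxon: str = "fish",
                brood=None) -> SpeciesRecord:
    """A species whose relative quality is exactly ``s`` (breeder mass 1)."""
    return SpeciesRecord(
        name=name, taxon_group=taxon, n_offspring=n,
        offspring_mass=s, breeder_mass=1.0, brood_masses=brood,
    )


def gini_pairwise(masses) -> float:
    """Brute-force mean-absolute-difference Gini over all ordered pairs.

    G = sum_{i,j} |m_i - m_j| / (2 N (N-1) mu); the independent oracle for
    the package's sorted-weights and rank-form implementations.
    """
    n = len(masses)
    mu = sum(masses) / n
    total = sum(abs(a - b) for a in masses for b in masses)
    return total / (2 * n * (n - 1) * mu)


def exact_replacement_probability(masses, p_level, threshold, w=2.0) -> float:
    """Exhaustive enumeration of replacement probability for a fixed brood.

    Enumerates all 2^n predation outcomes (each offspring survives with
    probability 1 - p_level); survivors must also clear the scarcity mass
    threshold; the brood replaces if at least w survive both.  Exact, so it
    anchors the Monte-Carlo harness for small broods.
    """
    n = len(masses)
    prob_replaced = 0.0
    for outcome in product((0, 1), repeat=n):
        prob = 1.0
        survivors = 0
        for alive, mass in zip(outcome, masses):
            prob *= (1.0 - p_level) if alive else p_level
            if alive and mass >= threshold:
                survivors += 1
        if survivors >= w:
            prob_replaced += prob
    return prob_replaced
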