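"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import itertools
import math

import pytest

from compactmix import CompactibilityProfile, Composition, GeneratorSpec, MaterialTruth


def enumerate_sequences_predict(n, volume_fractions, strengths):
    """Brute-force oracle for the interaction model.

    Enumerates all m^n ordered particle sequences; each has probability
    prod(V) and strength equal to the geometric mean of its particles'
    strengths. The closed-form cluster aggregation must match this sum.
    Exponential in n — test use only.
    """
    m = len(volume_fractions)
    total = 0.0
    for seq in itertools.product(range(m), repeat=n):
        prob = 1.0
        log_s = 0.0
        zero = False
        for j in seq:
            prob *= volume_fractions[j]
            if strengths[j] == 0.0:
                zero = True
            else:
                log_s += math.log(strengths[j])
        strength = 0.0 if zero else math.exp(log_s / n)
        total += prob * strength
    return total


def power_mean_predict(n, volume_fractions, strengths):
    """Closed-form identity: the order-n model is the power mean of order 1/n.

    (sum_j V_j sigma_j^(1/n))^n, by the multinomial theorem.
    """
    return sum(v * s ** (1.0 / n) for v, s in zip(volume_fractions, strengths)) ** n


@pytest.fixture
def binary_50_50():
    return Composition(components=(("A", 0.5), ("B", 0.5)))


@pytest.fixture
def default_spec():
    return GeneratorSpec(seed=42)


@pytest.fixture
def noiseless_spec():
    return GeneratorSpec(strength_noise_sd=0.0, seed=42)


@pytest.fixture
def strong_weak_profiles():
    """Profiles matching the default generator truth (strong/weak pair)."""
    return [
        CompactibilityProfile(material_id="strong", sigma0=10.0, k=8.0),
        CompactibilityProfile(material_id="weak", sigma0=1.0, k=9.0),
    ]


@pytest.fixture
def strong_weak_materials():
    return {
        "strong": MaterialTruth(sigma0=10.0, k=8.0, true_density=1.5),
        "weak": MaterialTruth(sigma0=1.0, k=9.0, true_density=1.6),
    }
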