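"""Shared fixtures: synthetic families and adapter stubs.

Families are session-scoped because generating one involves repeated
alignment-based distance measurement.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from codonscout.synth import FamilySpec, make_family, make_mock_backend

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def family():
    """Default 8-homolog family, divergences 12..40 %, seed 7."""
    return make_family(FamilySpec(seed=7))


@pytest.fixture(scope="session")
def backend(family):
    return make_mock_backend(family.homologs, family.metadata)


@pytest.fixture(scope="session")
def metadata(family):
    return family.metadata_lookup()


@pytest.fixture(scope="session")
def coding_family():
    """Family whose root embeds a stop-free 54-codon ORF at position 90."""
    return make_family(
        FamilySpec(
            root_length=600,
            n_homologs=4,
            target_distances=(12, 18, 24, 30),
            seed=11,
            coding=(90, 54),
        )
    )
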