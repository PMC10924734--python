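"""Shared fixtures: small deterministic geometries and short solver runs."""

import numpy as np
import pytest

import spinecable as sc
from spinecable.protocols import MorphologySpec, fixture_generator, reference_spine


@pytest.fixture(scope="session")
def species():
    return sc.default_species()


@pytest.fixture(scope="session")
def ref_geom():
    morph, _ = reference_spine()
    return morph.to_geometry()


@pytest.fixture(scope="session")
def tiny():
    """3/3/2-segment spine with a sub-microsecond rest protocol."""
    morph, protocol, settings = fixture_generator("tiny")
    return morph.to_geometry(), protocol, settings


@pytest.fixture(scope="session")
def small_inject_traj(species):
    """3/3/2-segment spine, 25 pA for 5 us (fast, deterministic)."""
    morph, protocol, settings = fixture_generator("small")
    return sc.run(morph.to_geometry(), species, protocol, settings)


@pytest.fixture(scope="session")
def short_ref_traj(ref_geom, species):
    """Reference morphology, 25 pA for 1 ms (concentration build-up visible)."""
    return sc.run(
        ref_geom,
        species,
        sc.step_protocol(25e-12, 1e-3),
        sc.SolverSettings(dt=0.5e-9, record_stride=2000),
    )
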