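"""Shared fixtures: synthetic structures and cached clearance fields.

Clearance-field construction dominates test runtime, so fields for the
standard fixtures are built once per session and shared read-only.
"""

from __future__ import annotations

import pytest

from channelpore.accessibility import build_clearance_field, default_seed, default_target
from channelpore.synthetic_structures import (
    closed_spec,
    cylinder_spec,
    hourglass_spec,
    make_fixture,
)


@pytest.fixture(scope="session")
def cyl65():
    """Cylinder fixture with exact 6.5 Å analytic bottleneck."""
    return make_fixture(cylinder_spec(6.5))


@pytest.fixture(scope="session")
def cyl20():
    """Small cylinder fixture (2.0 Å bottleneck) for fast end-to-end runs."""
    return make_fixture(cylinder_spec(2.0))


@pytest.fixture(scope="session")
def hourglass():
    return make_fixture(hourglass_spec())


@pytest.fixture(scope="session")
def closed():
    return make_fixture(closed_spec())


def _field_bundle(fixture):
    field = build_clearance_field(fixture.structure, fixture.grid)
    return {
        "fixture": fixture,
        "field": field,
        "seed": default_seed(field),
        "target": default_target(fixture.anchor_z),
    }


@pytest.fixture(scope="session")
def cyl65_bundle(cyl65):
    return _field_bundle(cyl65)


@pytest.fixture(scope="session")
def cyl20_bundle(cyl20):
    return _field_bundle(cyl20)


@pytest.fixture(scope="session")
def hourglass_bundle(hourglass):
    return _field_bundle(hourglass)


@pytest.fixture(scope="session")
def closed_bundle(closed):
    return _field_bundle(closed)
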