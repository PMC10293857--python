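"""Shared fixtures.

The expensive fixtures (self-assembled bursters, the ensemble) are
session-scoped so the acceptance-style tests share one set of simulations.
"""

from __future__ import annotations

import numpy as np
import pytest

from homeoburst import Model
from homeoburst.experiments import make_bursters


@pytest.fixture(scope="session")
def model():
    return Model()


@pytest.fixture(scope="session")
def bursters3(model):
    """Three self-assembled bursters for perturbation batteries."""
    return make_bursters(model, 3, seed=77)


@pytest.fixture(scope="session")
def burster(bursters3):
    """One self-assembled periodic burster (gated mode)."""
    return bursters3[0]
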