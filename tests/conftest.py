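"""Shared fixtures: tiny reaction systems with known closed-form answers."""

import numpy as np
import pytest

from episwitch import ReactionSystem


@pytest.fixture
def decay_system():
    """Single-species decay A -> 0 at rate 1/h; absorbing at extinction."""
    return ReactionSystem(
        species_labels=["A"],
        propensities=lambda s: np.array([1.0 * s[0]]),
        stoichiometry=np.array([[-1]]),
        absorbing=lambda s: s[0] == 0,
        reaction_labels=["decay"],
    )


@pytest.fixture
def telegraph_system():
    """M -> U at rate 0.25/h, absorbing at U: MFPT = 4 h."""
    return ReactionSystem(
        species_labels=["M"],
        propensities=lambda s: np.array([0.25 * s[0]]),
        stoichiometry=np.array([[-1]]),
        absorbing=lambda s: s[0] == 0,
    )


@pytest.fixture
def frozen_system():
    """All propensities zero, no scheduled events."""
    return ReactionSystem(
        species_labels=["A"],
        propensities=lambda s: np.array([0.0]),
        stoichiometry=np.array([[1]]),
        absorbing=lambda s: False,
    )
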