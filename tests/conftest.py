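"""Shared fixtures: the standard two-state toy crystal and derived datasets.

The standard fixture is a 12-atom orthogonal P1 cell (24 x 26 x 22 A) with
three atoms displaced by 1.1 A in the light state, sampled to 1.8 A --
small enough that every stage runs in seconds, rich enough that Patterson
and difference-density features are well resolved.
"""

import numpy as np
import pytest

from trxmap.reflections import _orth_matrix
from trxmap.synthetic import (
    displaced_indices,
    intensities_from_amplitudes,
    make_toy_crystal,
    mix_states,
    structure_factors,
)

STANDARD_SEED = 7
STANDARD_D_MIN = 1.8


@pytest.fixture(scope="session")
def toy_crystal():
    return make_toy_crystal(seed=STANDARD_SEED, n_atoms=12, displacement=1.1,
                            n_displaced=3)


@pytest.fixture(scope="session")
def f_dark(toy_crystal):
    return structure_factors(toy_crystal.atoms_dark, toy_crystal.cell,
                             toy_crystal.spacegroup, STANDARD_D_MIN)


@pytest.fixture(scope="session")
def f_light(toy_crystal):
    return structure_factors(toy_crystal.atoms_light, toy_crystal.cell,
                             toy_crystal.spacegroup, STANDARD_D_MIN)


@pytest.fixture(scope="session")
def i_dark(f_dark):
    return intensities_from_amplitudes(f_dark)


@pytest.fixture(scope="session")
def reporter_centers(toy_crystal):
    """Orthogonal-A dark positions of the displaced atoms -- the sites where
    negative difference density appears."""
    orth = _orth_matrix(toy_crystal.cell)
    idx = displaced_indices(toy_crystal)
    return np.array([orth @ toy_crystal.atoms_dark[i].frac_xyz for i in idx])


@pytest.fixture(scope="session")
def light_reporter_centers(toy_crystal):
    """Light-state positions of the displaced atoms -- where positive
    difference density builds up."""
    orth = _orth_matrix(toy_crystal.cell)
    idx = displaced_indices(toy_crystal)
    return np.array([orth @ toy_crystal.atoms_light[i].frac_xyz for i in idx])


@pytest.fixture(scope="session")
def mixed_light_factory(f_dark, f_light):
    """Amplitude set of a crystal with light fraction alpha (phases
    stripped, as measured data would be)."""

    def build(alpha):
        mixed = mix_states(f_dark, f_light, alpha)
        stripped = mixed.copy()
        stripped.phase = None
        return stripped

    return build
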