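"""Shared fixtures: registries, compositions, small synthetic systems."""

import numpy as np
import pytest

from curvsort import (
    Composition,
    CompositionEntry,
    MembraneFrame,
    SortingModel,
    make_buckle_profile,
    plasma_membrane_composition,
    sample_frame,
)
from curvsort.species import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def pm_composition():
    return plasma_membrane_composition()


@pytest.fixture(scope="session")
def small_composition():
    """Two-species membrane, 200 lipids per leaflet, for fast tests."""
    entries = (
        CompositionEntry(species="POPC", fraction=0.5, count=100),
        CompositionEntry(species="DIPE", fraction=0.5, count=100),
    )
    return Composition(leaflets={"outer": entries, "inner": entries})


@pytest.fixture(scope="session")
def profile_01():
    return make_buckle_profile(40.0, 0.1)


@pytest.fixture(scope="session")
def profile_03():
    return make_buckle_profile(40.0, 0.3)


def flat_bilayer_frame(n_per_leaflet=30, z_outer=12.0, z_inner=8.0,
                       Lx=40.0, species="POPC", rng=None):
    """Minimal flat bilayer of headgroup beads only."""
    rng = rng or np.random.default_rng(0)
    n = 2 * n_per_leaflet
    x = rng.uniform(0, Lx, n)
    y = rng.uniform(0, 20.0, n)
    z = np.concatenate([np.full(n_per_leaflet, z_outer),
                        np.full(n_per_leaflet, z_inner)])
    return MembraneFrame(
        box=(Lx, 20.0, 20.0),
        residue_id=np.arange(1, n + 1),
        species=np.full(n, species),
        bead_name=np.full(n, "PO4"),
        positions=np.stack([x, y, z], axis=1),
    )


@pytest.fixture()
def flat_frame():
    return flat_bilayer_frame()


@pytest.fixture(scope="session")
def buckled_frame(profile_03, pm_composition):
    """A single strongly buckled full-composition frame with ground truth."""
    frame, truth = sample_frame(profile_03, pm_composition, SortingModel(),
                                seed=11, headgroup_only=True)
    return frame, truth
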