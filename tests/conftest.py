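"""Shared fixtures: small bead complexes, ensembles and fast PB settings."""

import numpy as np
import pytest

from ppimutscan.energetics import PBSettings
from ppimutscan.ensemble_io import Structure
from ppimutscan.synthetic_data import (
    SyntheticTruth,
    make_ensemble,
    make_toy_complex,
    make_variant_suite,
)


@pytest.fixture(scope="session")
def fast_pb() -> PBSettings:
    """Coarse-grid PB settings for quick solvation in tests."""
    return PBSettings(grid_spacing=0.8)


@pytest.fixture(scope="session")
def toy_structure() -> "Structure":
    """10+10-residue two-chain complex with two planted interface contacts."""
    return make_toy_complex(10, 10, [(3, 3), (7, 7)], seed=11)


@pytest.fixture(scope="session")
def toy_ensemble(toy_structure):
    truth = SyntheticTruth(planted_contacts=[(3, 3), (7, 7)], jitter_sigma=0.25, seed=11)
    return make_ensemble(toy_structure, 20, truth, dt=200.0)


@pytest.fixture(scope="session")
def variant_suite():
    """Wild-type / contact-gain / charge-edit ensembles (6 frames, shared)."""
    return make_variant_suite(SyntheticTruth(seed=5), n_frames=6)


@pytest.fixture(scope="session")
def variant_suite_long():
    """Same suite at 40 frames for statistics that need tighter means."""
    return make_variant_suite(SyntheticTruth(seed=5), n_frames=40)


def two_chain_structure(positions_a, positions_b, charges=None, radius=1.7,
                        epsilon=0.3, sigma=3.0):
    """Hand-built fully parameterized two-chain structure (one atom per residue)."""
    pa = np.atleast_2d(positions_a)
    pb = np.atleast_2d(positions_b)
    n = len(pa) + len(pb)
    q = np.zeros(n) if charges is None else np.asarray(charges, float)
    return Structure(
        atom_ids=list(range(1, n + 1)),
        names=[f"X{i}" for i in range(n)],
        elements=["C"] * n,
        chain_ids=["A"] * len(pa) + ["B"] * len(pb),
        residue_numbers=list(range(1, len(pa) + 1)) + list(range(1, len(pb) + 1)),
        residue_names=["UNK"] * n,
        positions=np.vstack([pa, pb]),
        charges=q,
        vdw_radii=np.full(n, radius),
        lj_epsilons=np.full(n, epsilon),
        lj_sigmas=np.full(n, sigma),
    )


@pytest.fixture
def make_two_chain():
    return two_chain_structure
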