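"""Shared fixtures: random bead systems and small reference geometries."""

from __future__ import annotations

import numpy as np
import pytest

from allosnet.core import Atom, MolecularSystem, Residue, TrajectoryWindow


def make_bead_system(n_res: int, atoms_per_res: int = 1,
                     chain_id: str = "A") -> MolecularSystem:
    """n_res single-chain residues, each with a CA node atom plus
    (atoms_per_res − 1) heavy satellites."""
    residues = [Residue(chain_id=chain_id, res_id=i + 1, res_name="BEA",
                        node_index=i) for i in range(n_res)]
    atoms = []
    for i in range(n_res):
        atoms.append(Atom(residue_index=i, name="CA", element="C",
                          is_heavy=True, radius=1.7))
        for s in range(atoms_per_res - 1):
            atoms.append(Atom(residue_index=i, name=f"C{s + 1}",
                              element="C", is_heavy=True, radius=1.7))
    return MolecularSystem(residues, atoms)


def random_window(system: MolecularSystem, n_frames: int, rng,
                  box: float = 25.0, jitter: float = 0.8,
                  window_id: int = 0) -> TrajectoryWindow:
    """Random equilibrium positions in a box plus per-frame jitter, so
    some residue pairs sit near the contact cutoff and others far away."""
    n_atoms = system.n_atoms
    eq = rng.uniform(0.0, box, size=(n_atoms, 3))
    frames = eq[None, :, :] + jitter * rng.standard_normal(
        (n_frames, n_atoms, 3))
    return TrajectoryWindow(replica_id=0, window_id=window_id,
                            coords=frames)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ten_atom_cloud(rng):
    return 5.0 * rng.standard_normal((10, 3))
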