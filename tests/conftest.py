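import numpy as np
import pytest

from shiftcryst import synthetic as syn
from shiftcryst.ensemble import extract_environments
from shiftcryst.molecule import AtomSpec, build_graph


@pytest.fixture(scope="session")
def model_graph():
    graph, _template = syn.model_molecule()
    return graph


@pytest.fixture(scope="session")
def small_world():
    """A small planted-truth world shared by read-only tests."""
    cfg = syn.SynthConfig(n_runs=2, n_frames=3, n_molecules=40, seed=3)
    return syn.generate_ensemble(cfg)


@pytest.fixture(scope="session")
def small_envs(small_world):
    envs = []
    for run, frame in small_world.all_frames():
        envs.extend(extract_environments(frame, 7.0, run_id=run))
    return {e.env_id: e for e in envs}


@pytest.fixture()
def chain_graph():
    """Linear heavy chain C1-C2-C3-C4-C5 with one hydrogen on each carbon."""
    atoms = []
    bonds = []
    for i in range(1, 6):
        atoms.append(AtomSpec(f"C{i}", "C", assigned=True))
        atoms.append(AtomSpec(f"H{i}", "H", assigned=True))
        bonds.append((f"C{i}", f"H{i}"))
        if i > 1:
            bonds.append((f"C{i - 1}", f"C{i}"))
    return build_graph(atoms, bonds)


def random_molecule_frame(rng, n_molecules=5, box=20.0, max_atoms=4):
    """A random periodic frame of small compact 'molecules' (bonded chains).

    Atoms are wrapped into the box so unwrapping logic is exercised.
    """
    from shiftcryst.ensemble import Frame

    positions, elements, mol_ids = [], [], []
    for m in range(n_molecules):
        n = int(rng.integers(1, max_atoms + 1))
        start = rng.uniform(0, box, size=3)
        p = start
        for _ in range(n):
            positions.append(p % box)
            elements.append(rng.choice(["C", "N", "O", "H"]))
            mol_ids.append(m)
            step = rng.normal(size=3)
            step *= rng.uniform(0.9, 1.4) / np.linalg.norm(step)  # below the 1.8 Å heuristic
            p = p + step
    return Frame(
        lattice=np.eye(3) * box,
        positions=np.array(positions),
        elements=np.array(elements, dtype=object),
        mol_ids=np.array(mol_ids),
        frame_time=0.0,
    )
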