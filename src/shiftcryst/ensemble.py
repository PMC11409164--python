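"""Periodic snapshots and extraction of local molecular environments.

A snapshot is a periodic box of molecules identified by a per-atom molecule
index.  An environment is one central (solute) molecule plus every molecule
with at least one atom within a distance cutoff of it, all made whole and
brought to the central molecule's periodic image.

Frames are read and written as extended XYZ with a ``Lattice="..."`` header
and a per-atom molecule-id column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Frame",
    "MolecularEnvironment",
    "sample_frames",
    "extract_environments",
    "read_extxyz",
    "write_extxyz",
    "write_environments",
]

#: intramolecular bonding heuristic used to make molecules whole, Å
BOND_HEURISTIC = 1.8


class EnsembleError(ValueError):
    """Raised for malformed frames or invalid extraction parameters."""


@dataclass
class Frame:
    """One periodic snapshot."""

    lattice: np.ndarray          # (3, 3) cell vectors in Å, rows are vectors
    positions: np.ndarray        # (N, 3) Cartesian Å
    elements: np.ndarray         # (N,) element symbols
    mol_ids: np.ndarray          # (N,) integer molecule index
    frame_time: float = 0.0      # ps

    def __post_init__(self) -> None:
        self.lattice = np.asarray(self.lattice, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.elements = np.asarray(self.elements, dtype=object)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        n = len(self.positions)
        if not (len(self.elements) == len(self.mol_ids) == n):
            raise EnsembleError("positions, elements and mol_ids must have equal length")
        if abs(np.linalg.det(self.lattice)) < 1e-12:
            raise EnsembleError("lattice is singular")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def molecule_indices(self) -> dict[int, np.ndarray]:
        """Atom index arrays grouped by molecule id, in id order."""
        order = {}
        for mid in np.unique(self.mol_ids):
            order[int(mid)] = np.flatnonzero(self.mol_ids == mid)
        return order


@dataclass
class MolecularEnvironment:
    """A central molecule plus its neighbor molecules, unwrapped.

    Atom arrays cover the whole environment; the central molecule's atoms
    keep their intra-molecule order from the source frame, so coordinates
    can be matched to topology labels positionally.
    """

    env_id: str
    central_mol_id: int
    positions: np.ndarray        # (M, 3) Å, minimum-image relative to central
    elements: np.ndarray         # (M,)
    mol_ids: np.ndarray          # (M,)
    cutoff: float
    run_id: str = "run"

    @property
    def central_mask(self) -> np.ndarray:
        return self.mol_ids == self.central_mol_id

    @property
    def central_positions(self) -> np.ndarray:
        return self.positions[self.central_mask]

    @property
    def central_elements(self) -> np.ndarray:
        return self.elements[self.central_mask]

    @property
    def neighbor_mol_ids(self) -> list[int]:
        ids = [int(m) for m in np.unique(self.mol_ids) if m != self.central_mol_id]
        return ids

    def molecule_atoms(self, mol_id: int) -> np.ndarray:
        return np.flatnonzero(self.mol_ids == mol_id)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


def sample_frames(window_start: float, window_end: float, step: float) -> np.ndarray:
    """Evenly spaced frame times in ps, both endpoints included.

    The window length must be an integer multiple of ``step``; a
    non-divisible window is an error rather than a silent truncation.
    """
    if window_end < window_start:
        raise EnsembleError("window_end must be >= window_start")
    if step <= 0:
        raise EnsembleError("step must be positive")
    span = window_end - window_start
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, abs(n_steps)):
        raise EnsembleError(
            f"window of {span} ps is not divisible by step {step} ps"
        )
    n = int(round(n_steps)) + 1
    return window_start + step * np.arange(n)


# -- periodic geometry helpers ------------------------------------------

def _fractional(lattice: np.ndarray, positions: np.ndarray) -> np.ndarray:
    return positions @ np.linalg.inv(lattice)


def _cartesian(lattice: np.ndarray, frac: np.ndarray) -> np.ndarray:
    return frac @ lattice


def make_whole(frame: Frame) -> np.ndarray:
    """Unwrap every molecule across periodic boundaries.

    Returns a copy of the positions in which each molecule is contiguous
    (no bond longer than the heuristic once unwrapped).  Connectivity
    within a molecule id is inferred with a 1.8 Å minimum-image distance
    heuristic and traversed breadth-first.
    """
    lat = frame.lattice
    inv = np.linalg.inv(lat)
    pos = frame.positions.copy()
    for mid, idx in frame.molecule_indices().items():
        if len(idx) == 1:
            continue
        sub = pos[idx]
        n = len(sub)
        # minimum-image displacement between every atom pair of the molecule
        d = sub[None, :, :] - sub[:, None, :]
        df = d @ inv
        df -= np.round(df)
        dmin = np.linalg.norm(df @ lat, axis=-1)
        adj = dmin < BOND_HEURISTIC
        np.fill_diagonal(adj, False)
        new = np.empty_like(sub)
        seen = np.zeros(n, dtype=bool)
        new[0] = sub[0]
        seen[0] = True
        queue = [0]
        while queue:
            i = queue.pop()
            for j in np.flatnonzero(adj[i]):
                if seen[j]:
                    continue
                shift_f = np.round((sub[j] - new[i]) @ inv)
                new[j] = sub[j] - shift_f @ lat
                seen[j] = True
                queue.append(j)
        if not seen.all():
            raise EnsembleError(
                f"molecule {mid} cannot be unwrapped consistently "
                f"({(~seen).sum()} atoms disconnected at {BOND_HEURISTIC} Å)"
            )
        pos[idx] = new
    return pos


def _min_image_shift(
    lattice: np.ndarray,
    central: np.ndarray,
    neighbor: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Lattice translation bringing ``neighbor`` closest to ``central``.

    Searches the 27 translations around the centroid-difference estimate and
    returns (cartesian shift, minimum atom-atom distance after shifting).
    """
    inv = np.linalg.inv(lattice)
    base = np.round((np.mean(central, axis=0) - np.mean(neighbor, axis=0)) @ inv)
    best = (None, np.inf)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                shift = (base + (dx, dy, dz)) @ lattice
                d = central[:, None, :] - (neighbor + shift)[None, :, :]
                dmin = float(np.sqrt((d ** 2).sum(-1).min()))
                if dmin < best[1]:
                    best = (shift, dmin)
    return best  # type: ignore[return-value]


def _is_diagonal(lattice: np.ndarray) -> bool:
    return bool(np.allclose(lattice, np.diag(np.diag(lattice))))


def extract_environments(
    frame: Frame,
    cutoff: float,
    run_id: str = "run",
    water_size: int = 3,
) -> list[MolecularEnvironment]:
    """Extract one environment per solute molecule of a frame.

    A molecule is a neighbor of the central molecule when any minimum-image
    atom-atom distance between the two is <= ``cutoff``.  Neighbors are made
    whole and translated to the central molecule's periodic image.  Solvent
    (water) molecules — identified as molecule ids with exactly
    ``water_size`` atoms — are neighbors only, never centers.
    """
    if cutoff <= 0:
        raise EnsembleError("cutoff must be positive")
    lat = frame.lattice
    shortest = np.linalg.norm(lat, axis=1).min()
    if cutoff >= shortest / 2:
        raise EnsembleError(
            f"cutoff {cutoff} Å must be below half the shortest box vector "
            f"({shortest / 2:.2f} Å) for the minimum-image convention"
        )

    whole = make_whole(frame)
    groups = frame.molecule_indices()
    mol_order = list(groups)

    # candidate molecule pairs from a periodic neighbor query on wrapped atoms
    frac = _fractional(lat, frame.positions) % 1.0
    pair_mols: set[tuple[int, int]] = set()
    if _is_diagonal(lat):
        box = np.diag(lat)
        wrapped = _cartesian(lat, frac)
        # guard against coordinates landing exactly on the box edge
        wrapped = np.clip(wrapped, 0.0, np.nextafter(box, 0.0))
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if len(pairs):
            ma = frame.mol_ids[pairs[:, 0]]
            mb = frame.mol_ids[pairs[:, 1]]
            keep = ma != mb
            for a, b in zip(ma[keep], mb[keep]):
                pair_mols.add((min(int(a), int(b)), max(int(a), int(b))))
    else:
        # general (triclinic) fallback: all-pairs with 27-image search
        for i, mi in enumerate(mol_order):
            for mj in mol_order[i + 1:]:
                _, dmin = _min_image_shift(lat, whole[groups[mi]], whole[groups[mj]])
                if dmin <= cutoff:
                    pair_mols.add((min(mi, mj), max(mi, mj)))

    neighbor_map: dict[int, set[int]] = {m: set() for m in mol_order}
    for a, b in pair_mols:
        neighbor_map[a].add(b)
        neighbor_map[b].add(a)

    envs: list[MolecularEnvironment] = []
    for mid in mol_order:
        idx = groups[mid]
        if len(idx) == water_size:
            continue  # water: never a central molecule
        central = whole[idx]
        keep_pos = [central]
        keep_el = [frame.elements[idx]]
        keep_mid = [frame.mol_ids[idx]]
        for nid in sorted(neighbor_map[mid]):
            nidx = groups[nid]
            shift, dmin = _min_image_shift(lat, central, whole[nidx])
            if dmin > cutoff:
                continue  # KD-tree candidate that fails the molecule-level check
            keep_pos.append(whole[nidx] + shift)
            keep_el.append(frame.elements[nidx])
            keep_mid.append(frame.mol_ids[nidx])
        envs.append(
            MolecularEnvironment(
                env_id=f"{run_id}:{frame.frame_time:g}:{mid}",
                central_mol_id=mid,
                positions=np.concatenate(keep_pos),
                elements=np.concatenate(keep_el),
                mol_ids=np.concatenate(keep_mid),
                cutoff=cutoff,
                run_id=run_id,
            )
        )
    return envs


# -- extended-XYZ I/O ----------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"(?:frame_time|Time)=([-\d.eE+]+)")


def write_extxyz(frames: Iterable[Frame], path: str | Path) -> None:
    """Write frames as extended XYZ with lattice, time, and mol-id columns."""
    with open(path, "w") as fh:
        for frame in frames:
            lat = " ".join(f"{x:.8f}" for x in frame.lattice.ravel())
            fh.write(f"{frame.n_atoms}\n")
            fh.write(
                f'Lattice="{lat}" '
                f"Properties=species:S:1:pos:R:3:mol_id:I:1 "
                f"frame_time={frame.frame_time:g}\n"
            )
            for el, (x, y, z), mid in zip(frame.elements, frame.positions, frame.mol_ids):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f} {mid}\n")


def read_extxyz(path: str | Path) -> list[Frame]:
    """Read the extended-XYZ dialect written by :func:`write_extxyz`."""
    frames: list[Frame] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            m = _LATTICE_RE.search(comment)
            if m is None:
                raise EnsembleError("frame comment line lacks a Lattice entry")
            lattice = np.array([float(x) for x in m.group(1).split()]).reshape(3, 3)
            tm = _TIME_RE.search(comment)
            frame_time = float(tm.group(1)) if tm else 0.0
            pos = np.empty((n, 3))
            els = np.empty(n, dtype=object)
            mids = np.empty(n, dtype=int)
            for i in range(n):
                parts = fh.readline().split()
                els[i] = parts[0]
                pos[i] = [float(v) for v in parts[1:4]]
                mids[i] = int(parts[4])
            frames.append(Frame(lattice, pos, els, mids, frame_time))
    return frames


def write_environments(envs: Iterable[MolecularEnvironment], path: str | Path) -> None:
    """Write environments as concatenated XYZ clusters, env_id in the comment."""
    with open(path, "w") as fh:
        for env in envs:
            fh.write(f"{env.n_atoms}\n")
            fh.write(f"env_id={env.env_id} central_mol={env.central_mol_id} cutoff={env.cutoff:g}\n")
            for el, (x, y, z), mid in zip(env.elements, env.positions, env.mol_ids):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f} {mid}\n")
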