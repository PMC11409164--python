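"""Element-resolved average atomic density maps on a cubic grid.

Environments are rigidly aligned on reference atoms of the central
molecule; an amplitude-one Gaussian is placed at every atomic position and
averaged over environments, so a perfectly conserved atom position gives a
channel maximum of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ensemble import MolecularEnvironment
from .molecule import MoleculeGraph

__all__ = [
    "AlignmentSpec",
    "DensityMap",
    "kabsch",
    "align_environment",
    "accumulate_density",
    "export_cube",
    "read_cube",
]

BOHR_PER_ANGSTROM = 1.8897259886

_ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "Cl": 17,
}


class DensityError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentSpec:
    """How to superpose environments before accumulating density.

    ``kabsch`` does a least-squares proper-rotation fit of >= 3 reference
    atoms; ``bond_axis`` puts the first reference atom at the template's
    first position, the 1 -> 2 bond along +z, and the orientation atom in
    the xz half-plane (x > 0).
    """

    ref_atoms: tuple[str, ...]
    mode: str = "kabsch"
    orientation_atom: str | None = None  # bond_axis only

    def __post_init__(self) -> None:
        if self.mode not in ("kabsch", "bond_axis"):
            raise DensityError(f"unknown alignment mode {self.mode!r}")
        if self.mode == "kabsch" and len(self.ref_atoms) < 3:
            raise DensityError("kabsch alignment needs at least 3 reference atoms")
        if self.mode == "bond_axis":
            if len(self.ref_atoms) != 2:
                raise DensityError("bond_axis alignment needs exactly 2 reference atoms")
            if self.orientation_atom is None:
                raise DensityError("bond_axis alignment needs an orientation atom")


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing |R @ mobile.T + t - target|.

    Reflections are never applied (det(R) = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = ct - r @ cm
    return r, t


def _label_indices(env: MolecularEnvironment, graph: MoleculeGraph, labels) -> np.ndarray:
    central = np.flatnonzero(env.central_mask)
    order = {l: k for k, l in enumerate(graph.labels)}
    out = []
    for l in labels:
        if l not in order:
            raise DensityError(f"unknown reference atom {l!r}")
        out.append(central[order[l]])
    return np.array(out, dtype=int)


def align_environment(
    env: MolecularEnvironment,
    spec: AlignmentSpec,
    graph: MoleculeGraph,
    template: np.ndarray | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Rigidly transform all environment atoms per the alignment spec.

    ``template``: reference coordinates the environment is superposed onto.
    For ``kabsch`` it must hold one row per reference atom; for
    ``bond_axis`` only its first row is used (as the position the first
    reference atom is pinned to; default origin).

    Returns (transformed positions, (R, t)).
    """
    idx = _label_indices(env, graph, spec.ref_atoms)
    refs = env.positions[idx]

    if spec.mode == "kabsch":
        if template is None or len(template) != len(refs):
            raise DensityError("kabsch alignment needs a template with one row per reference atom")
        span = refs - refs.mean(axis=0)
        if np.linalg.matrix_rank(span, tol=1e-8) < 2:
            raise DensityError(
                "reference atoms are collinear; use bond_axis mode instead"
            )
        r, t = kabsch(refs, np.asarray(template, dtype=float))
    else:
        origin = np.zeros(3) if template is None else np.asarray(template, dtype=float).reshape(-1, 3)[0]
        o_idx = _label_indices(env, graph, [spec.orientation_atom])[0]
        a1, a2 = refs[0], refs[1]
        z = a2 - a1
        nz = np.linalg.norm(z)
        if nz < 1e-12:
            raise DensityError("bond_axis reference atoms coincide")
        z = z / nz
        v = env.positions[o_idx] - a1
        v_perp = v - np.dot(v, z) * z
        if np.linalg.norm(v_perp) < 1e-10:
            raise DensityError("orientation atom is collinear with the bond axis")
        x = v_perp / np.linalg.norm(v_perp)
        y = np.cross(z, x)
        r = np.vstack([x, y, z])          # rows are the new basis -> rotation matrix
        t = origin - r @ a1
    return (env.positions @ r.T + t), (r, t)


@dataclass
class DensityMap:
    """Average Gaussian density per element on a cubic grid."""

    origin: np.ndarray               # grid center (position of the first aligned atom)
    side: float                      # L, Å
    spacing: float                   # h, Å
    gaussian_width: float            # w, Å (standard deviation)
    n_env: int
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return int(round(self.side / self.spacing)) + 1

    def axis(self, dim: int) -> np.ndarray:
        return self.origin[dim] + np.linspace(-self.side / 2, self.side / 2, self.n_points)

    def value_at(self, element: str, point: np.ndarray) -> float:
        """Channel value at the grid point nearest to ``point``."""
        g = self.channels[element]
        idx = tuple(
            int(np.clip(round((point[d] - (self.origin[d] - self.side / 2)) / self.spacing),
                        0, self.n_points - 1))
            for d in range(3)
        )
        return float(g[idx])


def _h_channel_key(elements, positions, i, split_h):
    el = elements[i]
    if el != "H" or not split_h:
        return el
    # classify H by its nearest heavy atom: carbon-bound vs heteroatom-bound
    d = np.linalg.norm(positions - positions[i], axis=1)
    d[i] = np.inf
    heavy = np.array([e != "H" for e in elements])
    d[~heavy] = np.inf
    j = int(np.argmin(d))
    return "H(C)" if elements[j] == "C" else "H(X)"


def accumulate_density(
    aligned: Sequence[tuple[np.ndarray, Sequence[str]]],
    w: float = 0.5,
    side: float = 12.0,
    spacing: float = 0.2,
    origin: np.ndarray | None = None,
    elements_keep: Sequence[str] | None = None,
    split_h: bool = False,
) -> DensityMap:
    """Average amplitude-one Gaussian density over aligned environments.

    ``aligned`` is a sequence of (positions, elements) pairs, already in the
    common frame.  Each atom contributes exp(-|x - r|^2 / (2 w^2)); channels
    are averaged over environments, so a conserved atom position has channel
    maximum 1.  Atoms outside the box still contribute their in-grid tails.
    """
    if len(aligned) == 0:
        raise DensityError("no environments to accumulate")
    if w <= 0:
        raise DensityError("gaussian width must be positive")
    if spacing > w:
        raise DensityError("grid spacing must not exceed the gaussian width")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)

    n = int(round(side / spacing)) + 1
    axes = [origin[d] + np.linspace(-side / 2, side / 2, n) for d in range(3)]

    # gather atom positions per channel across all environments
    per_channel: dict[str, list[np.ndarray]] = {}
    for positions, elements in aligned:
        positions = np.asarray(positions, dtype=float)
        elements = list(elements)
        for i, el in enumerate(elements):
            key = _h_channel_key(elements, positions, i, split_h)
            if elements_keep is not None and key not in elements_keep:
                continue
            per_channel.setdefault(key, []).append(positions[i])

    channels: dict[str, np.ndarray] = {}
    inv2w2 = 1.0 / (2.0 * w * w)
    for key, pts_list in per_channel.items():
        pts = np.array(pts_list)
        grid = np.zeros((n, n, n))
        # separable Gaussians: per-atom 1D factors combined with an outer product
        chunk = 2000
        for s in range(0, len(pts), chunk):
            p = pts[s: s + chunk]
            gx = np.exp(-((axes[0][None, :] - p[:, 0:1]) ** 2) * inv2w2)
            gy = np.exp(-((axes[1][None, :] - p[:, 1:2]) ** 2) * inv2w2)
            gz = np.exp(-((axes[2][None, :] - p[:, 2:3]) ** 2) * inv2w2)
            grid += np.einsum("ai,aj,ak->ijk", gx, gy, gz, optimize=True)
        channels[key] = grid / len(aligned)

    if elements_keep is not None:
        for key in elements_keep:
            channels.setdefault(key, np.zeros((n, n, n)))

    return DensityMap(
        origin=origin, side=side, spacing=spacing, gaussian_width=w,
        n_env=len(aligned), channels=channels,
    )


def export_cube(dmap: DensityMap, element: str, path: str | Path) -> None:
    """Write one channel as a Gaussian cube file (lengths in bohr)."""
    if element not in dmap.channels:
        raise DensityError(f"no channel for element {element!r}")
    grid = dmap.channels[element]
    n = dmap.n_points
    h_bohr = dmap.spacing * BOHR_PER_ANGSTROM
    org = (dmap.origin - dmap.side / 2) * BOHR_PER_ANGSTROM
    znum = _ATOMIC_NUMBER.get(element.split("(")[0], 1)
    center_bohr = dmap.origin * BOHR_PER_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"average atomic density, element {element}\n")
        fh.write(f"{dmap.n_env} environments, w={dmap.gaussian_width} A\n")
        fh.write(f"{1:5d} {org[0]:12.6f} {org[1]:12.6f} {org[2]:12.6f}\n")
        fh.write(f"{n:5d} {h_bohr:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{n:5d} {0.0:12.6f} {h_bohr:12.6f} {0.0:12.6f}\n")
        fh.write(f"{n:5d} {0.0:12.6f} {0.0:12.6f} {h_bohr:12.6f}\n")
        fh.write(f"{znum:5d} {0.0:12.6f} {center_bohr[0]:12.6f} "
                 f"{center_bohr[1]:12.6f} {center_bohr[2]:12.6f}\n")
        flat = grid.reshape(n * n, n)  # z fastest
        for row in flat:
            for s in range(0, n, 6):
                fh.write(" ".join(f"{v:13.5e}" for v in row[s: s + 6]) + "\n")


def read_cube(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a cube file back: (grid, origin in Å, spacing in Å)."""
    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        n_atoms = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]]) / BOHR_PER_ANGSTROM
        counts = []
        spacing = None
        for d in range(3):
            parts = fh.readline().split()
            counts.append(int(parts[0]))
            step = float(parts[1 + d]) / BOHR_PER_ANGSTROM
            if spacing is None:
                spacing = step
        for _ in range(n_atoms):
            fh.readline()
        values = np.array(fh.read().split(), dtype=float)
    grid = values.reshape(counts)
    return grid, origin, float(spacing)
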