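"""Hydrogen-bond detection, dihedral angles and set-vs-set statistics.

Structural observables are computed per molecular environment; comparing
their category frequencies between the selected (NMR) set and the
background (MD) set yields promotion/demotion statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import MolecularEnvironment
from .molecule import MoleculeGraph

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "DihedralRecord",
    "CategoryComparison",
    "detect_hbond",
    "dihedral_angle",
    "environment_dihedral",
    "compare_categories",
    "angle_histogram",
]

WATER_SIZE = 3  # atoms in a water molecule (O, H, H)


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: H...A distance ceiling and D-H...A angle floor."""

    max_ha_distance: float = 2.5   # Å
    min_dha_angle: float = 120.0   # degrees

    def __post_init__(self) -> None:
        if self.max_ha_distance <= 0:
            raise AnalysisError("max_ha_distance must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise AnalysisError("min_dha_angle must lie in (0, 180]")


@dataclass(frozen=True)
class HBondRecord:
    env_id: str
    donor_h: str
    acceptor_class: str           # acceptor label, "water", or "none"
    ha_distance: float            # Å (nan when class is "none")
    dha_angle: float              # degrees (nan when class is "none")
    criteria: HBondCriteria = HBondCriteria()


@dataclass(frozen=True)
class DihedralRecord:
    env_id: str
    quad: tuple[str, str, str, str]
    angle: float                  # degrees in (-180, 180]


def _label_positions(env: MolecularEnvironment, graph: MoleculeGraph) -> dict[str, int]:
    """Map molecule labels to atom indices of the central molecule.

    Central-molecule atoms keep their source order, which must match the
    topology's label order; elements are cross-checked.
    """
    idx = np.flatnonzero(env.central_mask)
    labels = graph.labels
    if len(idx) != len(labels):
        raise AnalysisError(
            f"central molecule of {env.env_id} has {len(idx)} atoms, topology has {len(labels)}"
        )
    for i, label in zip(idx, labels):
        if env.elements[i] != graph.atoms[label].element:
            raise AnalysisError(
                f"element mismatch at {label!r} in {env.env_id}: "
                f"{env.elements[i]} vs {graph.atoms[label].element}"
            )
    return dict(zip(labels, (int(i) for i in idx)))


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbond(
    env: MolecularEnvironment,
    graph: MoleculeGraph,
    donor_h: str,
    criteria: HBondCriteria = HBondCriteria(),
    include_intramolecular: bool = False,
    min_bond_separation: int = 3,
) -> HBondRecord:
    """Find the hydrogen-bond acceptor of a donor proton, if any.

    Candidate acceptors are N/O atoms on neighbor molecules — water oxygens
    give the class "water", drug copies the label of the acceptor atom —
    plus, optionally, intramolecular N/O atoms at least
    ``min_bond_separation`` bonds from the donor.  Among candidates passing
    both geometric criteria the one with the smallest H...A distance wins.
    """
    label_idx = _label_positions(env, graph)
    if donor_h not in label_idx:
        raise AnalysisError(f"unknown donor proton {donor_h!r}")
    if not graph.atoms[donor_h].is_hydrogen:
        raise AnalysisError(f"donor {donor_h!r} is not a hydrogen")
    heavy_nbrs = [n for n in graph.neighbors(donor_h) if not graph.atoms[n].is_hydrogen]
    if not heavy_nbrs:
        raise AnalysisError(f"donor {donor_h!r} has no attached heavy atom")
    donor_heavy = heavy_nbrs[0]

    h_pos = env.positions[label_idx[donor_h]]
    d_pos = env.positions[label_idx[donor_heavy]]

    central_count = int(env.central_mask.sum())
    label_by_central_offset = {i: l for i, l in enumerate(graph.labels)}
    mol_sizes = {m: len(env.molecule_atoms(m)) for m in np.unique(env.mol_ids)}

    candidates: list[tuple[float, float, str]] = []  # (distance, angle, class)
    for i in range(env.n_atoms):
        el = env.elements[i]
        if el not in ("N", "O"):
            continue
        mid = int(env.mol_ids[i])
        if mid == env.central_mol_id:
            if not include_intramolecular:
                continue
            label = label_by_central_offset[i - np.flatnonzero(env.central_mask)[0]]
            # require a minimum through-bond separation from the donor proton
            import networkx as nx

            g = nx.Graph(graph.bonds)
            g.add_nodes_from(graph.labels)
            try:
                sep = nx.shortest_path_length(g, donor_h, label)
            except nx.NetworkXNoPath:
                sep = np.inf
            if sep < min_bond_separation:
                continue
            cls = label
        elif mol_sizes[mid] == WATER_SIZE:
            cls = "water"
        else:
            # neighbor drug copy: label by position within its molecule
            offset = i - int(env.molecule_atoms(mid)[0])
            if mol_sizes[mid] == central_count:
                cls = label_by_central_offset[offset]
            else:
                cls = el  # unknown species: fall back to the element
        dist = float(np.linalg.norm(env.positions[i] - h_pos))
        if dist > criteria.max_ha_distance:
            continue
        ang = _angle_deg(d_pos, h_pos, env.positions[i])
        if ang < criteria.min_dha_angle:
            continue
        candidates.append((dist, ang, cls))

    if not candidates:
        return HBondRecord(env.env_id, donor_h, "none", float("nan"), float("nan"), criteria)
    dist, ang, cls = min(candidates, key=lambda c: c[0])
    return HBondRecord(env.env_id, donor_h, cls, dist, ang, criteria)


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, in (-180, 180].

    Sign follows the convention in which a clockwise rotation of the far
    bond, viewed along p2 -> p3, is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-12:
        raise AnalysisError("central atoms of the torsion coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise AnalysisError("three consecutive torsion points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))
    if angle <= -180.0:
        angle += 360.0
    return angle


def environment_dihedral(
    env: MolecularEnvironment,
    graph: MoleculeGraph,
    quad: Sequence[str],
) -> DihedralRecord:
    """Torsion of four labeled atoms of the central molecule."""
    if len(quad) != 4:
        raise AnalysisError("a torsion needs exactly 4 atom labels")
    for a, b in zip(quad[:-1], quad[1:]):
        if b not in graph.neighbors(a):
            raise AnalysisError(f"torsion atoms {a!r} and {b!r} are not bonded")
    label_idx = _label_positions(env, graph)
    pts = [env.positions[label_idx[l]] for l in quad]
    return DihedralRecord(env.env_id, tuple(quad), dihedral_angle(*pts))


@dataclass
class CategoryComparison:
    """Per-category percentages for the background and selected sets."""

    table: pd.DataFrame  # columns: category, count_MD, count_NMR, percent_MD, percent_NMR

    def percent(self, category: str, which: str = "NMR") -> float:
        row = self.table[self.table["category"] == category]
        if row.empty:
            raise AnalysisError(f"unknown category {category!r}")
        return float(row[f"percent_{which}"].iloc[0])


def compare_categories(
    records_md: Sequence[HBondRecord],
    records_nmr: Sequence[HBondRecord],
    categories: Sequence[str] | None = None,
) -> CategoryComparison:
    """Promotion/demotion table of acceptor classes between the two sets."""
    if len(records_md) == 0 or len(records_nmr) == 0:
        raise AnalysisError("both record sets must be non-empty")
    md = pd.Series([r.acceptor_class for r in records_md]).value_counts()
    nmr = pd.Series([r.acceptor_class for r in records_nmr]).value_counts()
    if categories is None:
        categories = sorted(set(md.index) | set(nmr.index))
    rows = []
    for cat in categories:
        c_md = int(md.get(cat, 0))
        c_nmr = int(nmr.get(cat, 0))
        rows.append(
            {
                "category": cat,
                "count_MD": c_md,
                "count_NMR": c_nmr,
                "percent_MD": 100.0 * c_md / len(records_md),
                "percent_NMR": 100.0 * c_nmr / len(records_nmr),
            }
        )
    return CategoryComparison(pd.DataFrame(rows))


def angle_histogram(
    records: Sequence[DihedralRecord] | np.ndarray,
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Periodic histogram of torsion angles over (-180, 180].

    -180 and +180 are the same conformation and land in the same (last)
    bin.  Returns bin edges, counts and frequencies normalized to 1.
    """
    if abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise AnalysisError("bin_width must divide 360")
    angles = np.asarray(
        [r.angle for r in records] if len(records) and isinstance(records[0], DihedralRecord)
        else records, dtype=float,
    )
    # map to (-180, 180], with -180 folded onto +180
    wrapped = ((angles - 180.0) % -360.0) + 180.0
    wrapped[wrapped <= -180.0] += 360.0
    n_bins = int(round(360.0 / bin_width))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    # right-closed bins (-180, -180 + w], ..., (180 - w, 180]
    idx = np.ceil((wrapped + 180.0) / bin_width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    freq = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts, "frequency": freq}
    )
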