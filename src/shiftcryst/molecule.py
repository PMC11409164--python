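"""Molecular bond graph, atom labels and bond-shell ("W-n") subset selection.

The molecule topology is supplied explicitly (labels + bonds) rather than
perceived from coordinates, so that shell membership counts are exactly
reproducible.  Graph distance is measured over heavy atoms only; hydrogens
are appended as decorations of the heavy atoms they are bonded to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "AtomSpec",
    "MoleculeGraph",
    "ShellSelection",
    "build_graph",
    "bond_shell",
    "load_molecule",
    "save_molecule",
]

#: nuclei the scoring pipeline knows about
_NUCLEUS_BY_ELEMENT = {"H": "1H", "C": "13C"}


class MoleculeError(ValueError):
    """Raised for invalid molecule definitions or queries."""


@dataclass(frozen=True)
class AtomSpec:
    """One atom of the molecule: a label, an element, and an assignment flag."""

    label: str
    element: str
    assigned: bool = False

    @property
    def nucleus(self) -> str:
        """NMR nucleus implied by the element: H -> 1H, C -> 13C, else 'other'."""
        return _NUCLEUS_BY_ELEMENT.get(self.element, "other")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class MoleculeGraph:
    """Validated bonded graph of a single molecule.

    Attributes
    ----------
    atoms:
        Mapping label -> :class:`AtomSpec`, in insertion order (the order is
        meaningful: snapshot readers map coordinates to labels by position).
    bonds:
        List of unordered label pairs.
    """

    atoms: dict[str, AtomSpec]
    bonds: list[tuple[str, str]]
    _adj: dict[str, set[str]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._adj:
            self._adj = {label: set() for label in self.atoms}
            for a, b in self.bonds:
                self._adj[a].add(b)
                self._adj[b].add(a)

    # -- queries ---------------------------------------------------------
    def neighbors(self, label: str) -> set[str]:
        return self._adj[label]

    def degree(self, label: str) -> int:
        return len(self._adj[label])

    @property
    def labels(self) -> list[str]:
        return list(self.atoms)

    @property
    def heavy_labels(self) -> list[str]:
        return [l for l, a in self.atoms.items() if not a.is_hydrogen]

    def attached_hydrogens(self, label: str) -> set[str]:
        """Hydrogens bonded to the given heavy atom."""
        return {n for n in self._adj[label] if self.atoms[n].is_hydrogen}

    def heavy_graph(self) -> nx.Graph:
        """The graph restricted to heavy atoms (hydrogens removed)."""
        g = nx.Graph()
        g.add_nodes_from(self.heavy_labels)
        for a, b in self.bonds:
            if not self.atoms[a].is_hydrogen and not self.atoms[b].is_hydrogen:
                g.add_edge(a, b)
        return g

    def assigned_labels(self) -> set[str]:
        return {l for l, a in self.atoms.items() if a.assigned}


@dataclass(frozen=True)
class ShellSelection:
    """Atoms within ``n_bonds`` of ``center`` plus their attached hydrogens."""

    center: str
    n_bonds: int
    members: frozenset[str]
    n_shifts_used: int
    n_shifts_total: int


def build_graph(atoms: Sequence[AtomSpec], bonds: Iterable[tuple[str, str]]) -> MoleculeGraph:
    """Validate atoms and bonds and build a :class:`MoleculeGraph`.

    Raises
    ------
    MoleculeError
        On duplicate labels, self-bonds, or bonds referencing unknown labels.
    """
    atom_map: dict[str, AtomSpec] = {}
    for atom in atoms:
        if atom.label in atom_map:
            raise MoleculeError(f"duplicate atom label {atom.label!r}")
        atom_map[atom.label] = atom
    bond_list: list[tuple[str, str]] = []
    for a, b in bonds:
        if a == b:
            raise MoleculeError(f"self-bond on {a!r}")
        for end in (a, b):
            if end not in atom_map:
                raise MoleculeError(f"bond ({a!r}, {b!r}) references unknown atom {end!r}")
        bond_list.append((a, b))
    return MoleculeGraph(atoms=atom_map, bonds=bond_list)


def bond_shell(
    graph: MoleculeGraph,
    center: str,
    n_bonds: int,
    assignment: set[str] | None = None,
) -> ShellSelection:
    """Heavy atoms within ``n_bonds`` of ``center``, plus attached hydrogens.

    Distances are graph distances over the heavy-atom skeleton.  The shift
    counts refer to the set of assigned labels whose nucleus is 1H or 13C:
    ``n_shifts_total`` counts all of them, ``n_shifts_used`` those that fall
    inside the shell.
    """
    if center not in graph.atoms:
        raise MoleculeError(f"unknown center label {center!r}")
    if n_bonds < 0:
        raise MoleculeError("n_bonds must be >= 0")
    if graph.atoms[center].is_hydrogen:
        raise MoleculeError(
            f"center {center!r} is a hydrogen; use its attached heavy atom"
        )

    heavy = graph.heavy_graph()
    dist = nx.single_source_shortest_path_length(heavy, center, cutoff=n_bonds)
    members = set(dist)
    for label in list(members):
        members |= graph.attached_hydrogens(label)

    if assignment is None:
        assignment = graph.assigned_labels()
    scoreable = {
        l for l in assignment
        if l in graph.atoms and graph.atoms[l].nucleus in ("1H", "13C")
    }
    used = len(scoreable & members)
    return ShellSelection(
        center=center,
        n_bonds=n_bonds,
        members=frozenset(members),
        n_shifts_used=used,
        n_shifts_total=len(scoreable),
    )


# -- persistence ---------------------------------------------------------

def save_molecule(graph: MoleculeGraph, path: str | Path) -> None:
    """Write the molecule as JSON (atoms with labels/elements/flags, bonds)."""
    payload = {
        "atoms": [
            {"label": a.label, "element": a.element, "assigned": a.assigned}
            for a in graph.atoms.values()
        ],
        "bonds": [list(b) for b in graph.bonds],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_molecule(path: str | Path) -> MoleculeGraph:
    """Read a molecule JSON written by :func:`save_molecule`."""
    payload = json.loads(Path(path).read_text())
    atoms = [
        AtomSpec(label=a["label"], element=a["element"], assigned=bool(a.get("assigned", False)))
        for a in payload["atoms"]
    ]
    bonds = [(a, b) for a, b in payload["bonds"]]
    return build_graph(atoms, bonds)
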