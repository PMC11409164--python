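"""Synthetic amorphous ensembles with known ground truth.

A rigid 12-atom model molecule (aromatic ring C1-C6, an N1-H1 donor on C1,
an O1 acceptor on C3 and a flexible C7-C8-O2 tail on C4) is scattered over
periodic boxes.  A chosen fraction of molecules is planted with a
hydrogen-bond partner (a water, or another molecule offering its O1 or O2),
built with a comfortable geometric margin relative to the default detection
criteria.  A forward shift model moves the donor proton downfield when an
H bond is present, so the whole selection pipeline can be validated against
the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import dihedral_angle
from .ensemble import Frame
from .molecule import AtomSpec, MoleculeGraph, build_graph
from .spectra import ShiftDistribution

__all__ = [
    "SynthConfig",
    "SyntheticWorld",
    "model_molecule",
    "generate_ensemble",
    "forward_shifts",
    "subpopulation_distributions",
    "TORSION_QUAD",
    "DONOR_H",
    "DONOR_N",
]

DONOR_N = "N1"
DONOR_H = "H1"
TORSION_QUAD = ("C3", "C4", "C7", "C8")
H_TORSION_QUAD = ("C2", "C1", "N1", "H1")

#: default base shifts of the forward model, ppm
BASE_SHIFTS = {
    "H1": 8.0, "C1": 148.0, "C2": 122.0, "C3": 155.0, "C4": 135.0,
    "C5": 118.0, "C6": 126.0, "C7": 40.0, "C8": 65.0,
}

#: tail atoms whose shifts pick up a weak torsion dependence
TORSION_COUPLED = ("C4", "C7", "C8")

_MIN_CLEARANCE = 3.0  # Å kept free between clusters and around non-bonded H...acceptor pairs


class SyntheticError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Knobs of the synthetic world; every random draw comes from ``seed``."""

    n_runs: int = 2
    n_frames: int = 5
    n_molecules: int = 40            # drug molecules per frame
    box: float | None = None         # Å; None = auto-sized to fit the clusters
    planted_hbond_fraction: float = 0.3
    hbond_class_weights: dict[str, float] = field(
        default_factory=lambda: {"water": 1 / 3, "O1": 1 / 3, "O2": 1 / 3}
    )
    water_fraction: float = 0.1      # waters per drug molecule (planted partners count)
    dihedral_modes: tuple[tuple[float, float, float], ...] = (
        (60.0, 20.0, 0.5), (180.0, 20.0, 0.5),
    )                                # (center deg, von Mises concentration, weight)
    hbond_distance: float = 1.90     # Å, planted H...A distance
    delta_hb: float = 4.0            # ppm downfield increment on the donor proton
    noise_sd: float = 0.5            # ppm
    torsion_coupling: float = 0.3    # ppm amplitude of the tail-carbon torsion term
    frame_step: float = 100.0        # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_hbond_fraction <= 0.5):
            raise SyntheticError("planted_hbond_fraction must lie in [0, 0.5] "
                                 "(each drug-drug bond consumes an unflagged partner)")
        if self.noise_sd <= 0:
            raise SyntheticError("noise_sd must be positive")
        w = sum(self.hbond_class_weights.values())
        if w <= 0 or any(v < 0 for v in self.hbond_class_weights.values()):
            raise SyntheticError("hbond_class_weights must be non-negative with positive sum")
        self.hbond_class_weights = {k: v / w for k, v in self.hbond_class_weights.items()}
        tw = sum(m[2] for m in self.dihedral_modes)
        if tw <= 0:
            raise SyntheticError("dihedral mode weights must have positive sum")
        self.dihedral_modes = tuple((c, k, w / tw) for c, k, w in self.dihedral_modes)


# -- model molecule ------------------------------------------------------

def model_molecule() -> tuple[MoleculeGraph, np.ndarray]:
    """The fixed model molecule: topology (with assignment flags) + template coords."""
    ring_r = 1.40
    coords: dict[str, np.ndarray] = {}
    for k in range(6):
        th = np.radians(60.0 * k)
        coords[f"C{k + 1}"] = ring_r * np.array([np.cos(th), np.sin(th), 0.0])

    def _radial(label: str, dist: float) -> np.ndarray:
        p = coords[label]
        return p + dist * p / np.linalg.norm(p)

    coords["N1"] = _radial("C1", 1.40)
    # H1 at 120 deg from the C1->N1 direction, in-plane (rotatable about C1-N1)
    n1 = coords["N1"]
    axis_in = (n1 - coords["C1"]) / np.linalg.norm(n1 - coords["C1"])
    perp = np.array([-axis_in[1], axis_in[0], 0.0])
    coords["H1"] = n1 + 1.01 * (np.cos(np.radians(60.0)) * axis_in
                                + np.sin(np.radians(60.0)) * perp)
    coords["O1"] = _radial("C3", 1.36)
    coords["C7"] = _radial("C4", 1.50)
    c7 = coords["C7"]
    axis_t = (c7 - coords["C4"]) / np.linalg.norm(c7 - coords["C4"])
    perp_t = np.array([-axis_t[1], axis_t[0], 0.0])
    coords["C8"] = c7 + 1.50 * (np.cos(np.radians(60.0)) * axis_t
                                + np.sin(np.radians(60.0)) * perp_t)
    c8 = coords["C8"]
    axis_8 = (c8 - c7) / np.linalg.norm(c8 - c7)
    perp_8 = np.cross(np.array([0.0, 0.0, 1.0]), axis_8)
    coords["O2"] = c8 + 1.43 * (np.cos(np.radians(70.0)) * axis_8
                                + np.sin(np.radians(70.0)) * perp_8)

    atoms = [
        AtomSpec("C1", "C", True), AtomSpec("C2", "C", True), AtomSpec("C3", "C", True),
        AtomSpec("C4", "C", True), AtomSpec("C5", "C", True), AtomSpec("C6", "C", True),
        AtomSpec("N1", "N", False), AtomSpec("H1", "H", True),
        AtomSpec("O1", "O", False), AtomSpec("C7", "C", True), AtomSpec("C8", "C", True),
        AtomSpec("O2", "O", False),
    ]
    bonds = [
        ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"), ("C5", "C6"),
        ("C6", "C1"), ("C1", "N1"), ("N1", "H1"), ("C3", "O1"), ("C4", "C7"),
        ("C7", "C8"), ("C8", "O2"),
    ]
    graph = build_graph(atoms, bonds)
    template = np.array([coords[l] for l in graph.labels])
    return graph, template


# -- small rotation helpers ---------------------------------------------

def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        perp -= np.dot(perp, a) * a
        return _rotation_about(perp, 180.0)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k / (1.0 + c)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# -- molecule / cluster builders ----------------------------------------

def _conform(
    graph: MoleculeGraph,
    template: np.ndarray,
    torsion: float,
    h_torsion: float,
) -> np.ndarray:
    """Template copy with the tail and donor-H torsions set to given values."""
    order = {l: i for i, l in enumerate(graph.labels)}
    pos = template.copy()

    # rotating the far atoms by +phi about the p2 -> p3 axis decreases the
    # signed torsion, hence the (current - target) sense
    quad = [pos[order[l]] for l in TORSION_QUAD]
    current = dihedral_angle(*quad)
    axis = quad[2] - quad[1]
    rot = _rotation_about(axis, current - torsion)
    for l in ("C8", "O2"):
        i = order[l]
        pos[i] = quad[1] + rot @ (pos[i] - quad[1])

    hq = [pos[order[l]] for l in H_TORSION_QUAD]
    current_h = dihedral_angle(*hq)
    axis_h = hq[2] - hq[1]
    rot_h = _rotation_about(axis_h, current_h - h_torsion)
    i = order["H1"]
    pos[i] = hq[1] + rot_h @ (pos[i] - hq[1])
    return pos


def _water(direction: np.ndarray, origin: np.ndarray, spin_deg: float) -> np.ndarray:
    """Water with its O at origin and both hydrogens pointing along +direction."""
    d = direction / np.linalg.norm(direction)
    half = np.radians(104.5 / 2.0)
    local = np.array([
        [0.0, 0.0, 0.0],
        [0.96 * np.sin(half), 0.0, 0.96 * np.cos(half)],
        [-0.96 * np.sin(half), 0.0, 0.96 * np.cos(half)],
    ])  # bisector along +z
    r = _align_rotation(np.array([0.0, 0.0, 1.0]), d) @ _rotation_about(
        np.array([0.0, 0.0, 1.0]), spin_deg
    )
    return origin + local @ r.T


@dataclass
class SyntheticWorld:
    """Generated frames plus the ground truth attached to every environment."""

    frames: dict[str, list[Frame]]
    graph: MoleculeGraph
    template: np.ndarray
    truth: pd.DataFrame  # env_id, run, frame_time, mol_id, hbond, hbond_class, dihedral_mode, dihedral_angle
    config: SynthConfig

    def all_frames(self) -> list[tuple[str, Frame]]:
        return [(run, f) for run in sorted(self.frames) for f in self.frames[run]]


def _sample_torsion(rng: np.random.Generator, modes) -> tuple[int, float]:
    weights = np.array([m[2] for m in modes])
    mode = int(rng.choice(len(modes), p=weights))
    center, kappa, _ = modes[mode]
    angle = np.degrees(rng.vonmises(np.radians(center), kappa))
    return mode, float(angle)


def generate_ensemble(config: SynthConfig) -> SyntheticWorld:
    """Build the periodic frames and the per-environment ground truth."""
    rng = np.random.default_rng(config.seed)
    graph, template = model_molecule()
    order = {l: i for i, l in enumerate(graph.labels)}
    nat = len(graph.labels)

    n_flag = int(round(config.planted_hbond_fraction * config.n_molecules))
    class_names = list(config.hbond_class_weights)
    class_w = np.array([config.hbond_class_weights[c] for c in class_names])

    # conservative cell size: every cluster atom lies within 3 R_t + d_HA of
    # the focal molecule's centroid (partner centroid within R_t of its
    # acceptor, acceptor within d_HA + R_t of the focal centroid)
    r_t = float(np.linalg.norm(template - template.mean(axis=0), axis=1).max())
    cell = 2.0 * (3.0 * r_t + config.hbond_distance) + 2.0 * _MIN_CLEARANCE

    frames: dict[str, list[Frame]] = {}
    truth_rows: list[dict] = []

    for run_i in range(config.n_runs):
        run_id = f"run{run_i:02d}"
        frames[run_id] = []
        for frame_i in range(config.n_frames):
            frame_time = config.frame_step * (frame_i + 1)

            # plan the frame: which drugs are flagged and with which partner
            flags = np.zeros(config.n_molecules, dtype=bool)
            flags[:n_flag] = True
            classes = np.array(["none"] * config.n_molecules, dtype=object)
            if n_flag:
                classes[:n_flag] = rng.choice(class_names, size=n_flag, p=class_w)
            # drug-drug bonds consume unflagged partners
            n_pair = int(np.sum((classes == "O1") | (classes == "O2")))
            if n_pair > config.n_molecules - n_flag:
                raise SyntheticError(
                    "not enough unflagged molecules to serve as hydrogen-bond partners"
                )

            # clusters: (kind, payload)
            clusters: list[tuple[str, object]] = []
            partner_pool = list(range(n_flag, config.n_molecules))
            consumed: set[int] = set()
            for m in range(n_flag):
                if classes[m] == "water":
                    clusters.append(("water_pair", (m,)))
                else:
                    partner = partner_pool.pop()
                    consumed.add(partner)
                    clusters.append(("drug_pair", (m, partner, classes[m])))
            for m in range(n_flag, config.n_molecules):
                if m not in consumed:
                    clusters.append(("single", (m,)))
            n_pair_waters = int(np.sum(classes == "water"))
            n_lone_w = max(0, int(round(config.water_fraction * config.n_molecules)) - n_pair_waters)
            for wi in range(n_lone_w):
                clusters.append(("water", (wi,)))

            n_side = int(np.ceil(len(clusters) ** (1.0 / 3.0)))
            box = config.box if config.box is not None else n_side * cell
            if box < n_side * cell:
                raise SyntheticError(
                    f"box of {box:.1f} Å is too small for {len(clusters)} clusters "
                    f"(needs >= {n_side * cell:.1f} Å)"
                )
            cell_len = box / n_side
            cell_ids = rng.permutation(n_side ** 3)[: len(clusters)]

            pos_chunks: list[np.ndarray] = []
            el_chunks: list[np.ndarray] = []
            mid_chunks: list[np.ndarray] = []
            next_mid = 0
            mol_mid: dict[int, int] = {}
            elements_mol = np.array([graph.atoms[l].element for l in graph.labels], dtype=object)

            def _new_mid() -> int:
                nonlocal next_mid
                next_mid += 1
                return next_mid - 1

            def _place_drug(m: int) -> tuple[np.ndarray, int, float]:
                mode, ang = _sample_torsion(rng, config.dihedral_modes)
                h_tor = float(rng.uniform(-180.0, 180.0))
                pos = _conform(graph, template, ang, h_tor)
                pos = pos @ _random_rotation(rng).T
                return pos, mode, ang

            for cl_i, (kind, payload) in enumerate(clusters):
                cid = cell_ids[cl_i]
                cx = np.array([
                    (cid // (n_side * n_side)) + 0.5,
                    (cid // n_side) % n_side + 0.5,
                    cid % n_side + 0.5,
                ]) * cell_len

                if kind == "water":
                    w = _water(_random_rotation(rng) @ np.array([0.0, 0.0, 1.0]),
                               np.zeros(3), float(rng.uniform(0, 360)))
                    cluster_pos = [w]
                    cluster_el = [np.array(["O", "H", "H"], dtype=object)]
                    mids = [np.full(3, _new_mid())]
                else:
                    m = payload[0]
                    pos, mode, ang = _place_drug(m)
                    mid = _new_mid()
                    mol_mid[m] = mid
                    cluster_pos = [pos]
                    cluster_el = [elements_mol]
                    mids = [np.full(nat, mid)]
                    truth_rows.append({
                        "run": run_id, "frame_time": frame_time, "mol_id": mid,
                        "hbond": bool(flags[m]), "hbond_class": str(classes[m]),
                        "dihedral_mode": mode, "dihedral_angle": ang,
                    })
                    if kind != "single":
                        h = pos[order["H1"]]
                        nn = pos[order["N1"]]
                        u = (h - nn) / np.linalg.norm(h - nn)
                        site = h + config.hbond_distance * u
                        if kind == "water_pair":
                            w = _water(u, site, float(rng.uniform(0, 360)))
                            cluster_pos.append(w)
                            cluster_el.append(np.array(["O", "H", "H"], dtype=object))
                            mids.append(np.full(3, _new_mid()))
                        else:
                            partner, acc_label = payload[1], payload[2]
                            for _attempt in range(40):
                                ppos, pmode, pang = _place_drug(partner)
                                acc = ppos[order[acc_label]]
                                centroid = ppos.mean(axis=0)
                                g = centroid - acc
                                r = _align_rotation(g, u)
                                placed = site + (ppos - acc) @ r.T
                                # margin checks: partner's own donor proton must stay
                                # clear of every acceptor, and only the planted
                                # acceptor may approach the central donor proton
                                ph = placed[order["H1"]]
                                acc_central = [pos[order["O1"]], pos[order["O2"]],
                                               pos[order["N1"]]]
                                acc_partner = [placed[order["O1"]], placed[order["O2"]],
                                               placed[order["N1"]]]
                                d_ph = min(np.linalg.norm(ph - a) for a in acc_central)
                                others = [a for a in acc_partner
                                          if np.linalg.norm(a - placed[order[acc_label]]) > 1e-9]
                                d_h = min(np.linalg.norm(h - a) for a in others)
                                if d_ph > _MIN_CLEARANCE and d_h > _MIN_CLEARANCE:
                                    break
                            else:
                                raise SyntheticError(
                                    "could not place a clash-free hydrogen-bond partner"
                                )
                            cluster_pos.append(placed)
                            cluster_el.append(elements_mol)
                            pmid = _new_mid()
                            mol_mid[partner] = pmid
                            mids.append(np.full(nat, pmid))
                            truth_rows.append({
                                "run": run_id, "frame_time": frame_time, "mol_id": pmid,
                                "hbond": False, "hbond_class": "none",
                                "dihedral_mode": pmode, "dihedral_angle": pang,
                            })

                allpos = np.concatenate(cluster_pos)
                shift = cx - allpos.mean(axis=0)
                radius = np.linalg.norm(allpos - allpos.mean(axis=0), axis=1).max()
                if 2.0 * radius + _MIN_CLEARANCE > cell_len:
                    raise SyntheticError(
                        f"box too small: cluster radius {radius:.1f} Å does not fit a "
                        f"{cell_len:.1f} Å cell with {_MIN_CLEARANCE} Å clearance"
                    )
                pos_chunks.append(allpos + shift)
                el_chunks.append(np.concatenate(cluster_el))
                mid_chunks.append(np.concatenate(mids))

            positions = np.concatenate(pos_chunks)
            # random global translation + wrapping exercises the periodic unwrapping
            positions = (positions + rng.uniform(0, box, size=3)) % box
            frame = Frame(
                lattice=np.eye(3) * box,
                positions=positions,
                elements=np.concatenate(el_chunks),
                mol_ids=np.concatenate(mid_chunks),
                frame_time=frame_time,
            )
            frames[run_id].append(frame)

    truth = pd.DataFrame(truth_rows)
    truth["env_id"] = (
        truth["run"] + ":" + truth["frame_time"].map("{:g}".format)
        + ":" + truth["mol_id"].astype(str)
    )
    return SyntheticWorld(frames=frames, graph=graph, template=template,
                          truth=truth, config=config)


# -- forward shift model -------------------------------------------------

def forward_shifts(
    world: SyntheticWorld,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Predicted shifts for every environment, from the planted truth.

    Donor proton: base + delta_hb when H-bonded, plus noise.  Tail carbons:
    base + torsion_coupling * cos(torsion), plus noise.  Everything else:
    base plus pure noise.
    """
    cfg = world.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)

    labels = [l for l in BASE_SHIFTS]
    n_env = len(world.truth)
    rows = []
    hbond = world.truth["hbond"].to_numpy()
    theta = np.radians(world.truth["dihedral_angle"].to_numpy())
    env_ids = world.truth["env_id"].to_numpy()
    for label in labels:
        base = BASE_SHIFTS[label]
        vals = np.full(n_env, base, dtype=float)
        if label == DONOR_H:
            vals += cfg.delta_hb * hbond
        if label in TORSION_COUPLED:
            vals += cfg.torsion_coupling * np.cos(theta)
        vals += rng.normal(0.0, cfg.noise_sd, size=n_env)
        rows.append(pd.DataFrame({
            "env_id": env_ids, "atom_label": label, "value_ppm": vals, "kind": "shift",
        }))
    return pd.concat(rows, ignore_index=True)


def subpopulation_distributions(
    shifts: pd.DataFrame,
    member_env_ids,
    graph: MoleculeGraph,
) -> list[ShiftDistribution]:
    """Gaussian distributions fitted to a subpopulation's predicted shifts.

    Stands in for the experimentally fitted distributions: mean and standard
    deviation of each assigned label over the given environments.
    """
    members = set(member_env_ids)
    sub = shifts[shifts["env_id"].isin(members)]
    out = []
    for label, grp in sub.groupby("atom_label"):
        if label not in graph.atoms or not graph.atoms[label].assigned:
            continue
        out.append(ShiftDistribution(
            atom_label=str(label),
            nucleus=graph.atoms[label].nucleus,
            mean=float(grp["value_ppm"].mean()),
            width=float(max(grp["value_ppm"].std(ddof=1), 1e-6)),
        ))
    return out


def write_workspace(world: SyntheticWorld, shifts: pd.DataFrame, out_dir: str | Path) -> None:
    """Write a ready-to-run workspace: frames, topology, truth and shifts."""
    from .ensemble import write_extxyz
    from .molecule import save_molecule

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for run_id, frs in world.frames.items():
        write_extxyz(frs, out / f"{run_id}.extxyz")
    save_molecule(world.graph, out / "molecule.json")
    world.truth.to_csv(out / "truth.csv", index=False)
    shifts.to_csv(out / "shifts.csv", index=False)
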