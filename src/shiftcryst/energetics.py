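"""Local-environment formation energies with a pluggable energy backend.

The formation energy of an environment is the energy of the full cluster
minus the energy of the cluster with the central molecule removed; it
bundles the central molecule's conformational energy with its
intermolecular interaction energy.  The shipped backend is a deliberately
simple pair potential (a shallow Morse-type well per element pair plus a
directional hydrogen-bond term) — sufficient for testing the pipeline; a
real quantum backend plugs in behind the same contract.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .ensemble import MolecularEnvironment

__all__ = [
    "EnergyBackend",
    "ToyBackend",
    "CommandBackend",
    "EnergyRecord",
    "formation_energy",
    "compare_energy_sets",
]


class EnergeticsError(RuntimeError):
    pass


class EnergyBackend(Protocol):
    """Contract: deterministic total energy of a cluster in kJ/mol."""

    name: str

    def evaluate(self, positions: np.ndarray, elements: Sequence[str]) -> float: ...


@dataclass(frozen=True)
class EnergyRecord:
    env_id: str
    e_full: float            # kJ/mol
    e_minus_central: float   # kJ/mol

    @property
    def e_formation(self) -> float:
        return self.e_full - self.e_minus_central


# -- toy backend ---------------------------------------------------------

_VDW_R0 = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52}
_EPS = {"H": 0.05, "C": 0.15, "N": 0.12, "O": 0.12}  # kJ/mol, deliberately mild


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class ToyBackend:
    """Pairwise Morse wells plus a directional N/O-H...N/O hydrogen-bond well.

    The Morse form stays finite at r = 0, so no bonded-pair exclusion is
    needed; bonded contributions are conformation-independent offsets that
    cancel in set-vs-set comparisons.  The hydrogen-bond term contributes
    -hbond_well for an H (covalently bound to N/O within ``covalent_max``)
    whose acceptor N/O sits within the well range at a D-H...A angle of at
    least ``min_angle``; it switches smoothly to zero between ``r_on`` and
    ``r_off``.
    """

    name: str = "toy"
    hbond_well: float = 5.0     # kJ/mol
    r_on: float = 2.2           # Å, full well up to here
    r_off: float = 2.6          # Å, zero beyond
    min_angle: float = 120.0    # degrees
    covalent_max: float = 1.25  # Å, H-donor covalent detection
    morse_a: float = 1.6        # 1/Å

    def evaluate(self, positions: np.ndarray, elements: Sequence[str]) -> float:
        positions = np.asarray(positions, dtype=float)
        elements = list(elements)
        n = len(positions)
        if n == 0:
            return 0.0
        d = np.linalg.norm(positions[None, :, :] - positions[:, None, :], axis=-1)

        eps = np.array([_EPS.get(e, 0.1) for e in elements])
        r0 = np.array([_VDW_R0.get(e, 1.5) for e in elements])
        eps_ij = np.sqrt(eps[:, None] * eps[None, :])
        r0_ij = r0[:, None] + r0[None, :]
        iu = np.triu_indices(n, k=1)
        morse = eps_ij[iu] * (
            (1.0 - np.exp(-self.morse_a * (d[iu] - r0_ij[iu]))) ** 2 - 1.0
        )
        energy = float(morse.sum())

        # directional hydrogen-bond wells
        is_h = np.array([e == "H" for e in elements])
        is_acc = np.array([e in ("N", "O") for e in elements])
        for i in np.flatnonzero(is_h):
            dcol = d[i]
            donors = np.flatnonzero(is_acc & (dcol < self.covalent_max))
            if len(donors) == 0:
                continue
            j = donors[np.argmin(dcol[donors])]
            cands = np.flatnonzero(is_acc & (dcol <= self.r_off) & (dcol >= self.covalent_max))
            for k in cands:
                u = positions[j] - positions[i]
                v = positions[k] - positions[i]
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang < self.min_angle:
                    continue
                s = 1.0 - _smoothstep((dcol[k] - self.r_on) / (self.r_off - self.r_on))
                energy -= self.hbond_well * float(s)
        return energy


@dataclass
class CommandBackend:
    """External-command backend: writes an XYZ file, runs a command, reads kJ/mol.

    ``command`` is a shell template with ``{input}`` substituted; the command
    must print a single number (in ``unit_to_kj`` units) on stdout.
    """

    command: str
    name: str = "command"
    unit_to_kj: float = 1.0

    def evaluate(self, positions: np.ndarray, elements: Sequence[str]) -> float:
        with tempfile.NamedTemporaryFile("w", suffix=".xyz", delete=False) as fh:
            fh.write(f"{len(positions)}\n\n")
            for el, (x, y, z) in zip(elements, positions):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")
            name = fh.name
        try:
            out = subprocess.run(
                shlex.split(self.command.format(input=name)),
                capture_output=True, text=True, check=True,
            ).stdout.strip().split()
            return float(out[-1]) * self.unit_to_kj
        except (subprocess.CalledProcessError, ValueError, IndexError) as exc:
            raise EnergeticsError(f"external backend failed: {exc}") from exc
        finally:
            Path(name).unlink(missing_ok=True)


def formation_energy(env: MolecularEnvironment, backend: EnergyBackend) -> EnergyRecord:
    """Backend energy of the cluster with vs without the central molecule."""
    if env.n_atoms == 0:
        raise EnergeticsError(f"environment {env.env_id} is empty")
    try:
        e_full = backend.evaluate(env.positions, list(env.elements))
        mask = ~env.central_mask
        e_rest = backend.evaluate(env.positions[mask], list(env.elements[mask]))
    except EnergeticsError:
        raise
    except Exception as exc:  # propagate with context
        raise EnergeticsError(f"backend {backend.name!r} failed on {env.env_id}: {exc}") from exc
    return EnergyRecord(env.env_id, float(e_full), float(e_rest))


def compare_energy_sets(
    nmr_records: Sequence[EnergyRecord],
    baseline_records: Sequence[EnergyRecord],
    bin_values_nmr: Sequence[float] | None = None,
    bin_values_baseline: Sequence[float] | None = None,
    bin_edges: Sequence[float] | None = None,
    min_count: int = 5,
) -> pd.DataFrame:
    """Per-bin formation-energy summary of the selected vs the baseline set.

    Without binning the whole set is one bin.  With binning (e.g. by a
    torsion angle) both sets must supply one bin value per record; bins with
    fewer than ``min_count`` records on either side are flagged.  The
    difference columns are NMR minus baseline (negative = NMR set more
    stable).
    """
    if len(nmr_records) == 0 or len(baseline_records) == 0:
        raise EnergeticsError("both record sets must be non-empty")

    e_nmr = np.array([r.e_formation for r in nmr_records])
    e_base = np.array([r.e_formation for r in baseline_records])

    if bin_edges is None:
        rows = [{
            "bin_left": -np.inf, "bin_right": np.inf,
            "mean_NMR": e_nmr.mean(), "median_NMR": float(np.median(e_nmr)),
            "count_NMR": len(e_nmr),
            "mean_MD": e_base.mean(), "median_MD": float(np.median(e_base)),
            "count_MD": len(e_base),
        }]
    else:
        if bin_values_nmr is None or bin_values_baseline is None:
            raise EnergeticsError("binned comparison needs bin values for both sets")
        edges = np.asarray(bin_edges, dtype=float)
        iv_n = np.digitize(np.asarray(bin_values_nmr, dtype=float), edges) - 1
        iv_b = np.digitize(np.asarray(bin_values_baseline, dtype=float), edges) - 1
        rows = []
        any_shared = False
        for b in range(len(edges) - 1):
            sn = e_nmr[iv_n == b]
            sb = e_base[iv_b == b]
            if len(sn) and len(sb):
                any_shared = True
            rows.append({
                "bin_left": edges[b], "bin_right": edges[b + 1],
                "mean_NMR": sn.mean() if len(sn) else np.nan,
                "median_NMR": float(np.median(sn)) if len(sn) else np.nan,
                "count_NMR": len(sn),
                "mean_MD": sb.mean() if len(sb) else np.nan,
                "median_MD": float(np.median(sb)) if len(sb) else np.nan,
                "count_MD": len(sb),
            })
        if not any_shared:
            raise EnergeticsError("the two sets share no occupied bin")
    df = pd.DataFrame(rows)
    df["mean_diff"] = df["mean_NMR"] - df["mean_MD"]
    df["median_diff"] = df["median_NMR"] - df["median_MD"]
    df["low_count"] = (df["count_NMR"] < min_count) | (df["count_MD"] < min_count)
    return df
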