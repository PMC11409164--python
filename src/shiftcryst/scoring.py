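"""Score predicted shifts against experimental distributions and select.

Each predicted shift contributes a two-sided Gaussian tail probability
``p_i = erfc(|delta - mu| / (s * sqrt(2)))``; an environment's match
probability is the geometric mean of its per-shift probabilities.  The
"NMR set" is the subset above a probability threshold (equivalently the
top-k or top-fraction of the pool).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .molecule import ShellSelection
from .spectra import ShiftDistribution

__all__ = [
    "DEFAULT_OFFSETS",
    "SelectionResult",
    "shielding_to_shift",
    "shift_probability",
    "global_probability",
    "score_environments",
    "select",
    "sample_baseline",
]

#: shielding -> shift conversion offsets (ppm) per nucleus
DEFAULT_OFFSETS: dict[str, float] = {"1H": 30.78, "13C": 170.04}


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class SelectionResult:
    env_id: str
    p_global: float
    selected: bool
    threshold: float
    subset_used: str = "all"


def shielding_to_shift(
    sigma_iso: float | np.ndarray,
    nucleus: str,
    offsets: Mapping[str, float] | None = None,
) -> float | np.ndarray:
    """Convert an isotropic shielding to a chemical shift: delta = c - sigma."""
    offsets = DEFAULT_OFFSETS if offsets is None else offsets
    if nucleus not in offsets:
        raise ScoringError(f"no shielding offset registered for nucleus {nucleus!r}")
    return offsets[nucleus] - sigma_iso


def shift_probability(delta_pred: float | np.ndarray, dist: ShiftDistribution):
    """Two-sided tail probability that the prediction matches the distribution."""
    if getattr(dist, "width", 1.0) <= 0:
        raise ScoringError(f"distribution for {dist.atom_label!r} has non-positive width")
    return dist.tail_probability(delta_pred)


def global_probability(p_list: Sequence[float] | np.ndarray) -> float:
    """Geometric mean of per-shift probabilities."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ScoringError("global probability of an empty probability list")
    if np.any((p < 0) | (p > 1)):
        raise ScoringError("probabilities must lie in [0, 1]")
    if np.any(p == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(p))))


def score_environments(
    predictions: pd.DataFrame,
    dists: Sequence[ShiftDistribution],
    shell: ShellSelection | None = None,
    offsets: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-environment match probability against the assigned distributions.

    Parameters
    ----------
    predictions:
        Columns ``env_id``, ``atom_label``, ``value_ppm`` and optionally
        ``kind`` ("shift", the default, or "shielding"; shieldings are
        converted with the per-nucleus offsets).  Several rows for the same
        (env_id, atom_label) — chemically equivalent protons — are averaged
        before scoring.
    dists:
        The experimental distributions.  Atoms with a prediction but no
        distribution are ignored; a distribution with no prediction for some
        environment is an error (a data defect, not a partial assignment).
    shell:
        Optional bond-shell restriction ("W-n" scoring): only distributions
        whose label lies in ``shell.members`` are used.

    Returns
    -------
    DataFrame with columns ``env_id``, ``p_global``, ``n_shifts``.
    """
    required = {"env_id", "atom_label", "value_ppm"}
    if not required <= set(predictions.columns):
        raise ScoringError(f"predictions must have columns {sorted(required)}")

    dist_map = {d.atom_label: d for d in dists}
    if shell is not None:
        used = set(dist_map) & set(shell.members)
        if not used:
            raise ScoringError("bond shell shares no labels with the assigned distributions")
        dist_map = {l: dist_map[l] for l in used}

    df = predictions[predictions["atom_label"].isin(dist_map)].copy()
    if "kind" in df.columns:
        is_shield = df["kind"] == "shielding"
        if is_shield.any():
            nuc = df.loc[is_shield, "atom_label"].map(lambda l: dist_map[l].nucleus)
            off = nuc.map(DEFAULT_OFFSETS if offsets is None else dict(offsets))
            if off.isna().any():
                missing = sorted(nuc[off.isna()].unique())
                raise ScoringError(f"no shielding offset registered for nuclei {missing}")
            df.loc[is_shield, "value_ppm"] = off - df.loc[is_shield, "value_ppm"]

    # average chemically equivalent protons (duplicate env/label rows)
    df = df.groupby(["env_id", "atom_label"], as_index=False)["value_ppm"].mean()

    counts = df.groupby("env_id")["atom_label"].nunique()
    n_expected = len(dist_map)
    short = counts[counts < n_expected]
    if len(short):
        missing_env = short.index[0]
        have = set(df.loc[df["env_id"] == missing_env, "atom_label"])
        raise ScoringError(
            f"environment {missing_env!r} lacks predictions for assigned atoms "
            f"{sorted(set(dist_map) - have)}"
        )

    mu = df["atom_label"].map(lambda l: dist_map[l].mean)
    sd = df["atom_label"].map(lambda l: dist_map[l].width)
    df["log_p"] = np.log(
        np.clip(erfc(np.abs(df["value_ppm"] - mu) / (sd * np.sqrt(2.0))), 1e-300, 1.0)
    )
    agg = df.groupby("env_id").agg(log_p=("log_p", "mean"), n_shifts=("atom_label", "size"))
    agg["p_global"] = np.exp(agg["log_p"])
    return agg.reset_index()[["env_id", "p_global", "n_shifts"]]


def select(
    scores: pd.DataFrame,
    mode: str = "threshold",
    p_star: float | None = None,
    k: int | None = None,
    fraction: float | None = None,
    subset_used: str = "all",
) -> pd.DataFrame:
    """Select the NMR set from per-environment probabilities.

    Modes: ``threshold`` keeps p > p_star; ``top_k`` keeps the k largest
    (reporting the implied threshold as the probability of the last kept
    environment); ``top_fraction`` keeps the round(fraction * N) largest.
    Ties at the top-k boundary are broken by env_id after a stable sort.
    """
    if not {"env_id", "p_global"} <= set(scores.columns):
        raise ScoringError("scores must have columns env_id, p_global")
    if not np.all(np.isfinite(scores["p_global"])):
        raise ScoringError("probabilities must be finite")
    n = len(scores)
    ordered = scores.sort_values(
        by=["p_global", "env_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)

    if mode == "threshold":
        if p_star is None:
            raise ScoringError("threshold mode requires p_star")
        threshold = float(p_star)
        selected = ordered["p_global"] > threshold
    elif mode in ("top_k", "top_fraction"):
        if mode == "top_fraction":
            if fraction is None:
                raise ScoringError("top_fraction mode requires fraction")
            k = int(round(fraction * n))
        if k is None:
            raise ScoringError("top_k mode requires k")
        if k > n:
            raise ScoringError(f"cannot select top {k} of {n} environments")
        selected = pd.Series(np.arange(n) < k, index=ordered.index)
        threshold = float(ordered["p_global"].iloc[k - 1]) if k > 0 else float("inf")
    else:
        raise ScoringError(f"unknown selection mode {mode!r}")

    out = ordered.copy()
    out["selected"] = selected.to_numpy()
    out["threshold"] = threshold
    out["subset_used"] = subset_used
    return out


def sample_baseline(
    env_ids_by_run: Mapping[str, Sequence[str]],
    n_per_run: int,
    seed: int | np.random.Generator,
) -> list[str]:
    """Uniform without-replacement sample of n_per_run environments per run."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[str] = []
    for run in sorted(env_ids_by_run):
        ids = list(env_ids_by_run[run])
        if len(ids) < n_per_run:
            raise ScoringError(
                f"run {run!r} has only {len(ids)} environments, need {n_per_run}"
            )
        pick = rng.choice(len(ids), size=n_per_run, replace=False)
        out.extend(ids[i] for i in sorted(pick))
    return out
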