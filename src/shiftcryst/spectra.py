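"""Fit sums of Gaussians to 1D spectra and derive per-atom shift distributions.

The fit is seeded by a crystalline assignment: each fitted component is
assigned the label whose seed (crystalline) shift lies closest to the fitted
mean.  Proton distributions are then derived from heteronuclear correlation
peaks picked at the fitted carbon means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Spectrum1D",
    "ShiftDistribution",
    "TabulatedShiftDistribution",
    "FitError",
    "fit_gaussian_mixture",
    "assign_proton_distributions",
    "read_spectrum",
    "write_distributions",
    "read_distributions",
]

log = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when the mixture fit fails to converge."""

    def __init__(self, message: str, residual_norm: float | None = None) -> None:
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass
class Spectrum1D:
    """A 1D trace: strictly monotone ppm grid with non-negative intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    nucleus: str = "13C"

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1D arrays of equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm grid must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def spacing(self) -> float:
        return float(np.abs(np.diff(self.ppm)).min())


@dataclass
class ShiftDistribution:
    """A Gaussian experimental shift distribution for one assigned resonance."""

    atom_label: str
    nucleus: str
    mean: float          # ppm
    width: float         # ppm standard deviation
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be positive, got {self.width}")

    def tail_probability(self, delta: float | np.ndarray) -> float | np.ndarray:
        """Two-sided Gaussian tail probability of a predicted shift."""
        from scipy.special import erfc

        z = np.abs(np.asarray(delta, dtype=float) - self.mean) / (self.width * np.sqrt(2.0))
        out = erfc(z)
        return float(out) if out.ndim == 0 else out


@dataclass
class TabulatedShiftDistribution:
    """An empirically tabulated distribution usable in place of a Gaussian.

    The match probability is the two-sided tail of the empirical CDF:
    ``2 * min(F(x), 1 - F(x))``, clipped to [0, 1].
    """

    atom_label: str
    nucleus: str
    ppm: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        cdf = np.cumsum(self.density)
        if cdf[-1] <= 0:
            raise ValueError("density integrates to zero")
        self._cdf = cdf / cdf[-1]

    @property
    def mean(self) -> float:
        w = self.density / self.density.sum()
        return float(np.sum(self.ppm * w))

    def tail_probability(self, delta: float | np.ndarray) -> float | np.ndarray:
        f = np.interp(np.asarray(delta, dtype=float), self.ppm, self._cdf, left=0.0, right=1.0)
        out = np.clip(2.0 * np.minimum(f, 1.0 - f), 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


def _mixture(ppm: np.ndarray, params: np.ndarray, baseline: bool) -> np.ndarray:
    """Sum of Gaussians; params = [a1, mu1, s1, a2, ...] (+ [b0, b1])."""
    k = (len(params) - (2 if baseline else 0)) // 3
    out = np.zeros_like(ppm)
    for i in range(k):
        a, mu, s = params[3 * i: 3 * i + 3]
        out += a * np.exp(-0.5 * ((ppm - mu) / s) ** 2)
    if baseline:
        b0, b1 = params[-2:]
        out += b0 + b1 * (ppm - ppm.mean())
    return out


def fit_gaussian_mixture(
    spectrum: Spectrum1D,
    seed_means: Sequence[tuple[str, float]],
    width_init: float | None = None,
    baseline: bool = False,
    max_nfev: int = 20000,
) -> list[ShiftDistribution]:
    """Least-squares fit of a sum of Gaussians seeded at crystalline shifts.

    Each fitted component is labeled with the seed whose shift is closest to
    the fitted mean (ties broken toward the first seed in input order).
    Components whose fitted width collapses below the grid spacing are kept
    but flagged with a warning.
    """
    if len(seed_means) == 0:
        raise ValueError("at least one seed mean is required")
    lo, hi = float(spectrum.ppm.min()), float(spectrum.ppm.max())
    for label, mu in seed_means:
        if not (lo <= mu <= hi):
            raise ValueError(f"seed {label!r} at {mu} ppm is outside the window [{lo}, {hi}]")

    span = hi - lo
    if width_init is None:
        width_init = max(span / (10.0 * len(seed_means)), 2.0 * spectrum.spacing)

    p0, lower, upper = [], [], []
    for _, mu in seed_means:
        a0 = max(float(np.interp(mu, spectrum.ppm[np.argsort(spectrum.ppm)],
                                 spectrum.intensity[np.argsort(spectrum.ppm)])), 1e-6)
        p0 += [a0, mu, width_init]
        lower += [0.0, lo, spectrum.spacing / 10.0]
        upper += [np.inf, hi, span]
    if baseline:
        p0 += [0.0, 0.0]
        lower += [-np.inf, -np.inf]
        upper += [np.inf, np.inf]

    res = least_squares(
        lambda p: _mixture(spectrum.ppm, p, baseline) - spectrum.intensity,
        x0=np.array(p0), bounds=(np.array(lower), np.array(upper)), max_nfev=max_nfev,
    )
    if not res.success:
        raise FitError(
            f"mixture fit did not converge: {res.message}",
            residual_norm=float(np.linalg.norm(res.fun)),
        )

    k = len(seed_means)
    fitted = [(res.x[3 * i], res.x[3 * i + 1], res.x[3 * i + 2]) for i in range(k)]
    seeds = list(seed_means)
    dists: list[ShiftDistribution] = []
    for a, mu, s in fitted:
        nearest = min(seeds, key=lambda lm: abs(lm[1] - mu))
        if s < spectrum.spacing:
            warnings.warn(
                f"fitted width {s:.4g} ppm for {nearest[0]!r} collapsed below "
                f"the grid spacing {spectrum.spacing:.4g} ppm",
                stacklevel=2,
            )
        dists.append(
            ShiftDistribution(
                atom_label=nearest[0], nucleus=spectrum.nucleus,
                mean=float(mu), width=float(max(s, 1e-12)), amplitude=float(a),
            )
        )
    return dists


def default_proton_label(carbon_label: str) -> str:
    """C10 -> H10; used when the correlation table carries no proton label."""
    if carbon_label.startswith("C"):
        return "H" + carbon_label[1:]
    return "H_" + carbon_label


def assign_proton_distributions(
    hetcor_peaks: pd.DataFrame,
    carbon_dists: Sequence[ShiftDistribution],
    window: float = 2.0,
    default_width: float = 0.5,
    proton_label=default_proton_label,
) -> list[ShiftDistribution]:
    """Derive 1H distributions from correlation peaks at each carbon mean.

    ``hetcor_peaks`` needs columns ``ppm_13C``, ``ppm_1H``, ``intensity``
    and optionally ``width_1H`` (ppm standard deviation of the 1H profile;
    ``default_width`` is used when absent).  For each carbon distribution
    the peak whose 13C coordinate is nearest the fitted mean (within
    ``window`` ppm) supplies the proton mean; ties are broken toward higher
    intensity, then lower 1H ppm.  Carbons with no peak in the window are
    skipped with a log message.
    """
    required = {"ppm_13C", "ppm_1H", "intensity"}
    if not required <= set(hetcor_peaks.columns):
        raise ValueError(f"hetcor_peaks must have columns {sorted(required)}")

    out: list[ShiftDistribution] = []
    for cd in carbon_dists:
        d13 = (hetcor_peaks["ppm_13C"] - cd.mean).abs()
        near = hetcor_peaks[d13 <= window]
        if near.empty:
            log.info("no correlation peak within %.2f ppm of %s (%.2f ppm); proton unassigned",
                     window, cd.atom_label, cd.mean)
            continue
        key = near.assign(_d=d13[near.index]).sort_values(
            by=["_d", "intensity", "ppm_1H"], ascending=[True, False, True],
            kind="stable",
        )
        peak = key.iloc[0]
        width = float(peak["width_1H"]) if "width_1H" in near.columns and np.isfinite(
            peak.get("width_1H", np.nan)) else default_width
        out.append(
            ShiftDistribution(
                atom_label=proton_label(cd.atom_label), nucleus="1H",
                mean=float(peak["ppm_1H"]), width=width,
                amplitude=float(peak["intensity"]),
            )
        )
    return out


# -- I/O -----------------------------------------------------------------

def read_spectrum(path: str | Path, nucleus: str = "13C") -> Spectrum1D:
    """Read a two-column (ppm, intensity) text trace."""
    data = np.loadtxt(path)
    return Spectrum1D(ppm=data[:, 0], intensity=data[:, 1], nucleus=nucleus)


def write_distributions(dists: Sequence[ShiftDistribution], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"atom_label": d.atom_label, "nucleus": d.nucleus,
             "mean_ppm": d.mean, "sd_ppm": d.width, "amplitude": d.amplitude}
            for d in dists
        ]
    ).to_csv(path, index=False)


def read_distributions(path: str | Path) -> list[ShiftDistribution]:
    df = pd.read_csv(path)
    return [
        ShiftDistribution(
            atom_label=row.atom_label, nucleus=row.nucleus,
            mean=float(row.mean_ppm), width=float(row.sd_ppm),
            amplitude=float(getattr(row, "amplitude", 1.0)),
        )
        for row in df.itertuples()
    ]
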