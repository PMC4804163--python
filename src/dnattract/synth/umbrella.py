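"""Synthetic umbrella-sampling window series.

Emulates the inter-DNA-distance time series recorded in harmonic umbrella
windows: for window center d_i and force constant k the sampled density is

    p_i(d) ∝ exp(−[n_turns·ΔG(d) + (k/2)(d−d_i)²] / k_B T)

with ΔG the per-turn reference profile.  Samples are drawn by inverse-CDF
sampling on a fine distance grid (0.01 A), i.i.d. by default; an optional
AR(1) mode (Gaussian copula on the sample ranks) produces serially
correlated series for stress-testing block-bootstrap error bars.

The default protocol follows the study design: 20 windows at 23…42 A with
1-A spacing and k = 2,000 kJ mol⁻¹ nm⁻² = 4.780 kcal mol⁻¹ A⁻².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ..constants import KBT_300, K_UMBRELLA_KCAL
from ..refpmf import ReferencePMF

__all__ = [
    "UmbrellaWindow",
    "ResolutionError",
    "DEFAULT_WINDOW_CENTERS",
    "sample_umbrella_series",
]

#: 23, 24, …, 42 A
DEFAULT_WINDOW_CENTERS = tuple(float(c) for c in range(23, 43))

GRID_LO, GRID_HI, GRID_STEP = 15.0, 50.0, 0.01


class ResolutionError(ValueError):
    """Bias so stiff that the discretized window density degenerates."""


@dataclass
class UmbrellaWindow:
    """One umbrella window: bias parameters plus the sampled series."""

    center: float  # A
    force_constant: float  # kcal mol^-1 A^-2
    samples: np.ndarray  # distances, A
    sample_interval_ps: float = 2.0  # metadata only

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        if self.samples.size < 1:
            raise ValueError("window must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def bias_energy(self, d) -> np.ndarray:
        """Harmonic bias w(d) = (k/2)(d − center)², kcal/mol."""
        d = np.asarray(d, dtype=float)
        return 0.5 * self.force_constant * (d - self.center) ** 2


def _window_density(
    pmf: ReferencePMF, turns: float, center: float, k: float,
    kbt: float, grid: np.ndarray,
) -> np.ndarray:
    u = turns * pmf.profile(grid) + 0.5 * k * (grid - center) ** 2
    logp = -(u - u.min()) / kbt
    p = np.exp(logp)
    z = p.sum()
    if (p > 0).sum() < 2:
        raise ResolutionError(
            f"window at {center} A: density has support on fewer than two "
            "grid cells; refine the grid or soften the bias"
        )
    return p / z


def _inverse_cdf_draw(
    p: np.ndarray, grid: np.ndarray, u: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, u, side="left")
    # uniform jitter within the grid cell avoids a 0.01-A comb in histograms
    jitter = rng.uniform(-0.5, 0.5, size=idx.size) * GRID_STEP
    return grid[idx] + jitter


def sample_umbrella_series(
    pmf: ReferencePMF,
    turns: float,
    windows: tuple[float, ...] | list[float] = DEFAULT_WINDOW_CENTERS,
    k: float = K_UMBRELLA_KCAL,
    n_samples: int = 20000,
    seed: int = 0,
    *,
    kbt: float = KBT_300,
    ar1_rho: float | None = None,
    sample_interval_ps: float = 2.0,
) -> list[UmbrellaWindow]:
    """Draw biased distance series for every umbrella window.

    Parameters
    ----------
    pmf:
        Per-turn reference profile.
    turns:
        Helical turns per periodic unit; the sampled energy is
        ``turns * pmf(d)`` so that the generator works in absolute
        kcal/mol while the profile is per-turn.
    windows:
        Window centers (A), non-empty.
    k:
        Harmonic force constant, kcal/mol/A².
    n_samples:
        Samples per window (>= 100).
    seed:
        Seed; one independent child stream per window, so the output is
        bit-reproducible and windows are order-independent.
    ar1_rho:
        If given, samples are serially correlated through a Gaussian
        copula with lag-1 autocorrelation ``ar1_rho`` instead of i.i.d.
    """
    if len(windows) == 0:
        raise ValueError("windows must be non-empty")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if turns <= 0:
        raise ValueError("turns must be positive")
    grid = np.arange(GRID_LO, GRID_HI + 0.5 * GRID_STEP, GRID_STEP)
    streams = np.random.SeedSequence(seed).spawn(len(windows))
    out: list[UmbrellaWindow] = []
    for center, ss in zip(windows, streams):
        rng = np.random.default_rng(ss)
        p = _window_density(pmf, turns, float(center), k, kbt, grid)
        if ar1_rho is None:
            u = rng.uniform(0.0, 1.0, size=n_samples)
        else:
            rho = float(ar1_rho)
            if not -1.0 < rho < 1.0:
                raise ValueError("ar1_rho must lie in (-1, 1)")
            z = np.empty(n_samples)
            z[0] = rng.standard_normal()
            innov = rng.standard_normal(n_samples - 1) * np.sqrt(1 - rho ** 2)
            for t in range(1, n_samples):
                z[t] = rho * z[t - 1] + innov[t - 1]
            u = norm.cdf(z)
        d = _inverse_cdf_draw(p, grid, u, rng)
        out.append(
            UmbrellaWindow(
                center=float(center),
                force_constant=float(k),
                samples=d,
                sample_interval_ps=sample_interval_ps,
            )
        )
    return out
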