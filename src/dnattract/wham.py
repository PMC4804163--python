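"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

Combines the biased distance histograms of overlapping harmonic windows
into one unbiased free-energy profile by iterating the self-consistent
WHAM equations

    P(b) = Σ_i n_i(b) / Σ_i N_i exp[(f_i − w_i(b)) / k_B T]
    f_i  = −k_B T ln Σ_b P(b) exp[−w_i(b) / k_B T]

where n_i(b) is window i's count in bin b, N_i its total count and
w_i(b) = (k_i/2)(d_b − d_i)² the bias evaluated at the bin center.  The
profile −k_B T ln P is converted to per-turn units and pinned to zero
either at the largest supported grid point or at a caller-chosen distance
(the attraction strength |ΔG_min| is defined relative to maximum
separation).

Empty bins are dropped from the grid rather than zero-filled, and the
fixed-point iteration runs in log space throughout, so very stiff biases
underflow harmlessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KBT_300
from .synth.umbrella import UmbrellaWindow

__all__ = [
    "PMFEstimate",
    "WhamError",
    "ConnectivityError",
    "wham_reconstruct",
    "bootstrap_pmf_error",
    "pmf_summary",
]


class WhamError(RuntimeError):
    pass


class ConnectivityError(WhamError):
    """Window histograms do not overlap into a single connected range."""


@dataclass
class PMFEstimate:
    """Reconstructed free-energy profile and its summary statistics."""

    grid: np.ndarray  # bin centers, A, strictly increasing
    dG: np.ndarray  # kcal/mol per turn, 0 at the pinning point
    dG_err: np.ndarray | None  # bootstrap s.d. per grid point
    d_min_hat: float  # A, argmin of dG
    depth_hat: float  # |ΔG_min|, kcal/mol per turn
    converged: bool
    n_iterations: int
    f_window: np.ndarray  # per-window free energies, kcal/mol
    turns: float
    kbt: float
    pin: float  # distance (A) at which dG == 0
    max_delta_f: float  # final iteration change, kcal/mol

    def to_frame(self) -> pd.DataFrame:
        err = self.dG_err if self.dG_err is not None else np.full_like(self.dG, np.nan)
        return pd.DataFrame({"d_A": self.grid, "dG": self.dG, "dG_err": err})

    def summary(self) -> dict:
        return {
            "depth_hat": float(self.depth_hat),
            "d_min_hat": float(self.d_min_hat),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "pin": float(self.pin),
        }


def _histogram_windows(
    windows: list[UmbrellaWindow], bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    e0 = np.floor(lo / bin_width) * bin_width
    e1 = np.ceil(hi / bin_width) * bin_width
    edges = np.arange(e0, e1 + 0.5 * bin_width, bin_width)
    counts = np.stack(
        [np.histogram(w.samples, bins=edges)[0] for w in windows]
    ).astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def _check_connectivity(counts: np.ndarray) -> None:
    """All windows must chain together through shared occupied bins."""
    n_win = counts.shape[0]
    occupied = counts > 0
    reached = np.zeros(n_win, dtype=bool)
    reached[0] = True
    frontier_bins = occupied[0].copy()
    for _ in range(n_win):
        new = ~reached & (occupied & frontier_bins[None, :]).any(axis=1)
        if not new.any():
            break
        reached |= new
        frontier_bins |= occupied[new].any(axis=0)
    if not reached.all():
        raise ConnectivityError(
            f"windows {np.flatnonzero(~reached).tolist()} share no occupied "
            "bins with the rest; the sampled ranges do not overlap"
        )


def wham_reconstruct(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.2,
    tol: float = 1e-7,
    max_iter: int = 200000,
    turns: float = 1.0,
    *,
    kbt: float = KBT_300,
    pin: float | str = "max",
    depth_range: tuple[float, float] | None = None,
    f_init: np.ndarray | None = None,
) -> PMFEstimate:
    """Reconstruct the per-turn free-energy profile from umbrella windows.

    Parameters
    ----------
    windows:
        At least two windows with overlapping sampled ranges (a single
        window is allowed and reduces to the unbiased log-histogram when
        its force constant is negligible).
    bin_width:
        Histogram bin width (A).
    tol:
        Convergence threshold on max_i |Δf_i| (kcal/mol).
    max_iter:
        Iteration cap; on reaching it the estimate is returned with
        ``converged=False``.
    turns:
        Helical turns per periodic unit; the absolute profile is divided
        by this to give per-turn units.
    pin:
        ``"max"`` pins ΔG=0 at the largest supported grid point; a float
        pins at the grid point nearest that distance.
    depth_range:
        Optional (lo, hi) in A restricting where depth_hat/d_min_hat are
        measured; default is the whole grid.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not windows:
        raise ValueError("need at least one window")
    counts, centers = _histogram_windows(windows, bin_width)
    if len(windows) >= 2:
        _check_connectivity(counts)
    support = counts.sum(axis=0) > 0
    counts = counts[:, support]
    centers = centers[support]

    beta = 1.0 / kbt
    n_i = counts.sum(axis=1)  # (W,)
    m_b = counts.sum(axis=0)  # (B,)
    bias = np.stack([w.bias_energy(centers) for w in windows])  # (W, B)
    log_n = np.log(n_i)
    log_m = np.log(m_b)
    neg_beta_w = -beta * bias

    f = np.zeros(len(windows)) if f_init is None else np.asarray(f_init, float)
    delta = np.inf
    it = 0
    converged = False
    log_p = log_m.copy()
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_i [ln N_i + beta f_i - beta w_ib]
        a = log_n[:, None] + beta * f[:, None] + neg_beta_w
        log_denom = logsumexp(a, axis=0)
        log_p = log_m - log_denom
        f_new = -kbt * logsumexp(log_p[None, :] + neg_beta_w, axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations "
            f"(max|Δf| = {delta:.3e} kcal/mol)",
            RuntimeWarning,
        )

    dg_abs = -kbt * log_p  # up to a constant
    dg = dg_abs / turns
    if pin == "max":
        pin_idx = len(centers) - 1
    else:
        pin_idx = int(np.argmin(np.abs(centers - float(pin))))
    pin_at = float(centers[pin_idx])
    dg = dg - dg[pin_idx]

    if depth_range is not None:
        sel = (centers >= depth_range[0]) & (centers <= depth_range[1])
        if not sel.any():
            raise ValueError("depth_range excludes every grid point")
    else:
        sel = np.ones_like(centers, dtype=bool)
    i_min = int(np.flatnonzero(sel)[np.argmin(dg[sel])])
    depth_hat = max(0.0, -float(dg[i_min]))
    d_min_hat = float(centers[i_min]) if depth_hat > 0 else pin_at

    return PMFEstimate(
        grid=centers,
        dG=dg,
        dG_err=None,
        d_min_hat=d_min_hat,
        depth_hat=depth_hat,
        converged=converged,
        n_iterations=it,
        f_window=f,
        turns=turns,
        kbt=kbt,
        pin=pin_at,
        max_delta_f=delta,
    )


def bootstrap_pmf_error(
    windows: list[UmbrellaWindow],
    n_boot: int = 50,
    block_len: int = 50,
    seed: int = 0,
    *,
    bin_width: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 200000,
    turns: float = 1.0,
    kbt: float = KBT_300,
    pin: float | str = "max",
) -> np.ndarray:
    """Pointwise s.d. of the profile by within-window block bootstrap.

    Each replicate resamples every window's series in circular blocks of
    ``block_len`` frames (preserving short-range serial correlation) and
    reruns the reconstruction; profiles are aligned onto the original
    estimate's grid by linear interpolation.  Returns the s.d. array and
    leaves the original estimate untouched.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    for w in windows:
        if block_len > w.n_samples:
            raise ValueError(
                f"block_len {block_len} exceeds series length {w.n_samples}"
            )
    base = wham_reconstruct(
        windows, bin_width=bin_width, tol=tol, max_iter=max_iter,
        turns=turns, kbt=kbt, pin=pin,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    profiles = np.empty((n_boot, base.grid.size))
    for b in range(n_boot):
        resampled = []
        for w in windows:
            n = w.n_samples
            n_blocks = int(np.ceil(n / block_len))
            starts = rng.integers(0, n, size=n_blocks)
            idx = (starts[:, None] + np.arange(block_len)[None, :]) % n
            samples = w.samples[idx.ravel()[:n]]
            resampled.append(
                UmbrellaWindow(w.center, w.force_constant, samples,
                               w.sample_interval_ps)
            )
        est = wham_reconstruct(
            resampled, bin_width=bin_width, tol=tol, max_iter=max_iter,
            turns=turns, kbt=kbt, pin=pin, f_init=base.f_window,
        )
        profiles[b] = np.interp(base.grid, est.grid, est.dG)
    return profiles.std(axis=0, ddof=1)


def pmf_summary(
    estimates: PMFEstimate | dict[str, PMFEstimate],
) -> dict:
    """Summary statistics of one or several converged estimates.

    For a mapping of name → estimate, also returns pairwise depth
    differences and ratios and the depth rank order.
    """
    if isinstance(estimates, PMFEstimate):
        estimates = {"pmf": estimates}
    for name, est in estimates.items():
        if not est.converged:
            raise WhamError(
                f"estimate {name!r} is not converged "
                f"(max|Δf| = {est.max_delta_f:.3e}); refusing to summarize"
            )
    names = list(estimates)
    depths = {n: float(estimates[n].depth_hat) for n in names}
    out: dict = {
        "per_sequence": {
            n: estimates[n].summary() for n in names
        },
        "rank_order": sorted(names, key=lambda n: -depths[n]),
    }
    if len(names) > 1:
        diff = {
            a: {b: depths[a] - depths[b] for b in names} for a in names
        }
        ratio = {
            a: {
                b: (depths[a] / depths[b] if depths[b] > 0 else float("nan"))
                for b in names
            }
            for a in names
        }
        out["depth_difference"] = diff
        out["depth_ratio"] = ratio
    return out
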