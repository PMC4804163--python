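"""Mean-shift step detection for photobleaching analysis.

Binary segmentation on a piecewise-constant-plus-noise model: each segment
is recursively split at the change point that maximally reduces the
residual sum of squares; a split is kept when the step size exceeds a
multiple (3 by default) of the local noise s.d. and a BIC-style penalty.
The noise scale is estimated robustly from first differences
(MAD(diff)/sqrt(2)), which is insensitive to the steps themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Step", "estimate_noise_sd", "find_steps"]


@dataclass(frozen=True)
class Step:
    """A detected mean shift: the new segment starts at ``index``."""

    index: int
    size: float  # mean(after) - mean(before); negative for a drop

    @property
    def is_down(self) -> bool:
        return self.size < 0


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust frame-noise s.d. via the MAD of first differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return 0.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _best_split(x: np.ndarray, min_size: int) -> tuple[int, float] | None:
    """Split index (start of right segment) maximizing the RSS gain."""
    n = x.size
    if n < 2 * min_size:
        return None
    c = np.cumsum(x)
    tot = c[-1]
    k = np.arange(min_size, n - min_size + 1, dtype=float)  # left length
    left = c[min_size - 1 : n - min_size]
    right = tot - left
    # RSS gain of splitting at k: k*(n-k)/n * (meanL - meanR)^2
    gain = (left / k - right / (n - k)) ** 2 * k * (n - k) / n
    j = int(np.argmax(gain))
    return min_size + j, float(gain[j])


def find_steps(
    x: np.ndarray,
    *,
    min_size: int = 5,
    threshold_sigmas: float = 3.0,
    sigma: float | None = None,
    max_steps: int = 6,
) -> list[Step]:
    """Detect mean-shift change points by binary segmentation.

    Parameters
    ----------
    x:
        Intensity series.
    min_size:
        Minimum segment length in frames.
    threshold_sigmas:
        Minimum step size in units of the noise s.d.
    sigma:
        Noise s.d.; estimated robustly from the series when omitted.
    max_steps:
        Safety cap on the number of accepted steps.

    Returns
    -------
    list of :class:`Step`, sorted by index.
    """
    x = np.asarray(x, dtype=float)
    if sigma is None:
        sigma = estimate_noise_sd(x)
    if sigma <= 0:
        sigma = max(1e-12, float(np.std(x)) * 1e-3 + 1e-12)
    # BIC-style penalty for one extra change point on n points
    accepted: list[int] = []
    segments = [(0, x.size)]
    while segments and len(accepted) < max_steps:
        # pick the globally best split among open segments
        best = None
        for seg in segments:
            a, b = seg
            res = _best_split(x[a:b], min_size)
            if res is None:
                continue
            idx, gain = res
            if best is None or gain > best[2]:
                best = (seg, a + idx, gain)
        if best is None:
            break
        seg, split, gain = best
        a, b = seg
        n_seg = b - a
        penalty = (threshold_sigmas ** 2) * sigma ** 2 + \
            2.0 * sigma ** 2 * np.log(max(n_seg, 2))
        mean_l = x[a:split].mean()
        mean_r = x[split:b].mean()
        if gain < penalty or abs(mean_r - mean_l) < threshold_sigmas * sigma:
            segments.remove(seg)
            continue
        accepted.append(split)
        segments.remove(seg)
        segments += [(a, split), (split, b)]
    accepted.sort()
    steps = []
    bounds = [0] + accepted + [x.size]
    for i, idx in enumerate(accepted):
        lo, hi = bounds[i], bounds[i + 2]
        steps.append(Step(index=idx, size=float(x[idx:hi].mean() - x[lo:idx].mean())))
    return steps
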