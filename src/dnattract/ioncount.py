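"""Bridging-spermine statistics and cation density maps.

Coordinate convention for all operations: the midpoint between the two
helix axes is the origin and the inter-DNA axis is x, so the axes sit at
x = ±d/2, y = 0.  The bridging count N_spm is the trajectory average of
the number of spermine amine nitrogens inside a 10 A (x) × 20 A (y)
rectangular prism centred between the duplexes, spanning the full periodic
z length — the population of charge bridges that mediates the attraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .duplex import SequenceSpec, methyl_and_n7_sites
from .synth.ions import IonFrame, IonModelParams

__all__ = [
    "BridgingCount",
    "DensityMap",
    "count_bridging",
    "density_map",
    "groove_occupancy",
]


@dataclass
class BridgingCount:
    d: float  # A
    n_amine_mean: float
    n_amine_sem: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_amine_mean < 0 or self.n_amine_sem < 0:
            raise ValueError("bridging statistics must be non-negative")


@dataclass
class DensityMap:
    """Frame- and z-averaged xy number densities per species (A^-3)."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    rho: dict[str, np.ndarray]  # species -> (nx, ny) density
    projection_x: dict[str, np.ndarray]  # mean over y in [-10, 10] A
    bin_xy: float
    box_z: float
    n_frames: int


def count_bridging(
    frames: list[IonFrame],
    *,
    half_x: float = 5.0,
    half_y: float = 10.0,
) -> BridgingCount:
    """Mean ± s.e.m. of amine beads inside the central bridging prism.

    Counts beads with |x| ≤ half_x and |y| ≤ half_y (all z) per frame and
    averages over frames.  All frames must share the same inter-DNA
    distance.
    """
    if not frames:
        raise ValueError("frames must be non-empty")
    d0 = frames[0].d
    if any(abs(f.d - d0) > 1e-9 for f in frames):
        raise ValueError("all frames must be at the same inter-DNA distance")
    counts = np.array([
        int(np.sum(
            (np.abs(f.amine_xyz[:, 0]) <= half_x)
            & (np.abs(f.amine_xyz[:, 1]) <= half_y)
        ))
        for f in frames
    ], dtype=float)
    sem = counts.std(ddof=1) / np.sqrt(len(counts)) if len(counts) > 1 else 0.0
    return BridgingCount(
        d=d0,
        n_amine_mean=float(counts.mean()),
        n_amine_sem=float(sem),
        n_frames=len(frames),
    )


def density_map(
    frames: list[IonFrame],
    bin_xy: float = 1.0,
    *,
    extent: float | None = None,
    projection_half_y: float = 10.0,
) -> DensityMap:
    """Species-resolved xy number-density maps averaged over z and frames.

    rho has units of A^-3 (counts / bin area / box_z / n_frames), so
    integrating rho × bin area × box_z recovers the mean particle count.
    The 1D projection is the mean density over the y bins fully inside
    [-projection_half_y, +projection_half_y].
    """
    if bin_xy <= 0:
        raise ValueError("bin_xy must be positive")
    if not frames:
        raise ValueError("frames must be non-empty")
    box_z = frames[0].box_z
    species = {
        "amine": [f.amine_xyz for f in frames],
        "phosphate": [f.phosphate_xyz for f in frames],
        "sodium": [f.sodium_xyz for f in frames],
    }
    if extent is None:
        all_xy = np.vstack([
            arr[:, :2] for arrs in species.values() for arr in arrs if len(arr)
        ])
        extent = float(np.ceil(np.abs(all_xy).max() / bin_xy) * bin_xy)
    nbins = max(1, int(round(2 * extent / bin_xy)))
    edges = np.linspace(-extent, extent, nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    norm = 1.0 / (len(frames) * bin_xy * bin_xy * box_z)
    rho: dict[str, np.ndarray] = {}
    proj: dict[str, np.ndarray] = {}
    inside = (edges[:-1] >= -projection_half_y) & (edges[1:] <= projection_half_y)
    for name, arrs in species.items():
        h = np.zeros((nbins, nbins))
        for arr in arrs:
            if len(arr) == 0:
                continue
            h += np.histogram2d(arr[:, 0], arr[:, 1], bins=[edges, edges])[0]
        rho[name] = h * norm
        proj[name] = rho[name][:, inside].mean(axis=1) if inside.any() else \
            np.zeros(nbins)
    return DensityMap(
        x_centers=centers, y_centers=centers, rho=rho,
        projection_x=proj, bin_xy=bin_xy, box_z=box_z, n_frames=len(frames),
    )


def groove_occupancy(
    frames: list[IonFrame],
    seq_pair: SequenceSpec,
    *,
    capture_scale: float = 1.5,
    sigma_groove: float | None = None,
) -> float:
    """Fraction of amine beads within the groove capture radius of any N7.

    The capture radius is ``capture_scale × σ_groove`` around every purine
    N7 site of either duplex (blocked or not — blocking removes the
    attraction, so methylated duplexes score low here, which is the point
    of the comparison).  z-periodic distances.
    """
    if not frames:
        raise ValueError("frames must be non-empty")
    if sigma_groove is None:
        sigma_groove = IonModelParams().sigma_groove
    radius = capture_scale * sigma_groove
    d = frames[0].d
    sites = []
    for ax in (-d / 2.0, d / 2.0):
        sites.append(methyl_and_n7_sites(seq_pair, (ax, 0.0)).n7_xyz)
    sites = np.vstack(sites)
    if len(sites) == 0:
        return 0.0
    box_z = frames[0].box_z
    n_in = 0
    n_tot = 0
    for f in frames:
        pos = f.amine_xyz
        dxy = pos[:, None, :2] - sites[None, :, :2]
        dz = pos[:, None, 2] - sites[None, :, 2]
        dz -= box_z * np.round(dz / box_z)
        d2 = (dxy ** 2).sum(-1) + dz ** 2
        n_in += int((d2.min(axis=1) <= radius ** 2).sum())
        n_tot += len(pos)
    return n_in / n_tot
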