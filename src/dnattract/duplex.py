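"""Duplex sequence specifications and idealized major-groove site geometry.

A :class:`SequenceSpec` describes one 20-bp-scale double helix over the
alphabet ``{A, T, G, C, M}`` where ``M`` denotes 5-methylcytosine.  From it
we derive the positions of the two kinds of major-groove sites that drive
sequence-dependent polyamine adsorption:

* methyl sites — the 5-methyl groups of thymine and 5-methylcytosine,
  placed at helix radius 7 A;
* purine-N7 sites — the cation-binding hotspots of adenine and guanine,
  placed at helix radius 6 A.

An N7 site is *blocked* when any methyl group sits within a steric blocking
radius (4 A by default): in an A·T pair the thymine methyl shadows the
adenine N7, and in a G·mC pair the cytosine methyl shadows the guanine N7.
Blocked sites contribute no cation attraction in the ion model, which is the
microscopic origin of the stronger attraction between methyl-rich duplexes.

The helix is ideal B-form: rise 3.4 A per bp, twist 360°/``bp_per_turn``.
A 20-bp duplex at 10.0 bp/turn spans exactly two helical turns and 68 A,
commensurate with the periodic simulation box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "SequenceSpec",
    "SiteSet",
    "BUILTIN_SEQUENCES",
    "builtin_sequence",
    "per_turn_factor",
    "methyl_and_n7_sites",
]

#: Watson-Crick complement; M (5-methyl-C) pairs with G.
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "M": "G"}

RISE_PER_BP = 3.4  # A
R_METHYL = 7.0  # A, helix radius of the methyl site
R_N7 = 6.0  # A, helix radius of the purine-N7 site
R_BLOCK = 4.0  # A, methyl->N7 steric blocking radius
#: angular phase (degrees) of strand-2 sites relative to strand-1 sites at
#: the same base-pair step; 34° puts the intra-pair methyl 3.9 A from the
#: partner purine N7 (inside R_BLOCK) while keeping the two strands' site
#: tracks spatially distinct.
STRAND2_PHASE_DEG = 34.0


class ConfigurationError(ValueError):
    """Invalid sequence or model configuration."""


def _validate_pair(b1: str, b2: str) -> bool:
    return COMPLEMENT.get(b1) == b2 or COMPLEMENT.get(b2) == b1


def reverse_complement(strand: str) -> str:
    """Reverse complement over {A,T,G,C,M}; M maps to G (and G to C)."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(strand))
    except KeyError as exc:  # pragma: no cover - message path
        raise ConfigurationError(f"unknown base {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class SequenceSpec:
    """A duplex DNA sequence with optional 5-methylcytosine marks.

    Parameters
    ----------
    name:
        Label, e.g. ``"AT10"``.
    strand1:
        5'→3' sequence of the first strand over ``{A,T,G,C,M}``.
    strand2:
        Optional explicit second strand (5'→3').  When omitted it is the
        reverse complement of ``strand1``; supply it explicitly for
        symmetrically methylated duplexes such as (GmC)10, whose plain
        complement would lose the methyl marks.
    bp_per_turn:
        Helical repeat used for per-turn normalization and site geometry.
    """

    name: str
    strand1: str
    strand2: str | None = None
    bp_per_turn: float = 10.0

    def __post_init__(self) -> None:
        if len(self.strand1) < 1:
            raise ConfigurationError("strand1 must contain at least one base")
        bad = set(self.strand1) - set(COMPLEMENT)
        if bad:
            raise ConfigurationError(f"unknown bases in strand1: {sorted(bad)}")
        if self.bp_per_turn <= 0:
            raise ConfigurationError(
                f"bp_per_turn must be positive, got {self.bp_per_turn}"
            )
        s2 = self.strand2
        if s2 is None:
            object.__setattr__(self, "strand2", reverse_complement(self.strand1))
        else:
            if len(s2) != len(self.strand1):
                raise ConfigurationError("strand lengths differ")
            for i, (b1, b2) in enumerate(zip(self.strand1, s2[::-1])):
                if not _validate_pair(b1, b2):
                    raise ConfigurationError(
                        f"non-complementary pair {b1}·{b2} at position {i}"
                    )

    @property
    def length_bp(self) -> int:
        return len(self.strand1)

    def base_pairs(self) -> list[tuple[str, str]]:
        """(strand1 base, paired strand2 base) for each bp index."""
        assert self.strand2 is not None
        return [(b1, self.strand2[self.length_bp - 1 - i])
                for i, b1 in enumerate(self.strand1)]

    def methyl_positions(self) -> list[tuple[int, int]]:
        """(bp index, strand) of every methyl-carrying base (T or M).

        Strand is 0 for strand1, 1 for strand2; the bp index of a strand2
        base at string position j is ``length_bp - 1 - j``.
        """
        out = [(i, 0) for i, b in enumerate(self.strand1) if b in "TM"]
        assert self.strand2 is not None
        out += [
            (self.length_bp - 1 - j, 1)
            for j, b in enumerate(self.strand2)
            if b in "TM"
        ]
        return sorted(out)

    def purine_positions(self) -> list[tuple[int, int]]:
        """(bp index, strand) of every purine (A or G), i.e. every N7 site."""
        out = [(i, 0) for i, b in enumerate(self.strand1) if b in "AG"]
        assert self.strand2 is not None
        out += [
            (self.length_bp - 1 - j, 1)
            for j, b in enumerate(self.strand2)
            if b in "AG"
        ]
        return sorted(out)

    @property
    def n_methyl(self) -> int:
        return len(self.methyl_positions())


def _builtins() -> dict[str, SequenceSpec]:
    return {
        "A20": SequenceSpec("A20", "A" * 20),
        "AT10": SequenceSpec("AT10", "AT" * 10),
        "GC10": SequenceSpec("GC10", "GC" * 10),
        "G20": SequenceSpec("G20", "G" * 20),
        # symmetric methylation: both strands carry mC, all pairs G·mC
        "GmC10": SequenceSpec("GmC10", "GM" * 10, strand2="GM" * 10),
    }


BUILTIN_SEQUENCES: dict[str, SequenceSpec] = _builtins()


def builtin_sequence(name: str) -> SequenceSpec:
    try:
        return BUILTIN_SEQUENCES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown built-in sequence {name!r}; "
            f"choose from {sorted(BUILTIN_SEQUENCES)}"
        ) from None


def per_turn_factor(seq: SequenceSpec) -> float:
    """Number of helical turns in one periodic unit of the duplex.

    20 bp at 10.0 bp/turn → 2.0.  Free energies of the two-duplex periodic
    unit are divided by this to obtain per-turn values.
    """
    if seq.bp_per_turn <= 0:
        raise ConfigurationError("bp_per_turn must be positive")
    return seq.length_bp / seq.bp_per_turn


@dataclass
class SiteSet:
    """Major-groove site coordinates for one duplex."""

    methyl_xyz: np.ndarray  # (n_methyl, 3)
    n7_xyz: np.ndarray  # (n_n7, 3)
    n7_blocker_count: np.ndarray  # (n_n7,) methyls within blocking radius
    box_z: float

    @property
    def n7_blocked(self) -> np.ndarray:
        return self.n7_blocker_count >= 1

    @property
    def n7_unblocked_xyz(self) -> np.ndarray:
        return self.n7_xyz[~self.n7_blocked]


def _site_xyz(
    positions: list[tuple[int, int]],
    radius: float,
    axis_xy: tuple[float, float],
    bp_per_turn: float,
    phase0: float,
) -> np.ndarray:
    if not positions:
        return np.zeros((0, 3))
    idx = np.array([p[0] for p in positions], dtype=float)
    strand = np.array([p[1] for p in positions], dtype=float)
    theta = (
        2.0 * np.pi * idx / bp_per_turn
        + phase0
        + np.deg2rad(STRAND2_PHASE_DEG) * strand
    )
    x = axis_xy[0] + radius * np.cos(theta)
    y = axis_xy[1] + radius * np.sin(theta)
    z = idx * RISE_PER_BP
    return np.column_stack([x, y, z])


def _min_image_dz(dz: np.ndarray, box_z: float) -> np.ndarray:
    return dz - box_z * np.round(dz / box_z)


def methyl_and_n7_sites(
    seq: SequenceSpec,
    helix_axis_xy: tuple[float, float] = (0.0, 0.0),
    d: float | None = None,
    *,
    phase0: float = 0.0,
    blocking_radius: float = R_BLOCK,
) -> SiteSet:
    """Methyl and purine-N7 site coordinates on an ideal helix.

    Parameters
    ----------
    seq:
        Duplex specification.
    helix_axis_xy:
        (x, y) of the helix axis; the helix runs along z.
    d:
        Inter-DNA distance context (A).  Only validated for positivity when
        given; the sites of a single helix do not depend on it.
    phase0:
        Rigid rotation of the whole helix about its axis (radians).
    blocking_radius:
        Methyl→N7 steric blocking distance (A).

    Returns
    -------
    SiteSet
        Methyl coordinates, N7 coordinates, and per-N7 methyl coordination
        (number of methyls within ``blocking_radius``, z-periodic; a site
        is *blocked* when the count is nonzero).  On the ideal helix the
        coordination is 2 for every (A)20 N7 — the partner thymine methyl
        plus the stacked neighbour — 1 for (AT)10 and (GmC)10, and 0 for
        the unmethylated GC sequences, grading how strongly the methyls
        occlude the cation hotspot.
    """
    if d is not None and d <= 0:
        raise ConfigurationError(f"inter-DNA distance must be positive, got {d}")
    box_z = seq.length_bp * RISE_PER_BP
    methyl = _site_xyz(
        seq.methyl_positions(), R_METHYL, helix_axis_xy, seq.bp_per_turn, phase0
    )
    n7 = _site_xyz(
        seq.purine_positions(), R_N7, helix_axis_xy, seq.bp_per_turn, phase0
    )
    count = np.zeros(len(n7), dtype=int)
    if len(methyl) and len(n7):
        dxy = n7[:, None, :2] - methyl[None, :, :2]
        dz = _min_image_dz(n7[:, None, 2] - methyl[None, :, 2], box_z)
        dist2 = (dxy ** 2).sum(-1) + dz ** 2
        count = (dist2 <= blocking_radius ** 2).sum(axis=1)
    return SiteSet(methyl_xyz=methyl, n7_xyz=n7, n7_blocker_count=count,
                   box_z=box_z)


def phosphate_sites(
    seq: SequenceSpec,
    helix_axis_xy: tuple[float, float] = (0.0, 0.0),
    *,
    radius: float = 10.0,
    phase0: float = 0.0,
) -> np.ndarray:
    """Backbone phosphate site coordinates (two per bp, helix radius 10 A).

    The two backbone strands are placed at ±115° from the base-site track,
    flanking the grooves; over two helical turns each strand's phosphates
    cover all azimuths at 36° increments.
    """
    L = seq.length_bp
    pos1 = [(i, 0) for i in range(L)]
    pos2 = [(i, 1) for i in range(L)]
    p1 = _site_xyz(pos1, radius, helix_axis_xy, seq.bp_per_turn,
                   phase0 + np.deg2rad(115.0))
    p2 = _site_xyz(pos2, radius, helix_axis_xy, seq.bp_per_turn,
                   phase0 - np.deg2rad(115.0))
    return np.vstack([p1, p2])
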