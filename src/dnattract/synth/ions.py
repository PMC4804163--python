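"""Coarse-grained Metropolis Monte Carlo of spermine around two duplexes.

A deliberately minimal effective-energy caricature of the cation
atmosphere: each spermine is a chain of four amine beads (bond 4.5 A,
free internal angles) moving around two parallel duplexes whose axes run
along z at x = ±d/2.  The amine-bead energy is

* Gaussian attraction to backbone phosphate sites (helix radius 10 A),
* Gaussian attraction to purine-N7 major-groove sites (helix radius 6 A),
* Gaussian steric repulsion from methyl sites (helix radius 7 A),
* a soft harmonic cylinder core (radius 9 A) around each helix axis,
* screened amine–amine repulsion ε_r·exp(−r/λ_D) between non-bonded beads,

all z-periodic with box_z = 68 A.  Sodium ions are simulated alongside as
independent single beads feeling a weaker phosphate attraction and the
cores.

Methyl blocking of the N7 hotspots is *energetic* by default: every N7
site keeps its well, and the methyl repulsion raises its floor in
proportion to the local methyl coordination.  On the ideal helix an N7
carries two methyls within 4 A in (A)20, one in (AT)10/(GmC)10 and none
in the unmethylated GC sequences, so groove capture is graded
(G)20 > (GC)10 > (AT)10 ≈ (GmC)10 > (A)20 — clustered methyls protect
best, which is what relocates spermine into the bridging region for the
methyl-rich duplexes.  Setting ``binary_blocking=True`` instead removes
the wells of geometrically blocked sites outright (and then the fully
blocked (A)20 and (AT)10 become exactly degenerate).  The model's only
contract is to reproduce the qualitative adsorption and bridging
structure — not absolute energetics.

Moves are rigid translations, rigid rotations and internal pivots
(tail rotation about a bead), each preserving the bond lengths exactly,
plus two lattice-compatible mixing moves: a *screw* move (rotation about a
randomly chosen helix axis by a multiple of the helical twist combined
with the matching rise along z, which maps the adsorption-site lattice of
that helix onto itself) and a *helix swap* (translation by ±d along x,
mapping one helix's sites exactly onto the other's).  Both proposals are
symmetric, so detailed balance holds; without them, site-to-site
redistribution of adsorbed chains is the slowest mode by orders of
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import KBT_300
from ..duplex import SequenceSpec, methyl_and_n7_sites, phosphate_sites

try:  # numba accelerates the inner energy loops ~20x; numpy fallback below
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @numba.njit(fastmath=True)
    def _site_energy_nb(pos, sxyz, seps, sinv, box_z):  # pragma: no cover
        u = 0.0
        for i in range(pos.shape[0]):
            x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
            for s in range(sxyz.shape[0]):
                dx = x - sxyz[s, 0]
                dy = y - sxyz[s, 1]
                dz = z - sxyz[s, 2]
                dz -= box_z * np.floor(dz / box_z + 0.5)
                d2 = dx * dx + dy * dy + dz * dz
                u += seps[s] * np.exp(-d2 * sinv[s])
        return u

    @numba.njit(fastmath=True)
    def _screened_nb(pos, others, eps, lam, r_hard, k_hard, box_z):  # pragma: no cover
        u = 0.0
        for i in range(pos.shape[0]):
            x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
            for j in range(others.shape[0]):
                dx = x - others[j, 0]
                dy = y - others[j, 1]
                dz = z - others[j, 2]
                dz -= box_z * np.floor(dz / box_z + 0.5)
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if r < 1e-6:
                    r = 1e-6
                u += eps * np.exp(-r / lam)
                if r < r_hard:
                    u += 0.5 * k_hard * (r_hard - r) ** 2
        return u

__all__ = [
    "IonModelParams",
    "IonFrame",
    "CompositionError",
    "SamplerDiagnosticsError",
    "build_system_composition",
    "IonSampler",
    "sample_ion_frames",
]

AVOGADRO = 6.02214076e23


class CompositionError(ValueError):
    pass


class SamplerDiagnosticsError(RuntimeError):
    """Move acceptance collapsed; the chain is not sampling."""


@dataclass(frozen=True)
class IonModelParams:
    """Effective-energy and sampler parameters (kcal/mol, A)."""

    #: wide, overlapping backbone wells: an effectively smooth adsorption
    #: shell at helix radius 10 A (mean depth ~3 kcal/mol) that a chain can
    #: touch from any azimuth, so mixed groove+backbone binding is possible
    eps_phosphate: float = 3.0
    sigma_phosphate: float = 4.0
    eps_groove: float = 9.5
    sigma_groove: float = 2.0
    eps_methyl: float = 2.0
    sigma_methyl: float = 2.0
    #: each methyl within the blocking radius of an N7 site multiplies the
    #: site's well amplitude by this steric-occlusion factor
    occlusion_factor: float = 0.5
    core_radius: float = 9.0
    core_k: float = 0.3  # kcal/mol/A^2, harmonic inside the core
    eps_repulsion: float = 0.3
    debye_length: float = 8.0  # A, ~100 mM salt plus polyamine screening
    #: short-range amine-amine excluded volume (harmonic overlap penalty)
    r_hard: float = 4.0
    k_hard: float = 60.0  # kcal/mol/A^2
    eps_na: float = 0.8  # sodium-phosphate well depth
    bond_length: float = 4.5
    box_xy: float = 80.0
    box_z: float = 68.0
    kbt: float = KBT_300
    #: True removes the wells of methyl-blocked N7 sites outright instead
    #: of attenuating them (makes (A)20 and (AT)10 exactly degenerate)
    binary_blocking: bool = False
    # move amplitudes
    step_translate: float = 1.6
    step_rotate: float = 0.6  # rad
    step_pivot: float = 0.9  # rad
    step_na: float = 3.0


@dataclass
class IonFrame:
    """Bead coordinates of one configuration at fixed inter-DNA distance."""

    d: float  # A
    amine_xyz: np.ndarray  # (4*n_spermine, 3)
    phosphate_xyz: np.ndarray
    sodium_xyz: np.ndarray
    box_z: float = 68.0

    def __post_init__(self) -> None:
        if len(self.amine_xyz) % 4 != 0:
            raise ValueError("amine bead count must be divisible by 4")


def build_system_composition(
    seq_pair: SequenceSpec,
    spermine_charge: int = 4,
    *,
    nacl_mM: float = 100.0,
    box_width: float = 130.0,
    box_z: float = 68.0,
) -> dict:
    """Charge bookkeeping of the two-duplex periodic cell.

    DNA carries two unit charges per base pair per duplex; the spermine
    count neutralizes it exactly (an error if the charge does not divide),
    and NaCl pairs are added for the stated molarity in the hexagonal box
    volume.
    """
    if spermine_charge <= 0:
        raise CompositionError("spermine_charge must be positive")
    dna_charge = 2 * 2 * seq_pair.length_bp
    if dna_charge % spermine_charge != 0:
        raise CompositionError(
            f"DNA charge {dna_charge} e is not a multiple of the spermine "
            f"charge {spermine_charge} e"
        )
    n_spermine = dna_charge // spermine_charge
    volume_A3 = (np.sqrt(3.0) / 2.0) * box_width ** 2 * box_z
    n_salt = int(round(nacl_mM * 1e-3 * AVOGADRO * volume_A3 * 1e-27))
    return {
        "sequence": seq_pair.name,
        "dna_charge_e": dna_charge,
        "spermine_charge_e": spermine_charge,
        "n_spermine": n_spermine,
        "total_spermine_charge_e": n_spermine * spermine_charge,
        "nacl_mM": nacl_mM,
        "n_sodium": n_salt,
        "n_chloride": n_salt,
        "box_width_A": box_width,
        "box_z_A": box_z,
    }


def _wrap_z(z: np.ndarray, box_z: float) -> np.ndarray:
    return np.mod(z, box_z)


def _dist2_sites(pos: np.ndarray, sites: np.ndarray, box_z: float) -> np.ndarray:
    """(n_pos, n_sites) squared distances with z minimum image."""
    if len(sites) == 0:
        return np.zeros((len(pos), 0))
    dxy = pos[:, None, :2] - sites[None, :, :2]
    dz = pos[:, None, 2] - sites[None, :, 2]
    dz -= box_z * np.round(dz / box_z)
    return (dxy ** 2).sum(-1) + dz ** 2


class IonSampler:
    """Metropolis sampler for spermine chains plus sodium around two duplexes.

    The class exposes the energy model directly (``external_energy``,
    ``pair_energy``, ``total_energy``) so that detailed balance can be
    verified against direct Boltzmann enumeration on toy systems.
    """

    def __init__(
        self,
        seq_pair: SequenceSpec,
        d: float,
        *,
        n_spermine: int = 20,
        n_sodium: int = 60,
        n_beads: int = 4,
        params: IonModelParams | None = None,
        seed: int = 0,
    ) -> None:
        if not 20.0 <= d <= 45.0:
            raise ValueError(f"inter-DNA distance {d} outside [20, 45] A")
        if n_spermine < 1:
            raise ValueError("n_spermine must be >= 1")
        self.seq = seq_pair
        self.d = float(d)
        self.p = params or IonModelParams()
        self.n_spermine = n_spermine
        self.n_sodium = n_sodium
        self.n_beads = n_beads
        self.rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.axes = np.array([[-d / 2.0, 0.0], [d / 2.0, 0.0]])

        p = self.p
        phos, groove, groove_amp, methyl = [], [], [], []
        for axis in self.axes:
            sites = methyl_and_n7_sites(seq_pair, tuple(axis))
            phos.append(phosphate_sites(seq_pair, tuple(axis)))
            groove.append(sites.n7_xyz)
            # graded steric occlusion: each methyl within the blocking
            # radius attenuates the hotspot; binary mode zeroes it
            if p.binary_blocking:
                amp = np.where(sites.n7_blocked, 0.0, -p.eps_groove)
            else:
                amp = -p.eps_groove * \
                    p.occlusion_factor ** sites.n7_blocker_count
            groove_amp.append(amp)
            methyl.append(sites.methyl_xyz)
        self.phosphate_xyz = np.vstack(phos)
        self.groove_xyz = np.vstack(groove)
        self.groove_amp = np.concatenate(groove_amp)
        self.methyl_xyz = np.vstack(methyl)

        # packed site arrays (signed amplitude, 1/(2 sigma^2)) per species
        blocks = [
            (self.phosphate_xyz,
             np.full(len(self.phosphate_xyz), -p.eps_phosphate),
             p.sigma_phosphate),
            (self.groove_xyz, self.groove_amp, p.sigma_groove),
            (self.methyl_xyz,
             np.full(len(self.methyl_xyz), p.eps_methyl), p.sigma_methyl),
        ]
        xyz, eps, inv = [], [], []
        for sites, amp, sig in blocks:
            if len(sites) and np.any(amp):
                xyz.append(sites)
                eps.append(amp)
                inv.append(np.full(len(sites), 1.0 / (2.0 * sig * sig)))
        self._am_xyz = np.vstack(xyz) if xyz else np.zeros((0, 3))
        self._am_eps = np.concatenate(eps) if eps else np.zeros(0)
        self._am_inv = np.concatenate(inv) if inv else np.zeros(0)
        self._na_xyz = self.phosphate_xyz
        self._na_eps = np.full(len(self.phosphate_xyz), -p.eps_na)
        self._na_inv = np.full(
            len(self.phosphate_xyz), 1.0 / (2.0 * p.sigma_phosphate ** 2)
        )

        self.spermine = self._initial_chains()
        self.sodium = self._initial_sodium()
        self.n_proposed = 0
        self.n_accepted = 0

    # --- energy model -------------------------------------------------

    def _site_energy(self, pos: np.ndarray, sxyz, seps, sinv) -> float:
        if len(sxyz) == 0:
            return 0.0
        if _HAVE_NUMBA:
            return float(_site_energy_nb(pos, sxyz, seps, sinv, self.p.box_z))
        d2 = _dist2_sites(pos, sxyz, self.p.box_z)
        return float((seps[None, :] * np.exp(-d2 * sinv[None, :])).sum())

    def external_energy(self, pos: np.ndarray, species: str = "amine") -> float:
        """External (site + core) energy of beads at ``pos``; kcal/mol."""
        p = self.p
        if species == "amine":
            u = self._site_energy(pos, self._am_xyz, self._am_eps, self._am_inv)
        else:  # sodium
            u = self._site_energy(pos, self._na_xyz, self._na_eps, self._na_inv)
        for axis in self.axes:
            rho = np.hypot(pos[:, 0] - axis[0], pos[:, 1] - axis[1])
            inside = rho < p.core_radius
            u += 0.5 * p.core_k * ((p.core_radius - rho[inside]) ** 2).sum()
        return float(u)

    def pair_energy_with_others(self, mol: int, pos: np.ndarray) -> float:
        """Screened repulsion of molecule ``mol`` (at ``pos``) vs the rest."""
        p = self.p
        others = np.delete(self.spermine, mol, axis=0).reshape(-1, 3)
        if len(others) == 0:
            return 0.0
        if _HAVE_NUMBA:
            return float(_screened_nb(pos, others, p.eps_repulsion,
                                      p.debye_length, p.r_hard, p.k_hard,
                                      p.box_z))
        d2 = _dist2_sites(pos, others, p.box_z)
        r = np.sqrt(np.maximum(d2, 1e-12))
        u = p.eps_repulsion * np.exp(-r / p.debye_length).sum()
        close = r < p.r_hard
        u += 0.5 * p.k_hard * ((p.r_hard - r[close]) ** 2).sum()
        return float(u)

    def intra_energy(self, pos: np.ndarray) -> float:
        """Screened repulsion between non-bonded beads of one chain."""
        p = self.p
        u = 0.0
        n = len(pos)
        for i in range(n):
            for j in range(i + 2, n):  # skip bonded neighbours
                dz = pos[i, 2] - pos[j, 2]
                dz -= p.box_z * np.round(dz / p.box_z)
                r = max(np.sqrt(
                    (pos[i, 0] - pos[j, 0]) ** 2
                    + (pos[i, 1] - pos[j, 1]) ** 2 + dz ** 2
                ), 1e-6)
                u += p.eps_repulsion * np.exp(-r / p.debye_length)
                if r < p.r_hard:
                    u += 0.5 * p.k_hard * (p.r_hard - r) ** 2
        return float(u)

    def molecule_energy(self, mol: int, pos: np.ndarray) -> float:
        return (
            self.external_energy(pos)
            + self.pair_energy_with_others(mol, pos)
            + self.intra_energy(pos)
        )

    def total_energy(self) -> float:
        """Full-system energy (for diagnostics and toy-system checks)."""
        u = 0.0
        for m in range(self.n_spermine):
            u += self.external_energy(self.spermine[m])
            u += self.intra_energy(self.spermine[m])
            u += 0.5 * self.pair_energy_with_others(m, self.spermine[m])
        if self.n_sodium:
            u += self.external_energy(self.sodium, species="sodium")
        return u

    # --- configuration ------------------------------------------------

    def _random_xy(self, n: int) -> np.ndarray:
        half = self.p.box_xy / 2.0
        return self.rng.uniform(-half, half, size=(n, 2))

    def _initial_chains(self) -> np.ndarray:
        chains = np.zeros((self.n_spermine, self.n_beads, 3))
        for m in range(self.n_spermine):
            while True:
                start = np.concatenate([
                    self._random_xy(1)[0],
                    [self.rng.uniform(0, self.p.box_z)],
                ])
                direction = self.rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                beads = start[None, :] + np.arange(self.n_beads)[:, None] \
                    * self.p.bond_length * direction[None, :]
                if np.all(np.abs(beads[:, :2]) <= self.p.box_xy / 2.0):
                    chains[m] = beads
                    break
        chains[:, :, 2] = _wrap_z(chains[:, :, 2], self.p.box_z)
        return chains

    def _initial_sodium(self) -> np.ndarray:
        if self.n_sodium == 0:
            return np.zeros((0, 3))
        xy = self._random_xy(self.n_sodium)
        z = self.rng.uniform(0, self.p.box_z, size=self.n_sodium)
        return np.column_stack([xy, z])

    # --- moves ----------------------------------------------------------

    @staticmethod
    def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
        axis = axis / np.linalg.norm(axis)
        x, y, z = axis
        c, s = np.cos(angle), np.sin(angle)
        C = 1 - c
        return np.array([
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ])

    def _propose(self, mol: int) -> np.ndarray | None:
        p = self.p
        pos = self.spermine[mol]
        # z is stored wrapped; unwrap the chain around bead 0 before any
        # rigid-body or pivot transformation
        un = pos.copy()
        dz = un[:, 2] - un[0, 2]
        un[:, 2] = un[0, 2] + (dz - p.box_z * np.round(dz / p.box_z))
        kind = self.rng.integers(5)
        if kind == 0:  # rigid translation
            shift = self.rng.normal(0.0, p.step_translate, size=3)
            new = un + shift
        elif kind == 1:  # rigid rotation about the chain centroid
            axis = self.rng.standard_normal(3)
            angle = self.rng.normal(0.0, p.step_rotate)
            R = self._rotation_matrix(axis, angle)
            center = un.mean(axis=0)
            new = (un - center) @ R.T + center
        elif kind == 2:  # pivot: rotate the tail about an interior bead
            if self.n_beads < 2:
                return None
            j = int(self.rng.integers(0, self.n_beads - 1))
            axis = self.rng.standard_normal(3)
            angle = self.rng.normal(0.0, p.step_pivot)
            R = self._rotation_matrix(axis, angle)
            new = un.copy()
            pivot = un[j]
            new[j + 1:] = (un[j + 1:] - pivot) @ R.T + pivot
        elif kind == 3:  # screw move about a randomly chosen helix axis
            twist = 2.0 * np.pi / self.seq.bp_per_turn
            rise = self.p.box_z / self.seq.length_bp
            k = int(self.rng.integers(1, self.seq.length_bp // 2 + 1))
            if self.rng.random() < 0.5:
                k = -k
            axis_xy = self.axes[int(self.rng.integers(2))]
            R = self._rotation_matrix(np.array([0.0, 0.0, 1.0]), k * twist)
            new = un.copy()
            new[:, :2] -= axis_xy
            new = new @ R.T
            new[:, :2] += axis_xy
            new[:, 2] += k * rise
        else:  # helix swap: translate by ±d along x
            sign = 1.0 if self.rng.random() < 0.5 else -1.0
            new = un + np.array([sign * self.d, 0.0, 0.0])
        if np.any(np.abs(new[:, :2]) > p.box_xy / 2.0):
            return None
        new[:, 2] = _wrap_z(new[:, 2], p.box_z)
        return new

    def sweep(self) -> None:
        """One Monte-Carlo sweep: a move attempt per molecule and sodium."""
        p = self.p
        beta = 1.0 / p.kbt
        for mol in range(self.n_spermine):
            self.n_proposed += 1
            new = self._propose(mol)
            if new is None:
                continue
            du = self.molecule_energy(mol, new) - \
                self.molecule_energy(mol, self.spermine[mol])
            if du <= 0 or self.rng.random() < np.exp(-beta * du):
                self.spermine[mol] = new
                self.n_accepted += 1
        if self.n_sodium:
            idx = self.rng.integers(0, self.n_sodium, size=max(1, self.n_sodium // 4))
            for i in idx:
                self.n_proposed += 1
                new = self.sodium[i] + self.rng.normal(0, p.step_na, size=3)
                if np.any(np.abs(new[:2]) > p.box_xy / 2.0):
                    continue
                new[2] = np.mod(new[2], p.box_z)
                du = self.external_energy(new[None, :], species="sodium") - \
                    self.external_energy(self.sodium[i][None, :], species="sodium")
                if du <= 0 or self.rng.random() < np.exp(-beta * du):
                    self.sodium[i] = new
                    self.n_accepted += 1

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(self.n_proposed, 1)

    def frame(self) -> IonFrame:
        return IonFrame(
            d=self.d,
            amine_xyz=self.spermine.reshape(-1, 3).copy(),
            phosphate_xyz=self.phosphate_xyz.copy(),
            sodium_xyz=self.sodium.copy(),
            box_z=self.p.box_z,
        )


def sample_ion_frames(
    seq_pair: SequenceSpec,
    d: float,
    n_spermine: int = 20,
    n_frames: int = 200,
    *,
    params: IonModelParams | None = None,
    seed: int = 0,
    n_sodium: int = 60,
    burn_in_sweeps: int = 1500,
    thin_sweeps: int = 5,
) -> list[IonFrame]:
    """Equilibrate and emit spermine/sodium configurations at fixed d.

    Deterministic for a fixed seed.  Raises
    :class:`SamplerDiagnosticsError` when the overall move acceptance rate
    falls below 1% after burn-in.
    """
    sampler = IonSampler(
        seq_pair, d, n_spermine=n_spermine, n_sodium=n_sodium,
        params=params, seed=seed,
    )
    for _ in range(burn_in_sweeps):
        sampler.sweep()
    if sampler.acceptance_rate < 0.01:
        raise SamplerDiagnosticsError(
            f"move acceptance {sampler.acceptance_rate:.2%} < 1% after "
            "burn-in; retune the move amplitudes"
        )
    frames = []
    for _ in range(n_frames):
        for _ in range(thin_sweeps):
            sampler.sweep()
        frames.append(sampler.frame())
    return frames
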