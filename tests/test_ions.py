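"""Spermine Monte Carlo: composition arithmetic, chain constraints,
Metropolis correctness against direct Boltzmann enumeration."""

import numpy as np
import pytest

from dnattract.duplex import BUILTIN_SEQUENCES, SequenceSpec, builtin_sequence
from dnattract.synth.ions import (
    CompositionError,
    IonFrame,
    IonModelParams,
    IonSampler,
    build_system_composition,
    sample_ion_frames,
)


class TestComposition:
    def test_twenty_bp_pair_neutralized_by_twenty_spermine(self):
        comp = build_system_composition(builtin_sequence("AT10"), 4)
        assert comp["dna_charge_e"] == 80
        assert comp["n_spermine"] == 20
        assert comp["total_spermine_charge_e"] == 80

    def test_ten_bp_pair(self):
        comp = build_system_composition(SequenceSpec("s", "AT" * 5), 4)
        assert comp["n_spermine"] == 10

    def test_non_divisible_charge_rejected(self):
        with pytest.raises(CompositionError):
            build_system_composition(builtin_sequence("AT10"), 3)
        with pytest.raises(CompositionError):
            build_system_composition(builtin_sequence("AT10"), 0)

    def test_salt_count_scales_with_molarity(self):
        lo = build_system_composition(builtin_sequence("A20"), 4, nacl_mM=50)
        hi = build_system_composition(builtin_sequence("A20"), 4, nacl_mM=100)
        assert hi["n_sodium"] == pytest.approx(2 * lo["n_sodium"], abs=1)
        assert hi["n_sodium"] > 0


class TestIonFrame:
    def test_bead_count_divisibility_enforced(self):
        with pytest.raises(ValueError):
            IonFrame(d=28.0, amine_xyz=np.zeros((5, 3)),
                     phosphate_xyz=np.zeros((0, 3)),
                     sodium_xyz=np.zeros((0, 3)))


class TestSamplerStructure:
    def test_bond_lengths_preserved_and_z_wrapped(self):
        frames = sample_ion_frames(
            builtin_sequence("AT10"), 28.0, n_spermine=5, n_frames=10,
            seed=3, n_sodium=5, burn_in_sweeps=50, thin_sweeps=2,
        )
        p = IonModelParams()
        for f in frames:
            assert np.all(f.amine_xyz[:, 2] >= 0)
            assert np.all(f.amine_xyz[:, 2] < f.box_z)
            chains = f.amine_xyz.reshape(-1, 4, 3)
            dz = np.diff(chains[:, :, 2], axis=1)
            dz -= f.box_z * np.round(dz / f.box_z)
            bond = np.sqrt(
                (np.diff(chains[:, :, 0], axis=1)) ** 2
                + (np.diff(chains[:, :, 1], axis=1)) ** 2 + dz ** 2
            )
            assert np.allclose(bond, p.bond_length, atol=1e-8)

    def test_deterministic_for_fixed_seed(self):
        kw = dict(n_spermine=4, n_frames=5, seed=11, n_sodium=4,
                  burn_in_sweeps=30, thin_sweeps=1)
        f1 = sample_ion_frames(builtin_sequence("GC10"), 28.0, **kw)
        f2 = sample_ion_frames(builtin_sequence("GC10"), 28.0, **kw)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.amine_xyz, b.amine_xyz)
            assert np.array_equal(a.sodium_xyz, b.sodium_xyz)

    def test_distance_validation(self):
        with pytest.raises(ValueError):
            sample_ion_frames(builtin_sequence("AT10"), 10.0, n_frames=1,
                              seed=0)


class TestMetropolisCorrectness:
    def test_single_bead_occupancy_matches_boltzmann(self):
        """Detailed balance on a toy system: one single-bead chain in the
        external field; z-column occupancies must match the Boltzmann
        weights from direct enumeration on a coarse grid."""
        from dnattract.synth.ions import _dist2_sites

        seq = builtin_sequence("G20")
        p = IonModelParams(eps_repulsion=0.0, box_xy=40.0)
        s = IonSampler(seq, 28.0, n_spermine=1, n_sodium=0, n_beads=1,
                       params=p, seed=21)
        # empirical x-marginal occupancy over 8 coarse bins
        edges_x = np.linspace(-20, 20, 9)
        counts = np.zeros(8)
        for i in range(60000):
            s.sweep()
            if i < 5000 or i % 3:
                continue
            b = np.searchsorted(edges_x, s.spermine[0, 0, 0]) - 1
            if 0 <= b < 8:
                counts[b] += 1
        # direct Boltzmann enumeration of the same marginal on a fine grid
        gx = np.arange(-20, 20.01, 0.4)
        gz = np.arange(0.2, p.box_z, 0.8)
        X, Y, Z = np.meshgrid(gx, gx, gz, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        u = np.zeros(len(pts))
        for lo in range(0, len(pts), 50000):
            chunk = pts[lo:lo + 50000]
            d2 = _dist2_sites(chunk, s._am_xyz, p.box_z)
            uc = (s._am_eps[None, :] * np.exp(-d2 * s._am_inv[None, :])).sum(1)
            for axis in s.axes:
                rho = np.hypot(chunk[:, 0] - axis[0], chunk[:, 1] - axis[1])
                pen = np.where(rho < p.core_radius,
                               0.5 * p.core_k * (p.core_radius - rho) ** 2, 0.0)
                uc = uc + pen
            u[lo:lo + 50000] = uc
        w = np.exp(-u / p.kbt)
        marg = np.array([
            w[(pts[:, 0] >= edges_x[b]) & (pts[:, 0] < edges_x[b + 1])].sum()
            for b in range(8)
        ])
        marg /= marg.sum()
        emp = counts / counts.sum()
        # agreement within a few percent absolute per coarse bin
        assert np.max(np.abs(emp - marg)) < 0.05

    def test_acceptance_rate_reasonable(self):
        frames = sample_ion_frames(
            builtin_sequence("AT10"), 28.0, n_spermine=5, n_frames=5,
            seed=1, n_sodium=0, burn_in_sweeps=100, thin_sweeps=1,
        )
        assert len(frames) == 5
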