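"""Superposition, RMSF and quasi-harmonic entropy."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pamscope import flex_entropy as fe
from pamscope.io_selection import select
from pamscope.synthetic import HarmonicEnsembleSpec, gen_harmonic_ensemble
from pamscope.units import HBAR, KB, R_GAS

from conftest import make_structure, make_trajectory


def _rigid_copies(coords, n, seed=0):
    rng = np.random.default_rng(seed)
    frames = np.empty((n, coords.shape[0], 3))
    for i in range(n):
        rot = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
        frames[i] = coords @ rot.T + rng.normal(size=3)
    return frames


@pytest.fixture
def tetrahedron():
    spec = [(f"C{i}", 1, "RES", "A", 12.0) for i in range(4)]
    coords = np.array(
        [[0, 0, 0], [0.15, 0, 0], [0, 0.15, 0], [0, 0, 0.15]], dtype=float
    )
    return make_structure(spec, coords)


class TestSuperpose:
    def test_rigid_copies_collapse_to_reference(self, tetrahedron):
        frames = _rigid_copies(tetrahedron.coords, 10)
        traj = make_trajectory(tetrahedron, frames)
        g = select(tetrahedron, "all")
        aligned = fe.superpose_series(traj, g)
        for f in range(10):
            assert np.abs(aligned.frames[f] - aligned.frames[0]).max() < 1e-10

    def test_idempotent(self, tetrahedron, rng):
        frames = tetrahedron.coords[None] + 0.01 * rng.standard_normal((8, 4, 3))
        traj = make_trajectory(tetrahedron, frames)
        g = select(tetrahedron, "all")
        once = fe.superpose_series(traj, g)
        twice = fe.superpose_series(once, g)
        np.testing.assert_allclose(twice.frames, once.frames, atol=1e-12)

    def test_quaternion_oracle_agreement(self, tetrahedron, rng):
        """Aligned frames match an eigen-quaternion superposition."""
        frames = tetrahedron.coords[None] + 0.02 * rng.standard_normal((5, 4, 3))
        traj = make_trajectory(tetrahedron, frames)
        g = select(tetrahedron, "all")
        aligned = fe.superpose_series(traj, g, mass_weighted=False)
        ref = traj.frames[0]
        for f in range(1, 5):
            expect = _quaternion_superpose(ref, traj.frames[f])
            np.testing.assert_allclose(aligned.frames[f], expect, atol=1e-9)


def _quaternion_superpose(ref, mob):
    """Horn's closed-form quaternion superposition (independent algorithm)."""
    rc = ref - ref.mean(0)
    mc = mob - mob.mean(0)
    m = mc.T @ rc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    _, vecs = np.linalg.eigh(n)
    q = vecs[:, -1]  # w, x, y, z
    rot = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    return mc @ rot.T + ref.mean(0)


class TestRmsf:
    def test_static_structure_is_zero(self, tetrahedron):
        traj = make_trajectory(tetrahedron, np.repeat(tetrahedron.coords[None], 6, 0))
        prof = fe.rmsf(traj, select(tetrahedron, "all"))
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_isotropic_gaussian_closed_form(self):
        """Per-axis sigma = 0.1 nm gives RMSF = sqrt(3)*0.1 nm = 1.732 A."""
        spec = HarmonicEnsembleSpec(
            masses=np.array([12.0]), covariance=0.01 * np.eye(3),
            n_frames=100_000, seed=2,
        )
        traj = gen_harmonic_ensemble(spec)
        prof = fe.rmsf(traj, select(traj.structure, "all"))
        assert prof.values[0] == pytest.approx(math.sqrt(3) * 1.0, rel=0.02)

    def test_global_rotation_invariance(self, tetrahedron, rng):
        frames = tetrahedron.coords[None] + 0.01 * rng.standard_normal((50, 4, 3))
        rot = Rotation.random(random_state=5).as_matrix()
        g_spec = [(a.name, a.residue_number, a.residue_name, a.chain, a.mass)
                  for a in tetrahedron.atoms]
        s2 = make_structure(g_spec, tetrahedron.coords @ rot.T)
        t1 = make_trajectory(tetrahedron, frames)
        t2 = make_trajectory(s2, frames @ rot.T)
        p1 = fe.rmsf(t1, select(tetrahedron, "all"))
        p2 = fe.rmsf(t2, select(s2, "all"))
        np.testing.assert_allclose(p2.values, p1.values, atol=1e-10)


class TestCovariance:
    def test_recovers_generator_spec(self):
        target = np.diag([4e-3, 2e-3, 1e-3, 3e-3, 1.5e-3, 0.5e-3])
        spec = HarmonicEnsembleSpec(
            masses=np.array([1.0, 1.0]), covariance=target,
            n_frames=200_000, seed=8,
        )
        traj = gen_harmonic_ensemble(spec)
        cov = fe.fluctuation_covariance(
            traj, select(traj.structure, "all"), mass_weighted=False
        )
        np.testing.assert_allclose(np.diag(cov), np.diag(target), rtol=0.05)
        assert np.abs(cov - cov.T).max() == 0.0

    def test_mass_weighting(self):
        spec = HarmonicEnsembleSpec(
            masses=np.array([4.0]), covariance=1e-3 * np.eye(3),
            n_frames=5000, seed=1,
        )
        traj = gen_harmonic_ensemble(spec)
        g = select(traj.structure, "all")
        plain = fe.fluctuation_covariance(traj, g, mass_weighted=False)
        weighted = fe.fluctuation_covariance(traj, g, mass_weighted=True)
        np.testing.assert_allclose(weighted, 4.0 * plain, atol=1e-12)

    def test_rigid_group_covariance_vanishes_after_alignment(self, tetrahedron):
        frames = _rigid_copies(tetrahedron.coords, 40, seed=3)
        traj = make_trajectory(tetrahedron, frames)
        g = select(tetrahedron, "all")
        aligned = fe.superpose_series(traj, g)
        cov = fe.fluctuation_covariance(aligned, g)
        evals = np.linalg.eigvalsh(cov)
        # all 3A modes of a rigid body are removed (rank <= 3A-6 trivially)
        assert evals.max() < 1e-16


class TestQuasiharmonicEntropy:
    def test_single_mode_closed_form(self):
        """lambda chosen so hbar*omega = kT gives the x=1 oscillator entropy."""
        t = 300.0
        kt = KB * t
        lam = HBAR**2 / kt  # x = hbar/sqrt(kT*lam) = 1
        res = fe.quasiharmonic_entropy(np.diag([lam]), t)
        expected = R_GAS * (1.0 / (math.e - 1.0) - math.log(1.0 - math.exp(-1.0)))
        assert res.S == pytest.approx(expected, rel=1e-12)
        assert res.n_modes_used == 1

    def test_stiff_mode_limit_vanishes(self):
        res = fe.quasiharmonic_entropy(np.diag([1e-9]), 300.0)
        assert res.S < 1e-6

    def test_floor_excludes_frozen_modes(self):
        lam = HBAR**2 / (KB * 300.0)
        res = fe.quasiharmonic_entropy(np.diag([lam, 1e-15]), 300.0)
        assert res.n_modes_used == 1

    def test_monotone_in_eigenvalues(self):
        lam = HBAR**2 / (KB * 300.0)
        s1 = fe.quasiharmonic_entropy(np.diag([lam, lam]), 300.0).S
        s2 = fe.quasiharmonic_entropy(np.diag([lam, 2 * lam]), 300.0).S
        assert s2 > s1

    def test_orthogonal_invariance(self, rng):
        lam = HBAR**2 / (KB * 300.0)
        diag = np.diag([lam, 2 * lam, 0.5 * lam])
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = q @ diag @ q.T
        s_a = fe.quasiharmonic_entropy(diag, 300.0).S
        s_b = fe.quasiharmonic_entropy(rotated, 300.0).S
        assert s_b == pytest.approx(s_a, rel=1e-9)

    def test_classical_formula_differs(self):
        lam = HBAR**2 / (KB * 300.0)
        q = fe.quasiharmonic_entropy(np.diag([lam]), 300.0, formula="quantum").S
        c = fe.quasiharmonic_entropy(np.diag([lam]), 300.0, formula="classical").S
        assert q != pytest.approx(c)

    def test_asymmetric_covariance_rejected(self):
        bad = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            fe.quasiharmonic_entropy(bad, 300.0)

    def test_sampled_ensemble_converges_to_closed_form(self):
        """3-mode system at 1e5 frames reproduces the analytic S within 2%."""
        t = 300.0
        kt = KB * t
        mass = 12.0
        lams = np.array([1.0, 2.0, 0.5]) * HBAR**2 / kt  # nm^2 amu
        spec = HarmonicEnsembleSpec(
            masses=np.array([mass]), covariance=np.diag(lams / mass),
            n_frames=100_000, seed=13,
        )
        traj = gen_harmonic_ensemble(spec)
        g = select(traj.structure, "all")
        cov = fe.fluctuation_covariance(traj, g, mass_weighted=True)
        s_est = fe.quasiharmonic_entropy(cov, t).S
        s_true = fe.quasiharmonic_entropy(np.diag(lams), t).S
        assert s_est == pytest.approx(s_true, rel=0.02)

    def test_entropy_difference_bookkeeping(self):
        assert fe.entropy_difference(320.01, 103.18) == pytest.approx(216.83)
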