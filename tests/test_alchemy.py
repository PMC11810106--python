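"""MBAR estimation, exchange acceptance, schedule design, cycle, blocks."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from pamscope import alchemy as al
from pamscope.synthetic import gen_alchemical_harmonics


def bar_self_consistent(u: al.ReducedPotentialMatrix) -> float:
    """Independent two-state BAR oracle: root of the Bennett equation."""
    i0 = u.samples_from_state(0)
    i1 = u.samples_from_state(1)
    w_f = u.u_kn[1, i0] - u.u_kn[0, i0]  # forward work
    w_r = u.u_kn[0, i1] - u.u_kn[1, i1]  # reverse work
    m = math.log(i0.size / i1.size)

    def g(df):
        lhs = np.sum(1.0 / (1.0 + np.exp(m + w_f - df)))
        rhs = np.sum(1.0 / (1.0 + np.exp(-m + w_r + df)))
        return lhs - rhs

    return brentq(g, -50.0, 50.0, xtol=1e-13)


class TestMbar:
    def test_identical_states_are_degenerate(self, rng):
        x = rng.standard_normal(300)
        u_kn = np.vstack([0.5 * x**2, 0.5 * x**2, 0.5 * x**2])
        u = al.ReducedPotentialMatrix(u_kn=u_kn, n_k=np.array([100, 100, 100]))
        res = al.mbar_free_energies(u)
        np.testing.assert_allclose(res.delta_f, 0.0, atol=1e-10)

    def test_harmonic_closed_form_within_3_sigma(self):
        u, analytic = gen_alchemical_harmonics([1.0, 4.0], 10_000, seed=17)
        res = al.mbar_free_energies(u)
        assert abs(res.delta_f[1] - analytic[1]) <= 3.0 * res.d_delta_f[1]
        assert res.d_delta_f[1] < 0.02

    def test_reduces_to_bar_for_two_states(self):
        """MBAR with K=2 equals the Bennett root to 1e-8 kT."""
        u, _ = gen_alchemical_harmonics([1.0, 6.0], 2000, seed=3)
        res = al.mbar_free_energies(u, tolerance=1e-12)
        assert res.delta_f[1] == pytest.approx(bar_self_consistent(u), abs=1e-8)

    def test_antisymmetry_under_state_reversal(self):
        u, _ = gen_alchemical_harmonics([1.0, 5.0], 1500, seed=4)
        res_fwd = al.mbar_free_energies(u)
        rev = al.ReducedPotentialMatrix(
            u_kn=u.u_kn[::-1][:, ::-1], n_k=u.n_k[::-1]
        )
        res_rev = al.mbar_free_energies(rev)
        assert res_rev.delta_f[1] == pytest.approx(-res_fwd.delta_f[1], abs=1e-7)

    def test_path_sum_consistency(self):
        """Multistate increments compose exactly: f(0->2) = f(0->1)+f(1->2)."""
        u, _ = gen_alchemical_harmonics([1.0, 3.0, 9.0], 2000, seed=5)
        res = al.mbar_free_energies(u)
        f01 = res.delta_f[1] - res.delta_f[0]
        f12 = res.delta_f[2] - res.delta_f[1]
        assert res.delta_f[2] == pytest.approx(f01 + f12, abs=1e-12)

    def test_uncertainty_shrinks_with_samples(self):
        errs = []
        for n in (500, 8000):
            u, _ = gen_alchemical_harmonics([1.0, 4.0], n, seed=6)
            errs.append(al.mbar_free_energies(u).d_delta_f[1])
        assert errs[1] < errs[0]
        assert errs[0] / errs[1] == pytest.approx(math.sqrt(16.0), rel=0.3)

    def test_unsampled_evaluation_state(self):
        """A zero-sample state still gets a free energy (perturbation-style)."""
        u, analytic = gen_alchemical_harmonics([1.0, 1.5, 2.25], 4000, seed=8)
        u_kn = u.u_kn[:, : 8000]  # drop state-2 samples
        u2 = al.ReducedPotentialMatrix(u_kn=u_kn, n_k=np.array([4000, 4000, 0]))
        res = al.mbar_free_energies(u2)
        assert res.delta_f[2] == pytest.approx(analytic[2], abs=0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            al.ReducedPotentialMatrix(u_kn=np.zeros((2, 5)), n_k=np.array([2, 2]))


class TestExchangeAcceptance:
    def test_identical_states_accept_everything(self, rng):
        x = rng.standard_normal(400)
        u_kn = np.vstack([0.5 * x**2, 0.5 * x**2])
        u = al.ReducedPotentialMatrix(u_kn=u_kn, n_k=np.array([200, 200]))
        assert al.exchange_acceptance(u)[0] == pytest.approx(1.0)

    def test_disjoint_states_accept_nothing(self):
        u, _ = gen_alchemical_harmonics([1.0, 1e8], 500, seed=2)
        assert al.exchange_acceptance(u)[0] < 1e-3

    def test_monte_carlo_metropolis_oracle(self, rng):
        """<min(1, e^-delta)> matches simulated accept/reject frequencies."""
        u, _ = gen_alchemical_harmonics([1.0, 4.0], 20_000, seed=9)
        est = al.exchange_acceptance(u)[0]
        i0, i1 = u.samples_from_state(0), u.samples_from_state(1)
        delta = (u.u_kn[0, i1] + u.u_kn[1, i0]) - (u.u_kn[0, i0] + u.u_kn[1, i1])
        accepted = rng.random(delta.size) < np.exp(-delta)
        mc = accepted.mean()
        se = math.sqrt(mc * (1 - mc) / delta.size)
        assert est == pytest.approx(mc, abs=4 * se)


class TestScheduleOptimizer:
    def test_symmetric_three_windows_put_midpoint_at_half(self):
        model = al.HarmonicAlchemicalModel(1.0, 100.0)  # log-symmetric
        sched, _ = al.optimize_lambda_schedule(model, 3, seed=1)
        assert sched.values[1] == pytest.approx(0.5, abs=0.02)

    def test_improves_minimum_acceptance_on_steep_model(self):
        model = al.HarmonicAlchemicalModel(1.0, 100.0, interpolation="linear")
        z = np.random.default_rng(2).standard_normal((8, 2000))
        uniform_acc = al._model_acceptances(
            model, al.LambdaSchedule.uniform(8).values, z
        )
        sched, diag = al.optimize_lambda_schedule(model, 8, seed=2)
        assert diag["min_acceptance"] >= uniform_acc.min()

    def test_monotone_with_fixed_endpoints(self):
        model = al.HarmonicAlchemicalModel(1.0, 50.0)
        sched, _ = al.optimize_lambda_schedule(model, 6, seed=3)
        assert sched.values[0] == 0.0 and sched.values[-1] == 1.0
        assert np.all(np.diff(sched.values) > 0)

    def test_unreachable_target_raises(self):
        model = al.HarmonicAlchemicalModel(1.0, 1e12)
        with pytest.raises(al.ScheduleError, match="window"):
            al.optimize_lambda_schedule(
                model, 2, target_acceptance=0.10, seed=4, max_iter=5
            )

    def test_deterministic_under_seed(self):
        model = al.HarmonicAlchemicalModel(1.0, 100.0)
        s1, _ = al.optimize_lambda_schedule(model, 5, seed=11)
        s2, _ = al.optimize_lambda_schedule(model, 5, seed=11)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            al.LambdaSchedule(np.array([0.0, 0.5, 0.4, 1.0]))
        with pytest.raises(ValueError):
            al.LambdaSchedule(np.array([0.1, 0.5, 1.0]))


class TestThermodynamicCycle:
    def test_examples(self):
        res = al.thermodynamic_cycle(2.0, 0.0, -3.0, 0.0)
        assert res.ddg == pytest.approx(-5.0) and res.ddg_err == 0.0
        assert al.thermodynamic_cycle(1.3, 0.1, 1.3, 0.1).ddg == 0.0
        assert al.thermodynamic_cycle(0.0, 0.3, 0.0, 0.4).ddg_err == pytest.approx(0.5)

    def test_kt_kcal_conversion(self):
        # 1 kT at 300 K is about 0.596 kcal/mol
        assert al.kt_to_kcal_per_mol(1.0, 300.0) == pytest.approx(0.5962, abs=1e-3)


class TestDecomposition:
    def test_constant_series(self):
        res = al.interaction_energy_decomposition(
            {"R1335": (np.full(100, -3.0), np.full(100, -8.0))}
        )
        assert res.delta_e["R1335"] == pytest.approx(-5.0)
        assert res.errors["R1335"] == 0.0

    def test_block_error_matches_iid_closed_form(self, rng):
        """Mean estimated block-SE over many series ~ sigma/sqrt(n)."""
        sigma, n = 2.0, 5000
        n_eff = round(0.9 * n)  # frames kept after the 10% discard
        ses = []
        for _ in range(200):
            s0 = rng.normal(0.0, sigma, n)
            s1 = rng.normal(1.0, sigma, n)
            res = al.interaction_energy_decomposition({"g": (s0, s1)})
            ses.append(res.errors["g"])
        analytic = math.sqrt(2.0) * sigma / math.sqrt(n_eff)
        assert np.mean(ses) == pytest.approx(analytic, rel=0.20)

    def test_partition_conservation(self, rng):
        groups = {
            f"g{i}": (rng.normal(i, 1, 250), rng.normal(-i, 1, 250))
            for i in range(3)
        }
        total = (
            sum(groups[g][0] for g in groups) + rng.normal(0, 1, 250),
            sum(groups[g][1] for g in groups) + rng.normal(0, 1, 250),
        )
        res = al.interaction_energy_decomposition(groups, total)
        assert sum(res.delta_e.values()) == pytest.approx(res.total, abs=1e-6)
        assert "prot-rest" in res.delta_e

    def test_equilibration_discard(self):
        s0 = np.concatenate([np.full(10, 1000.0), np.full(90, 0.0)])
        s1 = np.concatenate([np.full(10, 1000.0), np.full(90, 4.0)])
        res = al.interaction_energy_decomposition({"g": (s0, s1)})
        assert res.delta_e["g"] == pytest.approx(4.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="blocks"):
            al.interaction_energy_decomposition(
                {"g": (np.arange(4.0), np.arange(4.0))}
            )
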