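"""Alchemical free energies: MBAR, exchange acceptance, schedule design.

Free-energy differences over a ladder of lambda windows are estimated with
the multistate Bennett acceptance ratio (MBAR): the self-consistent
solution of

    f_k = -ln sum_n exp(-u_k(x_n)) / sum_j N_j exp(f_j - u_j(x_n))

with uncertainties from the asymptotic covariance of the weight matrix.
Internally everything is in kT; reporting converts to kcal/mol at a stated
temperature.

The lambda-window placement follows the replica-exchange criterion: the
Metropolis acceptance for neighbouring windows is estimated from a
state-energy model, and interior lambda values are adjusted by plain
gradient descent on an acceptance-equalization loss (variance of the
neighbour acceptances, penalized when the minimum drops below the target
floor, 10% by default).

The thermodynamic-cycle difference DDG = DG_m2 - DG_m1 (DNA-bound minus
free transformation legs) carries the quadrature-propagated error, and the
per-residue enthalpic decomposition averages end-state interaction-energy
series with block-average errors (five blocks, first ~10% discarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .units import KB, KCAL

__all__ = [
    "ReducedPotentialMatrix",
    "FreeEnergyResult",
    "LambdaSchedule",
    "ThermoCycleResult",
    "DecompositionResult",
    "HarmonicAlchemicalModel",
    "mbar_free_energies",
    "exchange_acceptance",
    "optimize_lambda_schedule",
    "thermodynamic_cycle",
    "interaction_energy_decomposition",
    "kt_to_kcal_per_mol",
]


def kt_to_kcal_per_mol(value_kt: float, temperature: float) -> float:
    return value_kt * KB * temperature / KCAL


@dataclass
class ReducedPotentialMatrix:
    """u_kn samples: row k = evaluation state, column n = sample.

    Samples are ordered by source state: the first ``n_k[0]`` columns were
    drawn from state 0, the next ``n_k[1]`` from state 1, and so on.  A
    zero entry in ``n_k`` marks an unsampled evaluation-only state.
    """

    u_kn: np.ndarray  # (K, N), kT
    n_k: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u_kn.ndim != 2 or self.n_k.ndim != 1:
            raise ValueError("u_kn must be (K, N), n_k (K,)")
        if self.u_kn.shape[0] != self.n_k.size:
            raise ValueError("n_k length must match number of states")
        if self.n_k.sum() != self.u_kn.shape[1]:
            raise ValueError("sum of n_k must equal the sample count")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("reduced potentials must be finite")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]

    def samples_from_state(self, k: int) -> np.ndarray:
        """Column indices of the samples drawn from state k."""
        starts = np.concatenate(([0], np.cumsum(self.n_k)))
        return np.arange(starts[k], starts[k + 1])


@dataclass(frozen=True)
class FreeEnergyResult:
    """Per-state free energies relative to state 0, in kT."""

    delta_f: np.ndarray  # (K,), kT; delta_f[0] = 0
    d_delta_f: np.ndarray  # (K,), kT, asymptotic standard errors
    n_iterations: int
    final_residual: float

    def __post_init__(self) -> None:
        if abs(self.delta_f[0]) > 1e-12:
            raise ValueError("free energies must be relative to state 0")
        if np.any(self.d_delta_f < 0):
            raise ValueError("uncertainties must be >= 0")

    def in_kcal_per_mol(self, temperature: float) -> tuple[np.ndarray, np.ndarray]:
        fac = KB * temperature / KCAL
        return self.delta_f * fac, self.d_delta_f * fac


class ConvergenceError(RuntimeError):
    """MBAR iteration failed to reach tolerance; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def _mbar_objective(f: np.ndarray, u_kn: np.ndarray, n_k: np.ndarray):
    """Convex MBAR objective and gradient (gauge: all f free)."""
    log_n = np.log(n_k, where=n_k > 0, out=np.full(n_k.shape, -np.inf))
    # log_denom_n = logsumexp_k [ log N_k + f_k - u_kn ]
    log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
    obj = float(log_denom.sum() - n_k @ f)
    # grad_k = N_k * sum_n W_nk - N_k
    log_w = f[:, None] - u_kn - log_denom[None, :]
    grad = np.where(n_k > 0, n_k * np.exp(logsumexp(log_w, axis=1)) - n_k, 0.0)
    return obj, grad, log_denom


def mbar_free_energies(
    u: ReducedPotentialMatrix,
    tolerance: float = 1e-8,
    max_iter: int = 10_000,
) -> FreeEnergyResult:
    """Solve the MBAR equations and estimate asymptotic uncertainties.

    A quasi-Newton minimization of the convex MBAR objective provides a
    warm start; self-consistent iteration then polishes the solution until
    the largest free-energy increment falls below ``tolerance`` (kT).
    Uncertainties come from the asymptotic covariance of the normalized
    weight matrix.
    """
    u_kn, n_k = u.u_kn, u.n_k
    k_states = u.n_states
    sampled = n_k > 0
    if not sampled.any():
        raise ValueError("at least one state must carry samples")

    f = np.zeros(k_states)
    res = minimize(
        lambda x: _mbar_objective(x, u_kn, n_k)[:2],
        f,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
    )
    f = res.x
    n_newton = int(res.nit)

    # self-consistent polish: f_k = -ln sum_n exp(-u_kn - log_denom_n)
    residual = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        _, _, log_denom = _mbar_objective(f, u_kn, n_k)
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        f_new = f_new - f_new[0]
        # compare increments in the f_0 = 0 gauge
        residual = float(np.max(np.abs(f_new - (f - f[0]))))
        f = f_new
        if residual < tolerance:
            break
    else:
        raise ConvergenceError(
            f"MBAR did not converge within {max_iter} iterations "
            f"(residual {residual:.3e} kT)",
            residual,
        )

    # asymptotic covariance from the weight matrix (SVD form)
    _, _, log_denom = _mbar_objective(f, u_kn, n_k)
    w = np.exp(f[:, None] - u_kn - log_denom[None, :]).T  # (N, K), cols sum to 1
    u_svd, s, vt = np.linalg.svd(w, full_matrices=False)
    inner = np.eye(k_states) - (s[:, None] * vt) @ (
        n_k[:, None] * ((s[:, None] * vt).T)
    )
    theta = (s[:, None] * vt).T @ np.linalg.pinv(inner, rcond=1e-10) @ (
        s[:, None] * vt
    )
    var = theta.diagonal() + theta[0, 0] - 2.0 * theta[0, :]
    d_delta_f = np.sqrt(np.clip(var, 0.0, None))
    d_delta_f[0] = 0.0
    return FreeEnergyResult(
        delta_f=f - f[0],
        d_delta_f=d_delta_f,
        n_iterations=n_newton + it,
        final_residual=residual,
    )


# --------------------------------------------------------------------------
# Replica-exchange acceptance and lambda-schedule optimization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LambdaSchedule:
    """Strictly increasing lambda values with endpoints 0 and 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size < 2:
            raise ValueError("schedule needs at least two windows")
        if not (math.isclose(v[0], 0.0, abs_tol=1e-12)
                and math.isclose(v[-1], 1.0, abs_tol=1e-12)):
            raise ValueError("schedule endpoints must be 0 and 1")
        if np.any(np.diff(v) <= 0):
            raise ValueError("schedule must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return self.values.size

    @staticmethod
    def uniform(n_windows: int) -> "LambdaSchedule":
        return LambdaSchedule(np.linspace(0.0, 1.0, n_windows))


def exchange_acceptance(u: ReducedPotentialMatrix) -> np.ndarray:
    """Mean Metropolis acceptance for each neighbouring state pair.

    Samples from states i and i+1 are paired index-by-index (truncated to
    the shorter block); the configuration-swap energy difference is
    ``delta = u_i(y) + u_j(x) - u_i(x) - u_j(y)`` for x from i, y from j,
    and the acceptance is ``<min(1, exp(-delta))>``.
    """
    out = []
    for i in range(u.n_states - 1):
        j = i + 1
        idx_i = u.samples_from_state(i)
        idx_j = u.samples_from_state(j)
        n = min(idx_i.size, idx_j.size)
        if n == 0:
            raise ValueError(f"states {i}/{j} carry no samples to pair")
        xi, yj = idx_i[:n], idx_j[:n]
        delta = (u.u_kn[i, yj] + u.u_kn[j, xi]) - (u.u_kn[i, xi] + u.u_kn[j, yj])
        out.append(float(np.mean(np.minimum(1.0, np.exp(-delta)))))
    return np.array(out)


class HarmonicAlchemicalModel:
    """1D harmonic state-energy model: u_lam(x) = 0.5 k(lam) x^2 (kT).

    The spring constant interpolates between the end states, log-linearly
    by default (matching a ladder of log-spaced windows); ``transform``
    maps standard-normal base draws to samples of a window, which gives the
    optimizer a smooth, deterministic acceptance estimate under common
    random numbers.
    """

    def __init__(self, k0: float, k1: float, interpolation: str = "log"):
        if k0 <= 0 or k1 <= 0:
            raise ValueError("spring constants must be > 0")
        if interpolation not in ("log", "linear"):
            raise ValueError("interpolation must be 'log' or 'linear'")
        self.k0, self.k1 = float(k0), float(k1)
        self.interpolation = interpolation

    def spring(self, lam: float) -> float:
        if self.interpolation == "log":
            return math.exp(
                (1.0 - lam) * math.log(self.k0) + lam * math.log(self.k1)
            )
        return (1.0 - lam) * self.k0 + lam * self.k1

    def reduced_potential(self, lam: float, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring(lam) * np.asarray(x) ** 2

    def transform(self, lam: float, z: np.ndarray) -> np.ndarray:
        return np.asarray(z) / math.sqrt(self.spring(lam))

    def sample(self, lam: float, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.transform(lam, rng.standard_normal(n))

    def sample_matrix(
        self, schedule: "LambdaSchedule", n_per_state: int,
        rng: np.random.Generator,
    ) -> ReducedPotentialMatrix:
        """Draw fresh samples from every window of a schedule."""
        lams = schedule.values
        xs = [self.sample(l, n_per_state, rng) for l in lams]
        x_all = np.concatenate(xs)
        u_kn = np.stack([self.reduced_potential(l, x_all) for l in lams])
        return ReducedPotentialMatrix(
            u_kn=u_kn, n_k=np.full(lams.size, n_per_state, dtype=int)
        )


def _model_acceptances(
    model, lams: np.ndarray, z: np.ndarray
) -> np.ndarray:
    """Neighbour acceptances under common random numbers ``z`` (K, n)."""
    acc = np.empty(lams.size - 1)
    for i in range(lams.size - 1):
        la, lb = lams[i], lams[i + 1]
        x = model.transform(la, z[i])
        y = model.transform(lb, z[i + 1])
        delta = (
            model.reduced_potential(la, y)
            + model.reduced_potential(lb, x)
            - model.reduced_potential(la, x)
            - model.reduced_potential(lb, y)
        )
        acc[i] = float(np.mean(np.minimum(1.0, np.exp(-delta))))
    return acc


class ScheduleError(RuntimeError):
    """The acceptance target is unreachable with the given window count."""


def optimize_lambda_schedule(
    model,
    n_windows: int,
    target_acceptance: float = 0.10,
    n_pilot: int = 2000,
    seed: int = 0,
    max_iter: int = 300,
    learning_rate: float = 0.5,
    initial: LambdaSchedule | None = None,
) -> tuple[LambdaSchedule, dict]:
    """Place lambda windows by gradient descent on acceptance equalization.

    The loss is the variance of neighbour-pair acceptances plus a quadratic
    penalty when the minimum acceptance is below ``target_acceptance``;
    interior windows move along the finite-difference gradient in an
    unconstrained increment parameterization (softmax), so the schedule
    stays strictly monotone with fixed endpoints.  Acceptances are
    estimated from ``n_pilot`` common-random-number draws per window, which
    makes the loss smooth and the procedure deterministic under a seed.

    Returns the schedule and a diagnostics dict (per-pair acceptances,
    minimum acceptance, iterations, loss definition).  Raises
    :class:`ScheduleError` if the optimized schedule still misses the
    target — use more windows.
    """
    if n_windows < 2:
        raise ValueError("need at least two windows")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_windows, n_pilot))

    start = initial or LambdaSchedule.uniform(n_windows)
    # increment parameterization: lam = cumsum(softmax(theta))
    gaps = np.diff(start.values)
    theta = np.log(gaps)

    def lams_of(th: np.ndarray) -> np.ndarray:
        w = np.exp(th - th.max())
        lam = np.concatenate(([0.0], np.cumsum(w) / w.sum()))
        lam[-1] = 1.0
        return lam

    def loss_of(th: np.ndarray) -> tuple[float, np.ndarray]:
        acc = _model_acceptances(model, lams_of(th), z)
        shortfall = max(0.0, target_acceptance - acc.min())
        return float(np.var(acc) + 25.0 * shortfall**2), acc

    loss, acc = loss_of(theta)
    lr = learning_rate
    n_done = 0
    for n_done in range(1, max_iter + 1):
        grad = np.empty_like(theta)
        h = 1e-4
        for i in range(theta.size):
            tp = theta.copy()
            tp[i] += h
            tm = theta.copy()
            tm[i] -= h
            grad[i] = (loss_of(tp)[0] - loss_of(tm)[0]) / (2 * h)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-12:
            break
        step = lr * grad / max(gnorm, 1e-12)
        new_theta = theta - step
        new_loss, new_acc = loss_of(new_theta)
        if new_loss < loss:
            theta, loss, acc = new_theta, new_loss, new_acc
            lr = min(lr * 1.2, 2.0)
        else:
            lr *= 0.5
            if lr < 1e-6:
                break

    schedule = LambdaSchedule(lams_of(theta))
    diagnostics = {
        "acceptances": acc,
        "min_acceptance": float(acc.min()),
        "n_iterations": n_done,
        "loss": "variance of neighbour acceptances + 25*max(0, target - min)^2",
        "target_acceptance": target_acceptance,
    }
    if acc.min() < target_acceptance:
        raise ScheduleError(
            f"minimum neighbour acceptance {acc.min():.3f} is below the "
            f"target {target_acceptance:.3f} with {n_windows} windows; "
            "increase the window count"
        )
    return schedule, diagnostics


# --------------------------------------------------------------------------
# Thermodynamic cycle and enthalpic decomposition
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ThermoCycleResult:
    """DDG = DG_m2 - DG_m1 (kcal/mol) with quadrature-propagated error."""

    dg_m1: float
    dg_m1_err: float
    dg_m2: float
    dg_m2_err: float

    @property
    def ddg(self) -> float:
        return self.dg_m2 - self.dg_m1

    @property
    def ddg_err(self) -> float:
        return math.hypot(self.dg_m1_err, self.dg_m2_err)


def thermodynamic_cycle(
    dg_m1: float, dg_m1_err: float, dg_m2: float, dg_m2_err: float
) -> ThermoCycleResult:
    """Close the cycle: transformation without DNA (m1) vs DNA-bound (m2)."""
    if dg_m1_err < 0 or dg_m2_err < 0:
        raise ValueError("errors must be >= 0")
    return ThermoCycleResult(dg_m1, dg_m1_err, dg_m2, dg_m2_err)


@dataclass(frozen=True)
class DecompositionResult:
    """Per-group end-state interaction-energy changes with block errors.

    ``delta_e['prot-rest']`` is the remainder so that the group terms sum
    to the total protein-DNA change exactly.
    """

    delta_e: dict[str, float]  # kJ/mol
    errors: dict[str, float]  # kJ/mol
    total: float
    total_error: float
    n_blocks: int
    discard_fraction: float


def _block_stats(series: np.ndarray, n_blocks: int) -> tuple[float, float]:
    n = series.size
    if n < n_blocks:
        raise ValueError(f"need at least {n_blocks} frames, got {n}")
    usable = n - n % n_blocks
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    se = float(blocks.std(ddof=1) / math.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    return float(series.mean()), se


def interaction_energy_decomposition(
    group_series: Mapping[str, tuple[np.ndarray, np.ndarray]],
    total_series: tuple[np.ndarray, np.ndarray] | None = None,
    discard_fraction: float = 0.10,
    n_blocks: int = 5,
) -> DecompositionResult:
    """Average end-state interaction-energy changes per residue group.

    ``group_series`` maps a group label to its (lambda=0, lambda=1)
    interaction-energy series (kJ/mol); ``total_series`` is the overall
    protein-DNA pair.  For every series the first ``discard_fraction`` of
    frames is discarded as equilibration, the remainder split into
    ``n_blocks`` contiguous blocks; the standard error of the block means
    is combined across the two end states in quadrature.  When a total is
    given, a ``prot-rest`` remainder term (computed frame-wise, so the
    partition is exact) completes the table.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")

    def prep(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        start = int(round(discard_fraction * x.size))
        out = x[start:]
        if out.size < n_blocks:
            raise ValueError(
                f"series too short: {out.size} frames after discard, "
                f"{n_blocks} blocks requested"
            )
        return out

    delta_e: dict[str, float] = {}
    errors: dict[str, float] = {}
    sums: dict[int, np.ndarray] = {}
    for label, (s0, s1) in group_series.items():
        a0, a1 = prep(s0), prep(s1)
        m0, se0 = _block_stats(a0, n_blocks)
        m1, se1 = _block_stats(a1, n_blocks)
        delta_e[label] = m1 - m0
        errors[label] = math.hypot(se0, se1)
        for end, arr in ((0, a0), (1, a1)):
            sums[end] = arr.copy() if end not in sums else sums[end] + arr

    if total_series is not None:
        t0, t1 = prep(total_series[0]), prep(total_series[1])
        if t0.shape != sums[0].shape or t1.shape != sums[1].shape:
            raise ValueError("total and group series must be frame-aligned")
        r0, r1 = t0 - sums[0], t1 - sums[1]
        m0, se0 = _block_stats(r0, n_blocks)
        m1, se1 = _block_stats(r1, n_blocks)
        delta_e["prot-rest"] = m1 - m0
        errors["prot-rest"] = math.hypot(se0, se1)
        tm0, tse0 = _block_stats(t0, n_blocks)
        tm1, tse1 = _block_stats(t1, n_blocks)
        total, total_err = tm1 - tm0, math.hypot(tse0, tse1)
    else:
        total = float(sum(delta_e.values()))
        total_err = float("nan")
    return DecompositionResult(
        delta_e=delta_e,
        errors=errors,
        total=total,
        total_error=total_err,
        n_blocks=n_blocks,
        discard_fraction=discard_fraction,
    )
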