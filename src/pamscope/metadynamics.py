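"""Well-tempered metadynamics: bias assembly, free-energy recovery, toy engine.

The history-dependent bias is a sum of Gaussian hills deposited every
``t_G`` ps.  In the well-tempered variant each hill is deposited with the
instantaneous height ``omega * t_G * exp(-V(s)/(kB*DeltaT))`` where ``V(s)``
is the bias already present at the deposition point and
``DeltaT = (gamma - 1) * T`` with bias factor ``gamma``.  The free energy is
recovered from the asymptotic bias as

    F(s) = -(T + DeltaT)/DeltaT * V(s) = -gamma/(gamma - 1) * V(s)

up to an additive constant, fixed here by shifting min(F) to zero.

Defaults follow the production setup this toolkit models: omega = 1.0
kJ/mol/ps, t_G = 10 ps, gamma = 4 at 300 K, one-sided harmonic walls of
3500 kJ/(mol nm^2) limiting the CVs to 0.3-1.2 nm.  Hill widths are not part
of that setup and default to 0.05 nm per CV.

A multiple-walker overdamped-Langevin engine on the analytic potentials of
:mod:`pamscope.synthetic` validates the reconstruction end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .units import KB

__all__ = [
    "HillRecord",
    "MetadParams",
    "FreeEnergySurface",
    "bias_potential",
    "free_energy_surface",
    "wall_force",
    "run_wt_metad",
    "convergence_profile",
    "basin_delta_f",
    "read_hills",
    "write_hills",
]


@dataclass(frozen=True)
class HillRecord:
    """One deposited Gaussian hill."""

    time: float  # ps
    center: tuple[float, ...]  # nm, one entry per CV
    widths: tuple[float, ...]  # nm
    nominal_height: float  # kJ/mol, omega * t_G
    scaled_height: float  # kJ/mol, after the well-tempered factor

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be > 0")
        if not 0.0 < self.scaled_height <= self.nominal_height * (1 + 1e-12):
            raise ValueError("scaled height must be in (0, nominal height]")
        if len(self.center) != len(self.widths):
            raise ValueError("center and widths dimensionality mismatch")


@dataclass(frozen=True)
class MetadParams:
    """Well-tempered metadynamics parameters."""

    omega: float = 1.0  # deposition rate, kJ/mol/ps
    t_g: float = 10.0  # deposition stride, ps
    bias_factor: float = 4.0  # gamma = (T + DeltaT)/T
    temperature: float = 300.0  # K
    wall_low: float = 0.3  # nm
    wall_high: float = 1.2  # nm
    wall_k: float = 3500.0  # kJ/(mol nm^2)
    sigma: tuple[float, ...] = (0.05,)  # nm per CV

    def __post_init__(self) -> None:
        if self.bias_factor <= 1.0:
            raise ValueError("bias factor must be > 1")
        if self.omega <= 0 or self.t_g <= 0:
            raise ValueError("omega and t_g must be > 0")

    @property
    def delta_t(self) -> float:
        """DeltaT in K."""
        return (self.bias_factor - 1.0) * self.temperature

    @property
    def kb_delta_t(self) -> float:
        """kB*DeltaT in kJ/mol (the tempering energy scale)."""
        return KB * self.delta_t

    @property
    def nominal_height(self) -> float:
        return self.omega * self.t_g

    @property
    def fes_prefactor(self) -> float:
        """-(T+DeltaT)/DeltaT = -gamma/(gamma-1)."""
        return -self.bias_factor / (self.bias_factor - 1.0)


@dataclass
class FreeEnergySurface:
    """F on a regular CV lattice, min-shifted to zero (kJ/mol)."""

    axes: tuple[np.ndarray, ...]
    F: np.ndarray
    time: float = math.inf  # hills up to this time contributed

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.F)):
            raise ValueError("free energy must be finite on the grid")
        if abs(float(self.F.min())) > 1e-9:
            raise ValueError("free energy must be min-shifted to 0")

    @property
    def ndim(self) -> int:
        return len(self.axes)


def _hill_arrays(hills: Sequence[HillRecord]):
    centers = np.array([h.center for h in hills], dtype=float)  # (H, d)
    widths = np.array([h.widths for h in hills], dtype=float)
    heights = np.array([h.scaled_height for h in hills], dtype=float)
    return centers, widths, heights


def bias_potential(
    hills: Sequence[HillRecord], s: float | Sequence[float] | np.ndarray,
    params: MetadParams | None = None,
) -> float | np.ndarray:
    """Evaluate the accumulated bias V(s) in kJ/mol.

    ``s`` may be a scalar (1D CV), a d-vector, or an array of points with
    the CV dimension last.  Each hill contributes with the height recorded
    at deposition time.
    """
    s_arr = np.asarray(s, dtype=float)
    times = [h.time for h in hills]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("hills must be time-ordered")
    d = len(hills[0].center) if hills else 1
    # normalize to an (n, d) point list and remember the output shape
    if s_arr.ndim == 0:
        pts, out_shape, scalar = s_arr.reshape(1, 1), (), True
    elif s_arr.ndim == 1 and d == 1:
        pts, out_shape, scalar = s_arr.reshape(-1, 1), s_arr.shape, False
    elif s_arr.ndim == 1 and s_arr.shape == (d,):
        pts, out_shape, scalar = s_arr.reshape(1, d), (), True
    else:
        if s_arr.shape[-1] != d:
            raise ValueError(f"points have CV dimension {s_arr.shape[-1]}, hills {d}")
        pts, out_shape, scalar = s_arr.reshape(-1, d), s_arr.shape[:-1], False
    if not hills:
        v = np.zeros(pts.shape[0])
    else:
        centers, widths, heights = _hill_arrays(hills)
        expo = ((pts[:, None, :] - centers[None, :, :]) ** 2 /
                (2.0 * widths[None, :, :] ** 2)).sum(axis=2)
        v = (heights[None, :] * np.exp(-expo)).sum(axis=1)
    if scalar:
        return float(v[0])
    return v.reshape(out_shape)


def free_energy_surface(
    hills: Sequence[HillRecord],
    grid: np.ndarray | Sequence[np.ndarray],
    params: MetadParams,
    time: float = math.inf,
) -> FreeEnergySurface:
    """Recover F on a grid from deposited hills up to ``time``.

    ``grid`` is one axis array (1D CV) or a sequence of axis arrays (one per
    CV); the surface is evaluated on their tensor product.  The additive
    constant C(T) is absorbed by min-shifting.
    """
    axes = (np.asarray(grid, float),) if np.ndim(grid[0]) == 0 else tuple(
        np.asarray(g, float) for g in grid
    )
    kept = [h for h in hills if h.time <= time]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    if kept:
        v = bias_potential(kept, pts if len(axes) > 1 else pts[:, 0])
        v = np.asarray(v, float).reshape(mesh[0].shape)
    else:
        v = np.zeros(mesh[0].shape)
    f = params.fes_prefactor * v
    f = f - f.min()
    return FreeEnergySurface(axes=axes, F=f, time=time)


def wall_force(
    s: float | np.ndarray, params: MetadParams
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """One-sided harmonic restraints at the CV range bounds.

    Returns ``(energy, gradient)``: ``0.5*k*(s-bound)^2`` beyond each bound,
    zero (with continuous gradient) inside.
    """
    s_arr = np.asarray(s, dtype=float)
    lo_over = np.minimum(s_arr - params.wall_low, 0.0)
    hi_over = np.maximum(s_arr - params.wall_high, 0.0)
    energy = 0.5 * params.wall_k * (lo_over**2 + hi_over**2)
    grad = params.wall_k * (lo_over + hi_over)
    if np.ndim(s) == 0:
        return float(energy), float(grad)
    return energy, grad


class _GridBias1D:
    """Linear-interpolation bias accumulator for the 1D engine."""

    def __init__(self, lo: float, hi: float, n: int):
        self.x = np.linspace(lo, hi, n)
        self.dx = self.x[1] - self.x[0]
        self.lo = lo
        self.hi = hi
        self.n = n
        self.v = np.zeros(n)
        self.dv = np.zeros(n)

    def add_hill(self, c: float, sigma: float, h: float) -> None:
        g = h * np.exp(-((self.x - c) ** 2) / (2.0 * sigma**2))
        self.v += g
        self.dv = np.gradient(self.v, self.dx)

    def value(self, s: float) -> float:
        if s <= self.lo:
            return float(self.v[0])
        if s >= self.hi:
            return float(self.v[-1])
        i = int((s - self.lo) / self.dx)
        f = (s - self.lo) / self.dx - i
        return float(self.v[i] * (1 - f) + self.v[i + 1] * f)

    def grad(self, s: float) -> float:
        if s <= self.lo or s >= self.hi:
            return 0.0
        i = int((s - self.lo) / self.dx)
        f = (s - self.lo) / self.dx - i
        return float(self.dv[i] * (1 - f) + self.dv[i + 1] * f)


def run_wt_metad(
    potential,
    params: MetadParams,
    n_walkers: int = 1,
    n_steps: int = 100_000,
    dt: float = 0.01,
    friction: float = 50.0,
    seed: int = 0,
    x0: Sequence[float] | None = None,
    grid_bounds: tuple[float, float] = (0.25, 1.25),
    grid_points: int = 201,
) -> tuple[list[HillRecord], np.ndarray]:
    """Run well-tempered metadynamics with overdamped Langevin walkers (1D).

    All walkers feel (and grow) one shared bias; every ``t_g`` of simulated
    time the active walker — chosen round-robin — deposits a hill whose
    height is tempered by ``exp(-V(s)/(kB*DeltaT))`` with ``V`` the bias
    already present at its position.  Returns the hill list and the CV
    trajectory of shape ``(n_steps + 1, n_walkers)``.

    ``n_steps`` counts per-walker integration steps; the bias is kept on a
    linear-interpolation grid so the cost per step is O(1) in the number of
    hills.
    """
    if getattr(potential, "ndim", 1) != 1:
        raise ValueError("the toy engine supports 1D collective variables")
    if params.bias_factor <= 1.0:
        raise ValueError("bias factor must be > 1")
    rng = np.random.default_rng(seed)
    kt = KB * params.temperature
    sigma_cv = params.sigma[0]
    stride = max(1, int(round(params.t_g / dt)))
    bias = _GridBias1D(grid_bounds[0], grid_bounds[1], grid_points)
    if x0 is None:
        xs = [
            params.wall_low
            + (params.wall_high - params.wall_low) * (w + 0.5) / n_walkers
            for w in range(n_walkers)
        ]
    else:
        xs = [float(v) for v in x0]
        if len(xs) != n_walkers:
            raise ValueError("x0 must provide one start per walker")
    noise_scale = math.sqrt(2.0 * kt * dt / friction)
    inv_friction_dt = dt / friction
    hills: list[HillRecord] = []
    cv = np.empty((n_steps + 1, n_walkers))
    cv[0] = xs
    deposit_idx = 0
    nominal = params.nominal_height
    kb_dt = params.kb_delta_t
    # noise drawn per step per walker in one array (bit-reproducible)
    noise = rng.standard_normal((n_steps, n_walkers)) * noise_scale
    for step in range(n_steps):
        for w in range(n_walkers):
            x = xs[w]
            g = float(potential.gradient(x)) + bias.grad(x)
            g += wall_force(x, params)[1]
            xs[w] = x - g * inv_friction_dt + noise[step, w]
        cv[step + 1] = xs
        if (step + 1) % stride == 0:
            w = deposit_idx % n_walkers
            deposit_idx += 1
            c = xs[w]
            v_here = bias.value(c)
            h = nominal * math.exp(-v_here / kb_dt)
            hills.append(
                HillRecord(
                    time=(step + 1) * dt,
                    center=(c,),
                    widths=(sigma_cv,),
                    nominal_height=nominal,
                    scaled_height=h,
                )
            )
            bias.add_hill(c, sigma_cv, h)
    return hills, cv


def basin_delta_f(
    fes: FreeEnergySurface,
    basin_a: tuple[float, float],
    basin_b: tuple[float, float],
    temperature: float,
) -> float:
    """F(A) - F(B) in kJ/mol by Boltzmann integration over 1D basin windows.

    Less grid-sensitive than comparing minima: each basin free energy is
    ``-kT * ln sum exp(-F/kT) dx`` over the basin interval.
    """
    if fes.ndim != 1:
        raise ValueError("basin integration implemented for 1D surfaces")
    kt = KB * temperature
    x, f = fes.axes[0], fes.F

    def basin_f(lo: float, hi: float) -> float:
        m = (x >= lo) & (x <= hi)
        if not m.any():
            raise ValueError(f"basin [{lo}, {hi}] lies outside the grid")
        w = np.exp(-f[m] / kt)
        return -kt * math.log(np.trapezoid(w, x[m]))

    return basin_f(*basin_a) - basin_f(*basin_b)


def convergence_profile(
    hills: Sequence[HillRecord],
    checkpoints: Sequence[float],
    grid: np.ndarray | Sequence[np.ndarray],
    params: MetadParams,
    basin_a: tuple[float, float],
    basin_b: tuple[float, float],
) -> np.ndarray:
    """Basin DeltaF(t) from the surface truncated at each checkpoint time."""
    if len(checkpoints) == 0:
        raise ValueError("need at least one checkpoint time")
    out = []
    for t in checkpoints:
        fes = free_energy_surface(hills, grid, params, time=t)
        out.append(basin_delta_f(fes, basin_a, basin_b, params.temperature))
    return np.array(out)


# --------------------------------------------------------------------------
# HILLS text format (PLUMED dialect)
# --------------------------------------------------------------------------


def write_hills(
    hills: Sequence[HillRecord], path: str | Path, params: MetadParams,
    cv_names: Sequence[str] | None = None,
) -> None:
    """Write hills in the PLUMED HILLS dialect.

    Columns: time, one center per CV, one sigma per CV, height (the
    deposited, tempered height) and the bias factor.
    """
    d = len(hills[0].center) if hills else len(params.sigma)
    names = list(cv_names) if cv_names else [f"cv{i+1}" for i in range(d)]
    with open(path, "w") as fh:
        fields = ["time", *names, *(f"sigma_{n}" for n in names), "height", "biasf"]
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for h in hills:
            row = [h.time, *h.center, *h.widths, h.scaled_height, params.bias_factor]
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_hills(path: str | Path) -> tuple[list[HillRecord], float]:
    """Read a PLUMED-dialect HILLS file; returns (hills, bias_factor).

    The file stores the deposited (already tempered) height; the nominal
    height of each record is set to the stored height, which preserves the
    bias sum exactly.
    """
    hills: list[HillRecord] = []
    biasf = math.nan
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            vals = [float(v) for v in s.split()]
            # time + d centers + d sigmas + height + biasf -> 2d + 3 columns
            if len(vals) < 5 or len(vals) % 2 == 0:
                raise ValueError(f"{path}: bad HILLS row at line {ln}")
            d = (len(vals) - 3) // 2
            biasf = vals[-1]
            hills.append(
                HillRecord(
                    time=vals[0],
                    center=tuple(vals[1 : 1 + d]),
                    widths=tuple(vals[1 + d : 1 + 2 * d]),
                    nominal_height=vals[-2],
                    scaled_height=vals[-2],
                )
            )
    return hills, biasf
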