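"""Benchmark Lagrangian trajectory generators.

Three seeded ensembles exercise every qualitative regime the clustering
method is meant to resolve:

* an unsteady **quadruple-eddy** gyre flow (four counter-rotating cells on
  ``[0,2] x [-1,1]`` with an east-west oscillation that exchanges tracers
  between eastern and western cells),
* the **Bickley jet**, a meandering zonal jet with flanking eddies on a
  domain periodic in x (dimensional parameters typical of atmospheric
  zonal flow),
* a **uniform-noise control** with no coherent structure at all.

Tracers are advected with a fixed-step fifth-order Cash-Karp Runge-Kutta
scheme, vectorized over the ensemble.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dissimilarity import TrajectoryEnsemble
from .errors import InputError

__all__ = [
    "QuadrupleEddyParams",
    "BickleyParams",
    "quadruple_eddy_velocity",
    "bickley_velocity",
    "advect_ensemble",
    "quadruple_eddy_ensemble",
    "bickley_ensemble",
    "random_noise_ensemble",
]

DAY = 86400.0  # seconds


@dataclass(frozen=True)
class QuadrupleEddyParams:
    """Parameters of the unsteady quadruple-eddy flow (dimensionless).

    The stream function is ``psi = A sin(pi f(x, t)) sin(pi y)`` with
    ``f = a x^2 + b x``, ``a = eps sin(omega t)``, ``b = 1 - 2 eps sin(omega t)``,
    giving four closed recirculation cells whose internal east-west boundary
    oscillates with period ``2 pi / omega``.
    """

    amplitude: float = 0.1
    epsilon: float = 0.1
    omega: float = 2.0 * math.pi / 10.0
    x_range: tuple[float, float] = (0.0, 2.0)
    y_range: tuple[float, float] = (-1.0, 1.0)
    t_span: tuple[float, float] = (0.0, 40.0)

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.omega <= 0:
            raise InputError("amplitude and omega must be positive")


@dataclass(frozen=True)
class BickleyParams:
    """Parameters of the Bickley jet (SI units).

    Stream function ``psi = psi0 + psi1`` with

        psi0 = c3 y - U L tanh(y/L)
        psi1 = U L sech^2(y/L) * sum_n eps_n cos(k_n (x - sigma_n t))

    where ``k_n = 2 n / r0`` (``r0``: Earth's mean radius), phase speeds
    ``c = (0.1446 U, 0.205 U, 0.461 U)`` and ``sigma_n = c_n - c_3``.  The
    x direction is periodic with the domain length.
    """

    U: float = 62.66          # jet speed, m/s
    L: float = 1.77e6         # jet width scale, m
    r0: float = 6.371e6       # reference radius for the wavenumbers, m
    eps: tuple[float, float, float] = (0.0075, 0.15, 0.3)
    c_factors: tuple[float, float, float] = (0.1446, 0.205, 0.461)
    x_range: tuple[float, float] = (0.0, 2.0e7)
    y_range: tuple[float, float] = (-3.0e6, 3.0e6)
    t_span_days: tuple[float, float] = (0.0, 40.0)

    def __post_init__(self) -> None:
        if self.U <= 0 or self.L <= 0 or self.r0 <= 0:
            raise InputError("U, L and r0 must be positive")
        if len(self.eps) != 3 or len(self.c_factors) != 3:
            raise InputError("eps and c_factors must each have three entries")

    @property
    def c(self) -> np.ndarray:
        """Wave phase speeds, m/s."""
        return self.U * np.asarray(self.c_factors)

    @property
    def sigma(self) -> np.ndarray:
        """Phase speeds in the frame co-moving with wave 3: ``c_n - c_3``."""
        c = self.c
        return c - c[2]

    @property
    def k(self) -> np.ndarray:
        """Zonal wavenumbers ``k_n = 2 n / r0``, 1/m."""
        return 2.0 * np.arange(1, 4) / self.r0

    @property
    def period_x(self) -> float:
        return self.x_range[1] - self.x_range[0]


def quadruple_eddy_velocity(x, y, t, params: QuadrupleEddyParams | None = None):
    """Velocity ``(u, v)`` of the quadruple-eddy flow; accepts arrays.

    ``u = -pi A sin(pi f) cos(pi y)``, ``v = pi A cos(pi f) sin(pi y) (2 a x + b)``
    (the divergence-free pair derived from the stream function).
    """
    p = params or QuadrupleEddyParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = p.epsilon * np.sin(p.omega * t)
    b = 1.0 - 2.0 * p.epsilon * np.sin(p.omega * t)
    f = a * x * x + b * x
    piA = math.pi * p.amplitude
    u = -piA * np.sin(math.pi * f) * np.cos(math.pi * y)
    v = piA * np.cos(math.pi * f) * np.sin(math.pi * y) * (2.0 * a * x + b)
    return u, v


def bickley_velocity(x, y, t, params: BickleyParams | None = None):
    """Velocity ``(u, v)`` of the Bickley jet at time ``t`` (seconds).

    Analytic derivatives of the stream function:
    ``u = U sech^2(y/L) - c3 + 2 U sech^2(y/L) tanh(y/L) sum_n eps_n cos(theta_n)``
    and ``v = -U L sech^2(y/L) sum_n eps_n k_n sin(theta_n)`` with
    ``theta_n = k_n (x - sigma_n t)``.
    """
    p = params or BickleyParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    yl = y / p.L
    sech2 = 1.0 / np.cosh(yl) ** 2
    tanh = np.tanh(yl)
    k = p.k
    sig = p.sigma
    c3 = p.c[2]
    theta = k * (x[..., None] - sig * t)  # (..., 3)
    eps = np.asarray(p.eps)
    cos_sum = np.sum(eps * np.cos(theta), axis=-1)
    sin_sum = np.sum(eps * k * np.sin(theta), axis=-1)
    u = p.U * sech2 - c3 + 2.0 * p.U * sech2 * tanh * cos_sum
    v = -p.U * p.L * sech2 * sin_sum
    return u, v


# Cash-Karp fifth-order Runge-Kutta coefficients
_CK_A = (
    (1 / 5,),
    (3 / 40, 9 / 40),
    (3 / 10, -9 / 10, 6 / 5),
    (-11 / 54, 5 / 2, -70 / 27, 35 / 27),
    (1631 / 55296, 175 / 512, 575 / 13824, 44275 / 110592, 253 / 4096),
)
_CK_C = (0.0, 1 / 5, 3 / 10, 3 / 5, 1.0, 7 / 8)
_CK_B5 = (37 / 378, 0.0, 250 / 621, 125 / 594, 0.0, 512 / 1771)


def _cash_karp_step(f: Callable, t: float, y: np.ndarray, h: float) -> np.ndarray:
    """One fixed step of the fifth-order Cash-Karp scheme."""
    ks = [f(t, y)]
    for ci, ai in zip(_CK_C[1:], _CK_A):
        yi = y + h * sum(a * k for a, k in zip(ai, ks))
        ks.append(f(t + ci * h, yi))
    return y + h * sum(b * k for b, k in zip(_CK_B5, ks) if b)


def advect_ensemble(
    velocity: Callable,
    n: int,
    seed: int,
    *,
    domain,
    t_span: tuple[float, float],
    dt: float,
    n_saved: int,
    periodic_lengths=None,
    labels=None,
    clamp: bool = True,
) -> TrajectoryEnsemble:
    """Seed ``n`` tracers uniformly over the domain and advect them.

    Parameters
    ----------
    velocity
        Callable ``velocity(t, pos)`` mapping ``(n, d)`` positions to
        ``(n, d)`` velocities.
    domain
        Sequence of ``(lo, hi)`` per dimension; initial positions are drawn
        uniformly over it.
    dt
        Requested integration step.  Each save interval is subdivided into
        an integer number of steps of size ``<= dt``, so saved times are hit
        exactly.
    n_saved
        Number of uniformly spaced saved samples over ``t_span`` (endpoints
        included).
    periodic_lengths
        As in :class:`TrajectoryEnsemble`; positions in periodic dimensions
        are stored unwrapped (minimum-image distances are applied by the
        dissimilarity metric).
    clamp
        When true (default), tracers leaving a non-periodic domain are
        clamped to it with a warning — for flows whose boundaries are
        invariant streamlines this indicates an integration-step failure.
        Set false when the domain only delimits the seeding region and the
        velocity field extends beyond it.
    """
    if n < 2:
        raise InputError("at least two tracers are required")
    if n_saved < 2:
        raise InputError("n_saved must be at least 2")
    if dt <= 0:
        raise InputError("dt must be positive")
    dom = np.asarray(domain, dtype=float)
    if dom.ndim != 2 or dom.shape[1] != 2:
        raise InputError("domain must be a sequence of (lo, hi) pairs")
    d = dom.shape[0]
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise InputError("t_span must be increasing")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(dom[:, 0], dom[:, 1], size=(n, d))
    save_times = np.linspace(t0, t1, n_saved)
    out = np.empty((n, n_saved, d))
    out[:, 0] = pos
    t = t0
    for s in range(n_saved - 1):
        span = save_times[s + 1] - save_times[s]
        m = max(1, math.ceil(span / dt - 1e-12))
        h = span / m
        for _ in range(m):
            pos = _cash_karp_step(velocity, t, pos, h)
            t += h
        t = save_times[s + 1]  # avoid accumulation drift
        out[:, s + 1] = pos

    per = None
    if periodic_lengths is not None:
        per = np.asarray(periodic_lengths, dtype=float)
    clamped = 0
    for j in range(d):
        if not clamp or (per is not None and np.isfinite(per[j])):
            continue
        lo, hi = dom[j]
        esc = (out[:, :, j] < lo - 1e-9) | (out[:, :, j] > hi + 1e-9)
        if np.any(esc):
            clamped += int(np.sum(np.any(esc, axis=1)))
            out[:, :, j] = np.clip(out[:, :, j], lo, hi)
    if clamped:
        warnings.warn(
            f"{clamped} tracer(s) escaped the non-periodic domain and were "
            "clamped; consider a smaller integration step",
            stacklevel=2,
        )
    return TrajectoryEnsemble(
        positions=out, times=save_times, periodic_lengths=per, labels=labels
    )


def quadruple_eddy_ensemble(
    n: int,
    seed: int,
    params: QuadrupleEddyParams | None = None,
    n_saved: int = 401,
    dt: float = 0.01,
) -> TrajectoryEnsemble:
    """Advect ``n`` drifters in the quadruple-eddy flow (defaults: 40 time
    units = four oscillation periods, 401 saved samples, dt = 0.01)."""
    p = params or QuadrupleEddyParams()

    def f(t, pos):
        u, v = quadruple_eddy_velocity(pos[:, 0], pos[:, 1], t, p)
        return np.stack([u, v], axis=1)

    return advect_ensemble(
        f,
        n,
        seed,
        domain=(p.x_range, p.y_range),
        t_span=p.t_span,
        dt=dt,
        n_saved=n_saved,
    )


def bickley_ensemble(
    n: int,
    seed: int,
    params: BickleyParams | None = None,
    n_saved: int = 601,
    n_steps: int = 4000,
) -> TrajectoryEnsemble:
    """Advect ``n`` particles in the Bickley jet over 40 days, 601 saved
    samples, with the 40-day span divided into ``n_steps`` integration steps
    (x treated as periodic).  The stated y extent only bounds the seeding;
    the velocity field is defined for all y and particles may leave it."""
    p = params or BickleyParams()
    t_span = (p.t_span_days[0] * DAY, p.t_span_days[1] * DAY)
    dt = (t_span[1] - t_span[0]) / n_steps

    def f(t, pos):
        u, v = bickley_velocity(pos[:, 0], pos[:, 1], t, p)
        return np.stack([u, v], axis=1)

    return advect_ensemble(
        f,
        n,
        seed,
        domain=(p.x_range, p.y_range),
        t_span=t_span,
        dt=dt,
        n_saved=n_saved,
        periodic_lengths=(p.period_x, np.nan),
        clamp=False,
    )


def random_noise_ensemble(n: int, T: int, seed: int) -> TrajectoryEnsemble:
    """Structureless control: i.i.d. uniform positions on the unit square.

    Each state's position at each of the ``T`` time samples is drawn
    independently from ``U(0,1)^2``; there is no coherent structure by
    construction, so a sound clustering should keep nearly all states in a
    single dominant branch.
    """
    if n < 2 or T < 2:
        raise InputError("need n >= 2 states and T >= 2 time samples")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1.0, size=(n, T, 2))
    return TrajectoryEnsemble(positions=positions, times=np.arange(T, dtype=float))
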