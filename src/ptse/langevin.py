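"""Langevin propagation on the analytic surfaces.

Two integration schemes:

* ``baoab`` — Leimkuhler–Matthews splitting for inertial Langevin
  dynamics; stable canonical sampling at moderate time steps.
* ``overdamped`` — the Leimkuhler–Matthews discretization of the
  overdamped (Brownian) limit dx = −∇V/γ dt + √(2kT/γ) dW, which
  averages consecutive noise increments and thereby samples
  configurational averages to second order in dt (plain Euler–Maruyama
  inflates the stationary variance of a stiff restrained coordinate at
  first order, which would bias steered work distributions).  All
  closed-form committor oracles assume this limit.

A harmonic restraint may act on the reaction coordinate: force
−k(ξ(x) − λ)·∇ξ with a static or per-step center schedule λ.

The module-level :class:`BatchPropagator` advances many independent
walkers at once (vectorized over the leading axis); the public
:func:`run_langevin` is the single-trajectory recording front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .constants import thermal_energy
from .potentials import PotentialSpec, dimension, potential_functions, rc_value

__all__ = [
    "TrajectorySample",
    "IntegrationError",
    "BatchPropagator",
    "run_langevin",
    "draw_velocities",
]

#: (kcal/mol) / (g/mol)  expressed in Å²/ps² — converts kT/m to a squared
#: velocity in physical units.  In reduced mode the factor is 1.
KCAL_PER_AMU_TO_A2_PS2 = 418.4


@dataclass
class TrajectorySample:
    """Recorded trajectory of one walker.

    All per-step arrays share the same length; ``times`` is uniform with
    spacing ``dt * record_stride``.
    """

    times: np.ndarray
    coordinates: np.ndarray  # (n_rec, dim)
    rc_values: np.ndarray
    energies: np.ndarray
    dt: float
    seed: int
    velocities: Optional[np.ndarray] = None
    restraint_record: Optional[np.ndarray] = None  # (n_rec, 2): center, k

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("coordinates", "rc_values", "energies"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != times length")
        if not np.all(np.isfinite(self.rc_values)):
            raise ValueError("non-finite reaction-coordinate values")
        dts = np.diff(self.times)
        if n > 1 and (np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-9)):
            raise ValueError("times must be strictly increasing with constant spacing")


class IntegrationError(RuntimeError):
    """Raised when a walker leaves the declared evaluation domain."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"trajectory diverged at step {step}")


def _velocity_factor(units_mode: str) -> float:
    return KCAL_PER_AMU_TO_A2_PS2 if units_mode == "physical" else 1.0


class BatchPropagator:
    """Advances a batch of independent walkers on one potential.

    Positions have shape (n_walkers, dim).  Each walker consumes an
    independent stream spawned from the seeds supplied to
    :meth:`__init__`, so results are reproducible and independent of the
    batch composition order.
    """

    def __init__(
        self,
        spec: PotentialSpec,
        dt: float,
        friction: float,
        temperature: float,
        seeds,
        scheme: str = "overdamped",
        mass: float = 1.0,
    ):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if friction <= 0:
            raise ValueError("friction must be > 0")
        if scheme not in ("overdamped", "baoab"):
            raise ValueError(f"unknown scheme: {scheme!r}")
        self.spec = spec
        self.dt = float(dt)
        self.friction = float(friction)
        self.temperature = float(temperature)
        self.scheme = scheme
        self.mass = float(mass)
        self.kT = thermal_energy(temperature, spec.units_mode)
        self._f = _velocity_factor(spec.units_mode)
        self.energy, self.gradient = potential_functions(spec)
        seeds = np.atleast_1d(np.asarray(seeds, dtype=np.int64))
        self.n_walkers = len(seeds)
        # one vector stream keyed on the full seed tuple: identical seed
        # lists reproduce bit-for-bit
        self.rng = np.random.default_rng(
            np.random.SeedSequence([int(s) for s in seeds])
        )
        self.dim = dimension(spec)
        # BAOAB O-step constants
        self._c1 = np.exp(-self.friction * self.dt)
        self._c2 = np.sqrt(self.kT / self.mass * self._f * (1.0 - self._c1**2))
        # overdamped constants (mobility 1/(γ m)); Leimkuhler–Matthews
        # averages the current and previous noise draw
        self._mob = self._f / (self.friction * self.mass)
        self._sig = np.sqrt(2.0 * self.kT * self._mob * self.dt)
        self._prev_noise: Optional[np.ndarray] = None

    # -- noise ---------------------------------------------------------
    def _normals(self) -> np.ndarray:
        return self.rng.standard_normal((self.n_walkers, self.dim))

    def draw_maxwell_boltzmann(self) -> np.ndarray:
        sd = np.sqrt(self.kT / self.mass * self._f)
        return sd * self._normals()

    # -- forces --------------------------------------------------------
    def total_gradient(self, x: np.ndarray, restraint_k, centers) -> np.ndarray:
        g = self.gradient(x)
        if restraint_k is not None:
            xi = rc_value(self.spec, x)
            dev = restraint_k * (xi - centers)
            if self.spec.family == "pt_surface_2d":
                g = g + np.stack([dev, -dev], axis=-1)
            else:
                g = g + dev[..., None]
        return g

    # -- stepping ------------------------------------------------------
    def step(self, x, v, restraint_k=None, centers=None):
        """One integration step; returns updated (x, v).  v is ignored
        (and returned as None) in the overdamped scheme."""
        if self.scheme == "overdamped":
            g = self.total_gradient(x, restraint_k, centers)
            noise = self._normals()
            if self._prev_noise is None:
                self._prev_noise = self._normals()
            x = x - g * self._mob * self.dt + self._sig * 0.5 * (
                self._prev_noise + noise
            )
            self._prev_noise = noise
            return x, None
        # BAOAB
        half = 0.5 * self.dt
        acc = -self.total_gradient(x, restraint_k, centers) / self.mass * self._f
        v = v + half * acc
        x = x + half * v
        v = self._c1 * v + self._c2 * self._normals()
        x = x + half * v
        acc = -self.total_gradient(x, restraint_k, centers) / self.mass * self._f
        v = v + half * acc
        return x, v

    def check_domain(self, x: np.ndarray, step: int) -> None:
        if np.any(np.abs(x) > self.spec.domain_bound) or not np.all(np.isfinite(x)):
            raise IntegrationError(step)

    def equilibrate(self, x, n_steps, restraint_k=None, centers=None, v=None):
        """Advance without recording; returns final (x, v)."""
        if self.scheme == "baoab" and v is None:
            v = self.draw_maxwell_boltzmann()
        for i in range(n_steps):
            x, v = self.step(x, v, restraint_k, centers)
            if i % 256 == 0:
                self.check_domain(x, i)
        self.check_domain(x, n_steps)
        return x, v


def run_langevin(
    spec: PotentialSpec,
    initial,
    n_steps: int,
    dt: float,
    friction: float,
    temperature: float,
    seed: int,
    restraint: Optional[Tuple[np.ndarray, float]] = None,
    scheme: str = "overdamped",
    mass: float = 1.0,
    record_stride: int = 1,
) -> TrajectorySample:
    """Propagate one walker and record a :class:`TrajectorySample`.

    Parameters
    ----------
    restraint
        Optional ``(center_schedule, force_constant)``.  The schedule is a
        scalar (static restraint) or an array of length ``n_steps + 1``
        giving the center before each step and at the end.
    record_stride
        Record every this many steps (step 0 always recorded).
    """
    x0 = np.atleast_1d(np.asarray(initial, dtype=float))
    prop = BatchPropagator(
        spec, dt, friction, temperature, [seed], scheme=scheme, mass=mass
    )
    if x0.shape != (prop.dim,):
        raise ValueError(f"initial must have shape ({prop.dim},)")

    if restraint is not None:
        centers_sched, rk = restraint
        centers_sched = np.broadcast_to(
            np.asarray(centers_sched, dtype=float), (n_steps + 1,)
        )
    else:
        centers_sched, rk = None, None

    x = x0[None, :]
    v = prop.draw_maxwell_boltzmann() if scheme == "baoab" else None
    n_rec = n_steps // record_stride + 1
    coords = np.empty((n_rec, prop.dim))
    vels = np.empty((n_rec, prop.dim)) if scheme == "baoab" else None
    restr = np.empty((n_rec, 2)) if restraint is not None else None
    idx = 0

    def record(i_step: int) -> None:
        nonlocal idx
        coords[idx] = x[0]
        if vels is not None:
            vels[idx] = v[0]
        if restr is not None:
            restr[idx] = (centers_sched[i_step], rk)
        idx += 1

    record(0)
    for i in range(n_steps):
        c = centers_sched[i + 1] if centers_sched is not None else None
        x, v = prop.step(x, v, rk, c)
        prop.check_domain(x, i + 1)
        if (i + 1) % record_stride == 0:
            record(i + 1)

    coords = coords[:idx]
    times = dt * record_stride * np.arange(idx)
    return TrajectorySample(
        times=times,
        coordinates=coords,
        rc_values=rc_value(spec, coords),
        energies=prop.energy(coords),
        dt=dt,
        seed=int(seed),
        velocities=vels[:idx] if vels is not None else None,
        restraint_record=restr[:idx] if restr is not None else None,
    )


def draw_velocities(
    temperature: float,
    masses,
    seed: int,
    units_mode: str = "reduced",
    n_dim: int = 1,
) -> np.ndarray:
    """Maxwell–Boltzmann velocity components for the given masses.

    Each component is N(0, kT/m); at T → 0 all velocities are zero.
    Returns shape ``(len(masses),)`` for n_dim == 1, else
    ``(len(masses), n_dim)``.
    """
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if np.any(masses <= 0):
        raise ValueError("masses must be > 0")
    kT = thermal_energy(temperature, units_mode)
    sd = np.sqrt(kT / masses * _velocity_factor(units_mode))
    rng = np.random.default_rng(int(seed))
    out = rng.standard_normal((len(masses), n_dim)) * sd[:, None]
    return out[:, 0] if n_dim == 1 else out
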