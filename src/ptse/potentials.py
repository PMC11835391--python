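"""Analytic surrogate energy surfaces.

These stand in for a first-principles energy function so that every
downstream estimator (Jarzynski, WHAM, committor) can be checked against
closed forms.  Four families:

``flat``
    V = 0 everywhere (free diffusion).
``harmonic``
    V = ½ k |x − c|².
``double_well_1d``
    Quartic double well with configurable well positions, barrier height
    and well-to-well asymmetry.  The reaction coordinate is x itself.
``pt_surface_2d``
    Two-coordinate surface over the two P–O bond distances
    (d_leave, d_attack) of a phosphoryl transfer.  Internally expressed in
    s = d_leave − d_attack (the reaction coordinate ξ) and
    q = d_leave + d_attack: a flat-top double well along s plus a harmonic
    valley in q whose center shifts between the wells and the saddle.
    ``ts_flatness`` sets the length of the flat plateau through the
    saddle; ``topology`` places the saddle at a smaller (tight) or larger
    (loose) d_leave + d_attack than the wells.

Because the q-valley force constant is independent of s, the exact
potential of mean force along ξ for ``pt_surface_2d`` is the s-profile
itself up to an additive constant (Gaussian integral over q), which is
what :func:`analytic_rc_profile` returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Tuple

import numpy as np

from .constants import thermal_energy

__all__ = [
    "PotentialSpec",
    "evaluate_potential",
    "potential_functions",
    "rc_value",
    "rc_direction",
    "analytic_rc_profile",
    "dimension",
]


@dataclass(frozen=True)
class PotentialSpec:
    """Parameters of one analytic surface plus its thermodynamic state."""

    family: str = "double_well_1d"
    barrier_height: float = 5.0
    well_positions: Tuple[float, float] = (-1.0, 1.0)
    asymmetry: float = 0.0
    ts_flatness: float = 0.0
    topology: str = "tight"
    temperature: float = 1.0
    units_mode: str = "reduced"
    # harmonic family
    force_constant: float = 1.0
    center: Tuple[float, ...] = (0.0,)
    # pt_surface_2d valley geometry (sums of the two P–O distances)
    valley_force_constant: float = 30.0
    q_well: float = 4.4
    q_saddle_tight: float = 3.6
    q_saddle_loose: float = 5.2
    domain_bound: float = 50.0

    def __post_init__(self) -> None:
        if self.family not in ("flat", "harmonic", "double_well_1d", "pt_surface_2d"):
            raise ValueError(f"unknown potential family: {self.family!r}")
        if self.family in ("double_well_1d", "pt_surface_2d"):
            if self.barrier_height <= 0:
                raise ValueError("barrier_height must be > 0")
            if self.well_positions[0] == self.well_positions[1]:
                raise ValueError("well positions must be distinct")
        if self.topology not in ("tight", "loose"):
            raise ValueError(f"topology must be 'tight' or 'loose', got {self.topology!r}")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature, self.units_mode)

    def with_temperature(self, temperature: float) -> "PotentialSpec":
        return replace(self, temperature=temperature)


def dimension(spec: PotentialSpec) -> int:
    """Number of Cartesian-like coordinates the family is defined over."""
    if spec.family == "pt_surface_2d":
        return 2
    if spec.family in ("flat", "harmonic"):
        return len(np.atleast_1d(spec.center))
    return 1


def _flat_top_map(s: np.ndarray, flat_len: float) -> Tuple[np.ndarray, np.ndarray]:
    """Odd, monotone map that squashes |s| < flat_len/2 toward zero.

    g(s) = s − (L/2)·tanh(2s/L); g' = 1 − sech²(2s/L).  L → 0 recovers the
    identity.  Used to give the s double well a flat saddle plateau.
    """
    if flat_len <= 0:
        return s, np.ones_like(s)
    half = flat_len / 2.0
    t = np.tanh(s / half)
    g = s - half * t
    dg = 1.0 - (1.0 - t * t)  # 1 − sech² = tanh²
    return g, dg


def _s_profile(spec: PotentialSpec, s: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Double well along the RC with optional flat top; value and derivative."""
    x1, x2 = spec.well_positions
    mid = 0.5 * (x1 + x2)
    a = 0.5 * abs(x2 - x1)
    u = s - mid
    g, dg = _flat_top_map(u, spec.ts_flatness)
    ga, _ = _flat_top_map(np.asarray(a, dtype=float), spec.ts_flatness)
    G = g / ga
    h = spec.barrier_height
    v = h * (G * G - 1.0) ** 2 + 0.5 * spec.asymmetry * (u / a)
    dv = 4.0 * h * G * (G * G - 1.0) * dg / ga + 0.5 * spec.asymmetry / a
    return v, dv


def _q_center(spec: PotentialSpec, s: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """s-dependent center of the q = d1 + d2 valley, and its derivative."""
    x1, x2 = spec.well_positions
    a = 0.5 * abs(x2 - x1)
    q_ts = spec.q_saddle_tight if spec.topology == "tight" else spec.q_saddle_loose
    w = a / 1.5
    e = np.exp(-((s / w) ** 2))
    q0 = spec.q_well - (spec.q_well - q_ts) * e
    dq0 = (spec.q_well - q_ts) * e * 2.0 * s / (w * w)
    return q0, dq0


def potential_functions(
    spec: PotentialSpec,
) -> Tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]:
    """Vectorized (energy, gradient) callables over arrays of shape (..., dim)."""
    dim = dimension(spec)

    if spec.family == "flat":

        def energy(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return np.zeros(x.shape[:-1])

        def gradient(x: np.ndarray) -> np.ndarray:
            return np.zeros_like(np.asarray(x, dtype=float))

    elif spec.family == "harmonic":
        c = np.atleast_1d(np.asarray(spec.center, dtype=float))
        k = spec.force_constant

        def energy(x: np.ndarray) -> np.ndarray:
            d = np.asarray(x, dtype=float) - c
            return 0.5 * k * np.sum(d * d, axis=-1)

        def gradient(x: np.ndarray) -> np.ndarray:
            return k * (np.asarray(x, dtype=float) - c)

    elif spec.family == "double_well_1d":

        def energy(x: np.ndarray) -> np.ndarray:
            s = np.asarray(x, dtype=float)[..., 0]
            v, _ = _s_profile(spec, s)
            return v

        def gradient(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            _, dv = _s_profile(spec, x[..., 0])
            return dv[..., None]

    else:  # pt_surface_2d

        def energy(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            s = x[..., 0] - x[..., 1]
            q = x[..., 0] + x[..., 1]
            vs, _ = _s_profile(spec, s)
            q0, _ = _q_center(spec, s)
            return vs + 0.5 * spec.valley_force_constant * (q - q0) ** 2

        def gradient(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            s = x[..., 0] - x[..., 1]
            q = x[..., 0] + x[..., 1]
            _, dvs = _s_profile(spec, s)
            q0, dq0 = _q_center(spec, s)
            kq = spec.valley_force_constant
            r = q - q0
            g1 = dvs + kq * r * (1.0 - dq0)
            g2 = -dvs + kq * r * (1.0 + dq0)
            return np.stack([g1, g2], axis=-1)

    _ = dim
    return energy, gradient


def evaluate_potential(spec: PotentialSpec, point) -> Tuple[float, np.ndarray]:
    """Energy and exact analytic gradient at one point.

    Raises ValueError for non-finite input or points outside the declared
    evaluation domain.
    """
    x = np.atleast_1d(np.asarray(point, dtype=float))
    if x.shape[-1] != dimension(spec):
        raise ValueError(
            f"point has {x.shape[-1]} coordinates, family {spec.family!r} "
            f"expects {dimension(spec)}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite evaluation point")
    if np.any(np.abs(x) > spec.domain_bound):
        raise ValueError(
            f"point {x} outside evaluation domain |x| <= {spec.domain_bound}"
        )
    energy, gradient = potential_functions(spec)
    return float(energy(x)), np.asarray(gradient(x), dtype=float)


def rc_direction(spec: PotentialSpec) -> np.ndarray:
    """Constant gradient of the reaction coordinate in configuration space."""
    if spec.family == "pt_surface_2d":
        return np.array([1.0, -1.0])
    return np.ones(dimension(spec))[:1] if dimension(spec) == 1 else np.eye(dimension(spec))[0]


def rc_value(spec: PotentialSpec, x: np.ndarray) -> np.ndarray:
    """Reaction coordinate of configurations with shape (..., dim).

    For pt_surface_2d this is ξ = d_leave − d_attack; for 1D families the
    coordinate itself; for multi-D harmonic/flat, the first coordinate.
    """
    x = np.asarray(x, dtype=float)
    if spec.family == "pt_surface_2d":
        return x[..., 0] - x[..., 1]
    return x[..., 0]


def rc_to_configuration(spec: PotentialSpec, rc: np.ndarray) -> np.ndarray:
    """Minimum-energy configuration at a given RC value (valley floor)."""
    rc = np.asarray(rc, dtype=float)
    if spec.family == "pt_surface_2d":
        q0, _ = _q_center(spec, rc)
        return np.stack([(q0 + rc) / 2.0, (q0 - rc) / 2.0], axis=-1)
    return rc[..., None]


def analytic_rc_profile(spec: PotentialSpec, rc_grid: np.ndarray) -> np.ndarray:
    """Exact potential of mean force along the RC, normalized to min 0.

    For 1D families this is V(ξ).  For pt_surface_2d the q-valley is
    Gaussian with an s-independent force constant, so integrating it out
    contributes only a constant and the PMF equals the s-profile.
    """
    rc_grid = np.asarray(rc_grid, dtype=float)
    if spec.family == "pt_surface_2d":
        v, _ = _s_profile(spec, rc_grid)
    else:
        energy, _ = potential_functions(spec)
        v = energy(rc_grid[..., None])
    return v - v.min()
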