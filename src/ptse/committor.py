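"""Commitment analysis and transition-state-ensemble extraction.

Configurations are selected on an RC grid from existing trajectories,
re-equilibrated under a stiff harmonic restraint at their grid anchor,
and shot: unrestrained trajectories with freshly randomized initial
conditions are run until absorption into the reactant (RC ≤ ξ_R) or
product (RC ≥ ξ_P) basin.  The committor p_B of a grid point is the
fraction of decided shots that reached products, with a Wilson score
interval; the TSE is the set of configurations whose committor lies in
a band around the p = 0.5 separatrix.

For overdamped 1D dynamics the committor has the closed form

    p(ξ) = ∫_{ξ_R}^{ξ} e^{V(y)/kT} dy / ∫_{ξ_R}^{ξ_P} e^{V(y)/kT} dy

implemented in :func:`committor_closed_form_1d` as the independent
oracle for the shooting machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import quad
from statsmodels.stats.proportion import proportion_confint

from .langevin import BatchPropagator, TrajectorySample
from .potentials import (
    PotentialSpec,
    dimension,
    potential_functions,
    rc_to_configuration,
    rc_value,
)

__all__ = [
    "BasinDefinition",
    "ShotRecord",
    "CommittorEstimate",
    "TSEnsemble",
    "SelectionError",
    "select_configurations",
    "equilibrate_restrained",
    "shoot",
    "committor_curve",
    "committor_closed_form_1d",
    "define_tse",
]


@dataclass(frozen=True)
class BasinDefinition:
    """Absorbing RC thresholds and the step budget of a shot."""

    xi_reactant: float
    xi_product: float
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if not self.xi_reactant < self.xi_product:
            raise ValueError("xi_reactant must be < xi_product")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be > 0")


@dataclass
class ShotRecord:
    config_id: int
    launch_rc: float
    seed: int
    outcome: str  # reactant | product | undecided
    steps_to_absorption: int
    grid_rc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outcome not in ("reactant", "product", "undecided"):
            raise ValueError(f"bad outcome {self.outcome!r}")


@dataclass
class CommittorEstimate:
    grid_rc: float
    n_shots: int
    n_product: int
    p_B: float
    ci_low: float
    ci_high: float
    n_undecided: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.p_B <= self.ci_high <= 1.0):
            raise ValueError("committor CI ordering violated")


@dataclass
class TSEnsemble:
    members: List  # configurations (arrays or frames)
    member_rc: np.ndarray
    band: Tuple[float, float]
    rc_range: Tuple[float, float]

    @property
    def width(self) -> float:
        return self.rc_range[1] - self.rc_range[0]


@dataclass
class SelectedConfiguration:
    config_id: int
    grid_rc: float
    coordinates: np.ndarray
    launch_rc: float


class SelectionError(RuntimeError):
    pass


def select_configurations(
    trajectories: Sequence[TrajectorySample],
    grid: Sequence[float],
    per_point: int,
    window_delta: float,
    seed: int,
) -> List[SelectedConfiguration]:
    """Draw ``per_point`` stored configurations near each grid RC value.

    Candidates are all trajectory points with |ξ − grid point| ≤
    window_delta, drawn uniformly without replacement with a fixed seed.
    The reference protocol uses a 0.1 Å grid over the TS region with 20
    structures per point.
    """
    if per_point < 1:
        raise ValueError("per_point must be >= 1")
    coords = np.concatenate([t.coordinates for t in trajectories], axis=0)
    rcs = np.concatenate([t.rc_values for t in trajectories])
    rng = np.random.default_rng(int(seed))
    out: List[SelectedConfiguration] = []
    cid = 0
    for g in np.asarray(grid, dtype=float):
        cand = np.flatnonzero(np.abs(rcs - g) <= window_delta)
        if len(cand) < per_point:
            raise SelectionError(
                f"only {len(cand)} candidates within ±{window_delta} of grid point {g}"
            )
        pick = rng.choice(cand, size=per_point, replace=False)
        for i in pick:
            out.append(
                SelectedConfiguration(
                    config_id=cid,
                    grid_rc=float(g),
                    coordinates=coords[i].copy(),
                    launch_rc=float(rcs[i]),
                )
            )
            cid += 1
    return out


def equilibrate_restrained(
    spec: PotentialSpec,
    config: np.ndarray,
    anchor_rc: float,
    force_constant: float = 300.0,
    time: float = 5.0,
    seed: int = 0,
    dt: float = 5e-4,
    friction: float = 1.0,
    scheme: str = "overdamped",
) -> np.ndarray:
    """Relax a configuration under a static RC restraint; returns the
    final configuration (5 ps at k = 300 in the reference protocol)."""
    prop = BatchPropagator(spec, dt, friction, spec.temperature, [seed], scheme=scheme)
    x = np.atleast_1d(np.asarray(config, dtype=float))[None, :]
    n_steps = int(round(time / dt))
    x, _ = prop.equilibrate(x, n_steps, force_constant, float(anchor_rc))
    return x[0]


def _shoot_batch(
    spec: PotentialSpec,
    x0: np.ndarray,
    basin: BasinDefinition,
    temperature: float,
    seeds: Sequence[int],
    dt: float,
    friction: float,
    scheme: str,
) -> Tuple[np.ndarray, np.ndarray]:
    """Propagate a batch unrestrained until absorption.

    Returns (outcome codes: −1 reactant / +1 product / 0 undecided,
    steps to absorption)."""
    prop = BatchPropagator(spec, dt, friction, temperature, seeds, scheme=scheme)
    x = x0.copy()
    v = prop.draw_maxwell_boltzmann() if scheme == "baoab" else None
    n = x.shape[0]
    outcome = np.zeros(n, dtype=int)
    steps = np.full(n, basin.max_steps, dtype=int)
    active = np.ones(n, dtype=bool)
    for i in range(basin.max_steps):
        x_new, v = prop.step(x, v, None, None)
        # absorbed walkers stay frozen (their noise stream still advances,
        # keeping results independent of absorption order)
        x = np.where(active[:, None], x_new, x)
        xi = rc_value(spec, x)
        hit_r = active & (xi <= basin.xi_reactant)
        hit_p = active & (xi >= basin.xi_product)
        if hit_r.any() or hit_p.any():
            outcome[hit_r] = -1
            outcome[hit_p] = 1
            steps[hit_r | hit_p] = i + 1
            active &= ~(hit_r | hit_p)
            if not active.any():
                break
    return outcome, steps


def shoot(
    spec: PotentialSpec,
    config: np.ndarray,
    basin: BasinDefinition,
    n_shots: int,
    temperature: float,
    seeds: Sequence[int],
    dt: float = 1e-3,
    friction: float = 1.0,
    scheme: str = "overdamped",
    config_id: int = 0,
    grid_rc: Optional[float] = None,
) -> List[ShotRecord]:
    """Fire ``n_shots`` unrestrained trajectories from one configuration.

    Each shot draws fresh initial conditions from its own seed
    (Maxwell–Boltzmann velocities in the inertial scheme, an independent
    noise stream in the overdamped one) and runs until it is absorbed in
    a basin or the step budget runs out.  The reference protocol fires
    10 shots per configuration.
    """
    x0 = np.atleast_1d(np.asarray(config, dtype=float))
    launch_rc = float(rc_value(spec, x0[None, :])[0])
    if not (basin.xi_reactant < launch_rc < basin.xi_product):
        raise ValueError(
            f"launch RC {launch_rc:.4g} is not strictly between the basin "
            f"thresholds ({basin.xi_reactant}, {basin.xi_product})"
        )
    seeds = [int(s) for s in seeds]
    if len(seeds) != n_shots:
        raise ValueError("need one seed per shot")
    x_batch = np.broadcast_to(x0, (n_shots, len(x0))).copy()
    codes, steps = _shoot_batch(
        spec, x_batch, basin, temperature, seeds, dt, friction, scheme
    )
    records = [
        ShotRecord(
            config_id=config_id,
            launch_rc=launch_rc,
            seed=seeds[i],
            outcome={-1: "reactant", 1: "product", 0: "undecided"}[int(codes[i])],
            steps_to_absorption=int(steps[i]),
            grid_rc=grid_rc,
        )
        for i in range(n_shots)
    ]
    if all(r.outcome == "undecided" for r in records):
        warnings.warn(f"all {n_shots} shots undecided for config {config_id}")
    return records


def committor_curve(
    records: Sequence[ShotRecord],
    confidence: float = 0.95,
) -> List[CommittorEstimate]:
    """Per-grid-point committor estimates with Wilson score intervals.

    Shots are grouped by their ``grid_rc`` (falling back to launch RC);
    undecided shots are excluded from the denominator and reported via
    ``n_undecided``.  Groups with no decided shot are omitted with a
    warning.
    """
    groups: Dict[float, List[ShotRecord]] = {}
    for r in records:
        key = r.grid_rc if r.grid_rc is not None else r.launch_rc
        groups.setdefault(float(key), []).append(r)
    out: List[CommittorEstimate] = []
    for key in sorted(groups):
        recs = groups[key]
        decided = [r for r in recs if r.outcome != "undecided"]
        n_undecided = len(recs) - len(decided)
        if not decided:
            warnings.warn(f"grid point {key}: no decided shots, estimate omitted")
            continue
        n_prod = sum(r.outcome == "product" for r in decided)
        lo, hi = proportion_confint(
            n_prod, len(decided), alpha=1 - confidence, method="wilson"
        )
        out.append(
            CommittorEstimate(
                grid_rc=key,
                n_shots=len(decided),
                n_product=n_prod,
                p_B=n_prod / len(decided),
                ci_low=float(lo),
                ci_high=float(hi),
                n_undecided=n_undecided,
            )
        )
    return out


def committor_closed_form_1d(
    spec: PotentialSpec,
    temperature: float,
    xi_reactant: float,
    xi_product: float,
) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form overdamped committor on a 1D potential.

    Returns a vectorized p(ξ) evaluated by adaptive quadrature of
    exp(V/kT) between the absorbing boundaries; p is 0 at ξ_R, 1 at
    ξ_P and monotone non-decreasing.
    """
    if dimension(spec) != 1:
        raise ValueError("closed-form committor requires a 1D potential")
    from .constants import thermal_energy

    kT = thermal_energy(temperature, spec.units_mode)
    energy, _ = potential_functions(spec)

    # shift by the max on a scan grid so the integrand cannot overflow
    scan = np.linspace(xi_reactant, xi_product, 2001)
    vmax = float(energy(scan[:, None]).max())

    def integrand(y: float) -> float:
        return float(np.exp((energy(np.array([[y]]))[0] - vmax) / kT))

    denom, err = quad(integrand, xi_reactant, xi_product, limit=200)
    if not np.isfinite(denom) or denom <= 0:
        raise ArithmeticError("committor quadrature failed on the denominator")

    def p(xi) -> np.ndarray:
        xi_arr = np.atleast_1d(np.asarray(xi, dtype=float))
        vals = np.empty_like(xi_arr)
        for i, z in enumerate(xi_arr):
            z = min(max(z, xi_reactant), xi_product)
            num, _ = quad(integrand, xi_reactant, z, limit=200)
            vals[i] = num / denom
        vals = np.clip(vals, 0.0, 1.0)
        return vals if np.ndim(xi) else float(vals[0])

    return p


def grid_committor_study(
    spec: PotentialSpec,
    grid: Sequence[float],
    per_point: int,
    n_shots: int,
    basin: BasinDefinition,
    temperature: float,
    seed: int,
    restraint_force_constant: float = 300.0,
    equil_time: float = 5.0,
    dt: float = 1e-3,
    friction: float = 1.0,
    scheme: str = "overdamped",
) -> Tuple[List[SelectedConfiguration], List[ShotRecord]]:
    """Full commitment analysis over an RC grid, batched for speed.

    For every grid point, ``per_point`` configurations are produced by
    restrained equilibration at the anchor (the reference protocol uses
    20 configurations per point, 5 ps at k = 300), then ``n_shots``
    unrestrained shots are fired from each.  All walkers propagate in a
    single batch; results are reproducible from the one seed.
    """
    grid = np.asarray(grid, dtype=float)
    ss = np.random.SeedSequence(int(seed))
    child_eq, child_shot = ss.spawn(2)
    n_cfg = len(grid) * per_point
    eq_seeds = (child_eq.generate_state(n_cfg, dtype=np.uint64) % (2**31)).astype(int)
    shot_seeds = (
        child_shot.generate_state(n_cfg * n_shots, dtype=np.uint64) % (2**31)
    ).astype(int)

    anchors = np.repeat(grid, per_point)
    prop = BatchPropagator(
        spec, dt, friction, temperature, eq_seeds.tolist(), scheme=scheme
    )
    x0 = rc_to_configuration(spec, anchors).reshape(n_cfg, prop.dim).copy()
    x_eq, _ = prop.equilibrate(
        x0, int(round(equil_time / dt)), restraint_force_constant, anchors
    )
    launch_rc = rc_value(spec, x_eq)

    configs = [
        SelectedConfiguration(
            config_id=i,
            grid_rc=float(anchors[i]),
            coordinates=x_eq[i].copy(),
            launch_rc=float(launch_rc[i]),
        )
        for i in range(n_cfg)
    ]
    x_shots = np.repeat(x_eq, n_shots, axis=0)
    codes, steps = _shoot_batch(
        spec, x_shots, basin, temperature, shot_seeds.tolist(), dt, friction, scheme
    )
    records = []
    for j in range(n_cfg * n_shots):
        i = j // n_shots
        records.append(
            ShotRecord(
                config_id=i,
                launch_rc=float(launch_rc[i]),
                seed=int(shot_seeds[j]),
                outcome={-1: "reactant", 1: "product", 0: "undecided"}[int(codes[j])],
                steps_to_absorption=int(steps[j]),
                grid_rc=float(anchors[i]),
            )
        )
    return configs, records


def define_tse(
    estimates: Sequence[CommittorEstimate],
    configurations: Sequence[SelectedConfiguration],
    band: Tuple[float, float] = (0.4, 0.6),
) -> TSEnsemble:
    """Configurations whose grid-point committor lies in the TS band.

    The default band [0.4, 0.6] is symmetric about the p = 0.5
    separatrix.  ξ(TS) is reported as the min–max launch RC of the
    members; an empty ensemble is returned with zero width and a
    warning.
    """
    p_lo, p_hi = band
    if not (0.0 < p_lo < p_hi < 1.0):
        raise ValueError("band must satisfy 0 < p_lo < p_hi < 1")
    in_band = {e.grid_rc for e in estimates if p_lo <= e.p_B <= p_hi}
    members = [c for c in configurations if float(c.grid_rc) in in_band]
    if not members:
        warnings.warn("empty transition-state ensemble for the requested band")
        return TSEnsemble(
            members=[], member_rc=np.array([]), band=(p_lo, p_hi), rc_range=(0.0, 0.0)
        )
    rcs = np.array([c.launch_rc for c in members])
    return TSEnsemble(
        members=members,
        member_rc=rcs,
        band=(p_lo, p_hi),
        rc_range=(float(rcs.min()), float(rcs.max())),
    )
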