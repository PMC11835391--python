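"""Umbrella-window scheduling and sampling on the surrogate engine.

A ladder of static harmonic restraints along the reaction coordinate
(0.1 Å spacing and k = 300 kcal/mol/Å² in the reference configuration)
is sampled in one batch: every window is an independent walker with its
own restraint center.  Equilibration is discarded strictly by time;
production RC values are recorded at a fixed sampling interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .langevin import BatchPropagator
from .potentials import PotentialSpec, rc_to_configuration, rc_value

__all__ = ["UmbrellaWindow", "run_umbrella", "overlap_diagnostic"]


@dataclass
class UmbrellaWindow:
    """Production RC samples of one restrained window."""

    center: float
    force_constant: float
    rc_samples: np.ndarray
    equil_time: float
    prod_time: float
    sample_interval: float
    seed: int
    temperature: float = 1.0
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rc_samples = np.asarray(self.rc_samples, dtype=float)
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0")
        if len(self.rc_samples) < 1:
            raise ValueError("window must contain at least one sample")
        if not np.all(np.isfinite(self.rc_samples)):
            raise ValueError("non-finite RC samples")


def run_umbrella(
    spec: PotentialSpec,
    centers: Sequence[float],
    force_constant: float = 300.0,
    equil_time: float = 60.0,
    prod_time: float = 40.0,
    sample_interval: float = 1e-3,
    seeds: Optional[Sequence[int]] = None,
    dt: float = 2.5e-4,
    friction: float = 1.0,
    scheme: str = "overdamped",
    initial_trajectory: Optional[np.ndarray] = None,
) -> List[UmbrellaWindow]:
    """Sample every window of the ladder; one walker per center.

    Times share the unit of ``dt`` (ps in physical mode).  Initial
    configurations are the valley floor at each center, or the nearest
    point of ``initial_trajectory`` (an array of configurations) when
    supplied.  A window whose production mean deviates from the
    restrained-harmonic prediction by more than 3 SD is flagged.
    """
    centers = np.asarray(centers, dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be sorted and strictly increasing")
    n_win = len(centers)
    if seeds is None:
        seeds = list(range(n_win))
    seeds = [int(s) for s in seeds]
    if len(seeds) != n_win:
        raise ValueError("need one seed per window")

    temperature = spec.temperature
    prop = BatchPropagator(spec, dt, friction, temperature, seeds, scheme=scheme)
    if initial_trajectory is not None:
        traj = np.asarray(initial_trajectory, dtype=float)
        traj_rc = rc_value(spec, traj)
        x0 = traj[np.argmin(np.abs(traj_rc[None, :] - centers[:, None]), axis=1)]
    else:
        x0 = rc_to_configuration(spec, centers)
    x0 = x0.reshape(n_win, prop.dim).copy()

    equil_steps = int(round(equil_time / dt))
    stride = max(1, int(round(sample_interval / dt)))
    prod_steps = int(round(prod_time / dt))
    n_samp = prod_steps // stride

    x, v = prop.equilibrate(x0, equil_steps, force_constant, centers)
    samples = np.empty((n_win, n_samp))
    j = 0
    for i in range(prod_steps):
        x, v = prop.step(x, v, force_constant, centers)
        if (i + 1) % stride == 0:
            samples[:, j] = rc_value(spec, x)
            j += 1
        if i % 1024 == 0:
            prop.check_domain(x, i)
    samples = samples[:, :j]

    kT = prop.kT
    windows = []
    for w in range(n_win):
        flags: List[str] = []
        if temperature > 0 and len(samples[w]) > 1:
            # restrained-harmonic diagnostic: mean within 3 SD of center
            sd = np.sqrt(kT / force_constant)
            if abs(samples[w].mean() - centers[w]) > 3.0 * sd:
                flags.append("off-center")
                warnings.warn(
                    f"window at {centers[w]:.3g} never equilibrated near its center"
                )
        windows.append(
            UmbrellaWindow(
                center=float(centers[w]),
                force_constant=force_constant,
                rc_samples=samples[w],
                equil_time=equil_time,
                prod_time=prod_time,
                sample_interval=sample_interval,
                seed=seeds[w],
                temperature=temperature,
                flags=flags,
            )
        )
    return windows


def overlap_diagnostic(
    windows: Sequence[UmbrellaWindow], bin_width: float = 0.02
) -> np.ndarray:
    """Shared histogram mass of each adjacent window pair, in [0, 1].

    Histograms are built on one common grid; the overlap of a pair is
    Σ_b min(p_i(b), p_j(b)) — 1 for identical sample sets, 0 for
    disjoint ones.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    lo = min(w.rc_samples.min() for w in windows)
    hi = max(w.rc_samples.max() for w in windows)
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    hists = [
        np.histogram(w.rc_samples, bins=edges)[0] / len(w.rc_samples)
        for w in windows
    ]
    return np.array(
        [np.minimum(hists[i], hists[i + 1]).sum() for i in range(len(windows) - 1)]
    )
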