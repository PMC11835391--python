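"""Weighted histogram analysis method, from scratch.

Self-consistent unbiasing of overlapping restrained-window histograms:

    P(b) = M(b) / Σ_i N_i exp(−[c_i(b) − f_i]/kT)
    exp(−f_i/kT) = Σ_b exp(−c_i(b)/kT) P(b)

with c_i the bias energy of window i evaluated at the bin center and M
the pooled bin counts.  Direct fixed-point iteration is used until the
largest change in any window free energy f_i falls below the tolerance.
The solution is gauge invariant: adding one constant to all biases
shifts all f_i but leaves the profile unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import thermal_energy
from .fep import FreeEnergyProfile
from .umbrella import UmbrellaWindow

__all__ = ["WhamSolution", "WhamError", "wham_solve"]


class WhamError(RuntimeError):
    pass


@dataclass
class WhamSolution:
    profile: FreeEnergyProfile
    window_free_energies: np.ndarray
    iterations: int
    converged: bool
    bin_edges: np.ndarray
    objective: Optional[np.ndarray] = None  # per-iteration NLL when tracked


def _check_adjacent_overlap(counts: np.ndarray, centers_order: np.ndarray) -> None:
    for a, b in zip(centers_order[:-1], centers_order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            raise WhamError(
                f"no histogram overlap between adjacent windows {a} and {b}"
            )


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    temperature: float,
    bin_width: float = 0.02,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    units_mode: str = "reduced",
    bias_offsets: Optional[Sequence[float]] = None,
    track_objective: bool = False,
) -> WhamSolution:
    """Reconstruct the free-energy profile from umbrella windows.

    ``tolerance`` is the convergence threshold on max |Δf_i| in energy
    units; non-convergence returns the last iterate with
    ``converged=False``.  ``bias_offsets`` adds a per-window constant to
    the bias energy (used to verify gauge invariance).
    """
    if len(windows) == 0:
        raise ValueError("no windows given")
    kT = thermal_energy(temperature, units_mode)
    if kT <= 0:
        raise ValueError("WHAM requires a positive temperature")
    beta = 1.0 / kT

    all_samples = np.concatenate([w.rc_samples for w in windows])
    lo, hi = all_samples.min(), all_samples.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi + 1e-12)  # ensure coverage of the max sample
    mids = 0.5 * (edges[:-1] + edges[1:])

    n_win = len(windows)
    counts = np.array(
        [np.histogram(w.rc_samples, bins=edges)[0] for w in windows], dtype=float
    )
    order = np.argsort([w.center for w in windows])
    _check_adjacent_overlap(counts, order)

    N = counts.sum(axis=1)
    M = counts.sum(axis=0)
    bias = np.array(
        [0.5 * w.force_constant * (mids - w.center) ** 2 for w in windows]
    )
    if bias_offsets is not None:
        bias = bias + np.asarray(bias_offsets, dtype=float)[:, None]

    log_c = -beta * bias  # (n_win, n_bins)
    log_N = np.log(N)
    log_M = np.where(M > 0, np.log(np.maximum(M, 1)), -np.inf)

    f = np.zeros(n_win)
    objective: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        # log denominator per bin: logsumexp_i [log N_i + beta f_i + log c_i(b)]
        log_den = logsumexp(log_N[:, None] + beta * f[:, None] + log_c, axis=0)
        log_P = log_M - log_den
        if track_objective:
            # negative log-likelihood at the current window free energies
            keep = M > 0
            objective.append(float(-(M[keep] * log_P[keep]).sum() - (N * beta * f).sum()))
        # window normalization: exp(-beta f_i) = sum_b c_i(b) P(b)
        f_new = -kT * logsumexp(log_c + log_P[None, :], axis=1)
        f_new = f_new - f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            converged = True
            break

    keep = M > 0
    G = -kT * log_P[keep]
    stderr = kT / np.sqrt(np.maximum(M[keep], 1.0))
    profile = FreeEnergyProfile(
        rc_grid=mids[keep],
        G=G,
        stderr=stderr,
        estimator="wham",
        n_replicates=n_win,
        temperature=temperature,
        units_mode=units_mode,
        info={"bin_width": bin_width, "iterations": it, "converged": converged},
    )
    return WhamSolution(
        profile=profile,
        window_free_energies=f,
        iterations=it,
        converged=converged,
        bin_edges=edges,
        objective=np.asarray(objective) if track_objective else None,
    )
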