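"""Toy 3D phosphoryl-transfer frames parameterized by the RC.

The generator builds an idealized in-line transfer geometry: leaving
and attacking oxygens fixed on the x axis at the requested
donor–acceptor distance, the transferring phosphorus between them at
the position that realizes the requested ξ exactly, and three
non-bridging oxygens arranged with threefold symmetry around the axis.
Their polar tilt is solved numerically so the improper dihedral ζ
equals 180° minus the requested pyramidalization exactly (before
jitter).  Optional per-atom isotropic Gaussian jitter creates dispersed
pseudo-TSEs for the ensemble-width statistic; an optional Mg ion is
placed at a fixed position relative to the donor–acceptor axis so that
it can serve as a non-collinear alignment anchor.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
from scipy.optimize import brentq

from .geometry import MolecularFrame, improper_dihedral

__all__ = ["GeometryError", "make_pt_frames"]


class GeometryError(ValueError):
    pass


def _nb_ring(theta: float, bond: float) -> np.ndarray:
    """Three non-bridging oxygen offsets at polar angle theta from +x."""
    phis = np.deg2rad([90.0, 210.0, 330.0])
    return bond * np.stack(
        [
            np.full(3, np.cos(theta)),
            np.sin(theta) * np.cos(phis),
            np.sin(theta) * np.sin(phis),
        ],
        axis=1,
    )


def _build_frame(
    xi: float,
    d_da: float,
    theta: float,
    include_mg: bool,
    nb_bond: float,
) -> MolecularFrame:
    d_leave = 0.5 * (d_da + xi)
    p = np.array([d_leave, 0.0, 0.0])
    coords = [
        np.zeros(3),  # O_leaving
        np.array([d_da, 0.0, 0.0]),  # O_attacking
        p,  # P_T
    ]
    labels = ["O", "O", "P"]
    roles = {"O_leaving": 0, "O_attacking": 1, "P_T": 2}
    ring = p + _nb_ring(theta, nb_bond)
    for i in range(3):
        coords.append(ring[i])
        labels.append("O")
        roles[f"O_nb{i + 1}"] = 3 + i
    if include_mg:
        coords.append(np.array([0.62 * d_da, 2.1, 0.0]))
        labels.append("Mg")
        roles["Mg"] = len(coords) - 1
    return MolecularFrame(labels, np.array(coords), roles)


def _solve_theta(target_zeta: float, nb_bond: float) -> float:
    """Polar tilt of the non-bridging ring giving the requested ζ."""

    def f(theta: float) -> float:
        fr = _build_frame(0.0, 4.5, theta, False, nb_bond)
        z = improper_dihedral(fr)
        if z > 300.0:  # unwrap across the 0/360 seam
            z -= 360.0
        return z - target_zeta

    return brentq(f, np.deg2rad(40.0), np.deg2rad(140.0), xtol=1e-13)


def make_pt_frames(
    xi_values: Sequence[float],
    donor_acceptor_distance: float = 4.5,
    pyramidalization: float = 0.0,
    include_mg: bool = False,
    jitter_sd: float = 0.0,
    seed: int = 0,
    nb_bond_length: float = 1.6,
    min_bond_length: float = 0.8,
) -> List[MolecularFrame]:
    """One idealized frame per ξ value (Å), jittered if requested.

    Before jitter every frame satisfies
    d(O_leaving−P) − d(O_attacking−P) = ξ and
    d(O_leaving···O_attacking) = donor_acceptor_distance exactly, and
    the PO₃ improper dihedral equals 180° − pyramidalization (degrees).
    The default donor–acceptor distance of 4.5 Å matches the compressed
    active-site geometry at which the transfer becomes feasible.
    """
    xi_values = np.asarray(xi_values, dtype=float)
    d_da = float(donor_acceptor_distance)
    for xi in xi_values:
        d1 = 0.5 * (d_da + xi)
        d2 = 0.5 * (d_da - xi)
        if d1 < min_bond_length or d2 < min_bond_length:
            raise GeometryError(
                f"infeasible geometry: xi={xi} with donor-acceptor {d_da} "
                f"leaves a P–O distance below {min_bond_length} Å"
            )
    theta = _solve_theta(180.0 - float(pyramidalization), nb_bond_length)
    rng = np.random.default_rng(int(seed))
    frames = []
    for xi in xi_values:
        fr = _build_frame(float(xi), d_da, theta, include_mg, nb_bond_length)
        if jitter_sd > 0:
            fr = fr.with_coordinates(
                fr.coordinates + rng.normal(0.0, jitter_sd, fr.coordinates.shape)
            )
        frames.append(fr)
    return frames
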