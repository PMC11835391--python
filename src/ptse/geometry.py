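"""Geometric characterization of phosphoryl-transfer frames and TSEs.

A :class:`MolecularFrame` carries role-labeled Cartesian coordinates;
the minimum role set is the transferring phosphorus ``P_T``, the
leaving and attacking oxygens, and the three non-bridging oxygens
``O_nb1..3``.  Derived quantities:

* reaction coordinate ξ = d(O_leaving−P_T) − d(O_attacking−P_T),
  negative at reactants and positive at products;
* donor–acceptor distance d(O_leaving···O_attacking), the active-site
  compression measure;
* improper dihedral ζ over (O_nb1, O_nb2, O_nb3, P_T), anchored so a
  trigonal-planar PO₃ gives exactly 180° and reported in [0°, 360°);
* Pauling bond orders n = exp((r0 − d)/b) of the breaking and forming
  P–O bonds, and the tight/loose/synchronous classification of the
  Moore-O'Ferrall–Jencks diagram by total bond order;
* Kabsch superposition, the P-atom ensemble-width statistic, and PCA
  over a selected atom subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "MolecularFrame",
    "GeometryReport",
    "PCAResult",
    "RoleError",
    "REQUIRED_ROLES",
    "reaction_coordinate",
    "donor_acceptor_distance",
    "improper_dihedral",
    "mofj_classify",
    "geometry_report",
    "kabsch_superpose",
    "tse_width",
    "pca_tse",
]

REQUIRED_ROLES = ("P_T", "O_leaving", "O_attacking", "O_nb1", "O_nb2", "O_nb3")
OPTIONAL_ROLES = ("Mg", "P_alpha", "O3_alpha", "P_beta", "O3_beta")


class RoleError(KeyError):
    pass


@dataclass
class MolecularFrame:
    """Role-labeled 3D coordinates (Å)."""

    labels: List[str]
    coordinates: np.ndarray  # (n_atoms, 3)
    roles: Dict[str, int]  # role name -> atom index

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if len(self.labels) != len(self.coordinates):
            raise ValueError("labels and coordinates length mismatch")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        idx = list(self.roles.values())
        if len(set(idx)) != len(idx):
            raise ValueError("role indices must be unique")
        if any(not 0 <= i < len(self.coordinates) for i in idx):
            raise ValueError("role index out of range")
        if len(self.coordinates) > 1 and pdist(self.coordinates).min() <= 0.1:
            raise ValueError("atoms closer than 0.1 Å")

    def position(self, role: str) -> np.ndarray:
        try:
            return self.coordinates[self.roles[role]]
        except KeyError:
            raise RoleError(f"frame is missing required role {role!r}") from None

    def with_coordinates(self, coords: np.ndarray) -> "MolecularFrame":
        return MolecularFrame(list(self.labels), np.asarray(coords, dtype=float), dict(self.roles))


@dataclass
class GeometryReport:
    d_attack: float
    d_leave: float
    xi: float
    d_donor_acceptor: float
    zeta: float
    bond_order_attack: float
    bond_order_leave: float
    mofj_class: str

    def __post_init__(self) -> None:
        if abs(self.xi - (self.d_leave - self.d_attack)) > 1e-12:
            raise ValueError("xi must equal d_leave - d_attack")
        if self.d_donor_acceptor > self.d_attack + self.d_leave + 1e-9:
            raise ValueError("donor-acceptor distance violates triangle inequality")
        if not 0.0 <= self.zeta < 360.0:
            raise ValueError("zeta must lie in [0, 360)")


@dataclass
class PCAResult:
    components: np.ndarray  # (n_components, 3m) orthonormal rows
    eigenvalues: np.ndarray  # descending, >= 0
    projections: np.ndarray  # (n_frames, n_components)
    rank: int
    mean: np.ndarray


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def reaction_coordinate(frame: MolecularFrame) -> float:
    """ξ = d(O_leaving−P_T) − d(O_attacking−P_T)."""
    p = frame.position("P_T")
    return _dist(frame.position("O_leaving"), p) - _dist(frame.position("O_attacking"), p)


def donor_acceptor_distance(frame: MolecularFrame) -> float:
    """Euclidean distance between the leaving and attacking oxygens."""
    return _dist(frame.position("O_leaving"), frame.position("O_attacking"))


def improper_dihedral(frame: MolecularFrame) -> float:
    """Improper dihedral ζ over (O_nb1, O_nb2, O_nb3, P_T) in degrees.

    Conventional 4-atom torsion with the branch shifted so that a
    trigonal-planar PO₃ group returns exactly 180°; values in [0°, 360°).
    Raises for a collinear non-bridging-oxygen triple.
    """
    a = frame.position("O_nb1")
    b = frame.position("O_nb2")
    c = frame.position("O_nb3")
    d = frame.position("P_T")
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 * np.linalg.norm(b1) * np.linalg.norm(b2):
        raise ValueError("collinear non-bridging oxygens: dihedral undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    phi = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    return float((phi + 180.0) % 360.0)


def mofj_classify(
    frame: MolecularFrame,
    reference_bond_length: float = 1.7,
    pauling_b: float = 0.6,
    tau: float = 0.1,
) -> Tuple[Tuple[float, float], str]:
    """Pauling bond orders of the two P–O bonds and the MOFJ class.

    n = exp((r0 − d)/b) per bond; total order above 1 + τ is ``tight``,
    below 1 − τ ``loose``, otherwise ``synchronous``.
    """
    if reference_bond_length <= 0 or pauling_b <= 0:
        raise ValueError("reference_bond_length and pauling_b must be > 0")
    p = frame.position("P_T")
    d_att = _dist(frame.position("O_attacking"), p)
    d_lv = _dist(frame.position("O_leaving"), p)
    n_att = float(np.exp((reference_bond_length - d_att) / pauling_b))
    n_lv = float(np.exp((reference_bond_length - d_lv) / pauling_b))
    total = n_att + n_lv
    if total > 1.0 + tau:
        cls = "tight"
    elif total < 1.0 - tau:
        cls = "loose"
    else:
        cls = "synchronous"
    return (n_att, n_lv), cls


def geometry_report(
    frame: MolecularFrame,
    reference_bond_length: float = 1.7,
    pauling_b: float = 0.6,
    tau: float = 0.1,
) -> GeometryReport:
    """All scalar geometric descriptors of one frame."""
    p = frame.position("P_T")
    d_att = _dist(frame.position("O_attacking"), p)
    d_lv = _dist(frame.position("O_leaving"), p)
    (n_att, n_lv), cls = mofj_classify(frame, reference_bond_length, pauling_b, tau)
    return GeometryReport(
        d_attack=d_att,
        d_leave=d_lv,
        xi=d_lv - d_att,
        d_donor_acceptor=donor_acceptor_distance(frame),
        zeta=improper_dihedral(frame),
        bond_order_attack=n_att,
        bond_order_leave=n_lv,
        mofj_class=cls,
    )


def _role_indices(frame: MolecularFrame, roles: Sequence[str]) -> List[int]:
    out = []
    for r in roles:
        if r not in frame.roles:
            raise RoleError(f"frame is missing required role {r!r}")
        out.append(frame.roles[r])
    return out


def kabsch_superpose(
    frames: Sequence[MolecularFrame],
    align_roles: Optional[Sequence[str]] = None,
    reference: Optional[MolecularFrame] = None,
) -> Tuple[List[MolecularFrame], np.ndarray]:
    """Least-squares superposition of each frame onto a reference.

    The optimal proper rotation (det = +1) and translation are computed
    over the alignment-role atoms (all roles by default; the first frame
    is the default reference) and applied to the whole frame.  Returns
    the aligned frames and the per-frame RMSD over alignment atoms.
    """
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    ref = reference if reference is not None else frames[0]
    roles = list(align_roles) if align_roles is not None else sorted(ref.roles)
    ref_idx = _role_indices(ref, roles)
    Q = ref.coordinates[ref_idx]
    if len(Q) < 3:
        raise ValueError("need at least 3 alignment atoms")
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Qc, tol=1e-9) < 2:
        raise ValueError("alignment atoms are collinear")

    aligned: List[MolecularFrame] = []
    rmsd = np.empty(len(frames))
    for i, fr in enumerate(frames):
        idx = _role_indices(fr, roles)
        P = fr.coordinates[idx]
        Pm, Qm = P.mean(axis=0), Q.mean(axis=0)
        H = (P - Pm).T @ (Q - Qm)
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        new_coords = (fr.coordinates - Pm) @ R.T + Qm
        aligned.append(fr.with_coordinates(new_coords))
        rmsd[i] = float(
            np.sqrt(np.mean(np.sum((new_coords[idx] - Q) ** 2, axis=1)))
        )
    return aligned, rmsd


def tse_width(
    aligned_frames: Sequence[MolecularFrame], atom_role: str = "P_T"
) -> Tuple[float, float]:
    """Ensemble width: mean ± SD of the distances of one atom from its
    average position across aligned frames."""
    if len(aligned_frames) < 2:
        raise ValueError("need at least two frames")
    pos = np.array([f.position(atom_role) for f in aligned_frames])
    center = pos.mean(axis=0)
    d = np.linalg.norm(pos - center, axis=1)
    return float(d.mean()), float(d.std(ddof=0))


def pca_tse(
    aligned_frames: Sequence[MolecularFrame],
    pca_roles: Sequence[str],
) -> PCAResult:
    """PCA of the flattened coordinates of a role subset across frames.

    Components are orthonormal rows with non-negative, descending
    eigenvalues summing to the total coordinate variance; rank-deficient
    ensembles report a reduced component count.
    """
    if len(aligned_frames) < 3:
        raise ValueError("need at least 3 frames for PCA")
    X = np.array(
        [f.coordinates[_role_indices(f, pca_roles)].ravel() for f in aligned_frames]
    )
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (len(X) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    tol = max(vals.max(), 1e-30) * 1e-12
    rank = int(np.sum(vals > tol))
    return PCAResult(
        components=vecs.T,
        eigenvalues=vals,
        projections=Xc @ vecs,
        rank=rank,
        mean=mean,
    )
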