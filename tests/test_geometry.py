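import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ptse import (
    MolecularFrame,
    donor_acceptor_distance,
    improper_dihedral,
    kabsch_superpose,
    make_pt_frames,
    mofj_classify,
    pca_tse,
    reaction_coordinate,
    tse_width,
)
from ptse.geometry import RoleError, geometry_report


def _frame(coords, roles=None):
    coords = np.asarray(coords, dtype=float)
    labels = ["X"] * len(coords)
    if roles is None:
        roles = {r: i for i, r in enumerate(
            ["O_leaving", "O_attacking", "P_T", "O_nb1", "O_nb2", "O_nb3"])}
    return MolecularFrame(labels, coords, roles)


def _pt_frame(d_leave=1.7, d_attack=3.3):
    """Collinear transfer frame with explicit P–O distances."""
    base = make_pt_frames([0.0], donor_acceptor_distance=d_leave + d_attack)[0]
    coords = base.coordinates.copy()
    shift = d_leave - 0.5 * (d_leave + d_attack)
    coords[base.roles["P_T"]][0] += shift
    for i in range(1, 4):
        coords[base.roles[f"O_nb{i}"]][0] += shift
    return base.with_coordinates(coords)


def test_reaction_coordinate_arithmetic():
    fr = _pt_frame(1.7, 3.3)
    assert reaction_coordinate(fr) == pytest.approx(1.7 - 3.3, abs=1e-12)


def test_donor_acceptor_collinear_and_pythagorean():
    fr = _pt_frame(1.7, 2.8)
    assert donor_acceptor_distance(fr) == pytest.approx(4.5, abs=1e-12)
    tri = _frame([[0, 0, 0], [3, 4, 0], [0, 4, 0],
                  [1, 1, 1], [1, 2, 1], [2, 1, 1]])
    assert donor_acceptor_distance(tri) == pytest.approx(5.0)


def test_missing_role_raises():
    fr = _pt_frame()
    roles = {k: v for k, v in fr.roles.items() if k != "O_nb3"}
    broken = MolecularFrame(fr.labels, fr.coordinates, roles)
    with pytest.raises(RoleError):
        improper_dihedral(broken)


def _brute_torsion(a, b, c, d):
    """Independent textbook torsion: signed angle between half-planes."""
    b1, b2, b3 = b - a, c - b, d - c
    b2u = b2 / np.linalg.norm(b2)
    v = b1 - np.dot(b1, b2u) * b2u
    w = b3 - np.dot(b3, b2u) * b2u
    x = np.dot(v, w)
    y = np.dot(np.cross(b2u, v), w)
    return np.degrees(np.arctan2(y, x))


def test_improper_matches_brute_force_torsion():
    """ζ equals the independent vector-algebra torsion (shifted to the
    planar-PO₃ → 180° anchor) on random frames, to 1e−9."""
    rng = np.random.default_rng(2)
    frames = make_pt_frames(rng.uniform(-0.8, 0.8, 200), pyramidalization=9.0,
                            jitter_sd=0.08, seed=6)
    for fr in frames:
        a, b, c = (fr.position(f"O_nb{i}") for i in (1, 2, 3))
        d = fr.position("P_T")
        # package convention: negated textbook torsion, wrapped to [0, 360)
        expected = (-_brute_torsion(a, b, c, d)) % 360.0
        assert abs(improper_dihedral(fr) - expected) < 1e-9


def test_scalar_geometry_rigid_invariance():
    """All scalar descriptors are invariant under rigid transforms."""
    rng = np.random.default_rng(7)
    fr = make_pt_frames([0.25], pyramidalization=12.0, jitter_sd=0.05, seed=1)[0]
    ref = geometry_report(fr)
    for k in range(10):
        R = Rotation.random(random_state=k).as_matrix()
        t = rng.normal(0, 5, 3)
        moved = fr.with_coordinates(fr.coordinates @ R.T + t)
        rep = geometry_report(moved)
        assert rep.xi == pytest.approx(ref.xi, abs=1e-9)
        assert rep.d_donor_acceptor == pytest.approx(ref.d_donor_acceptor, abs=1e-9)
        assert rep.zeta == pytest.approx(ref.zeta, abs=1e-8)


def test_mofj_classification_definitional_cases():
    fr = _pt_frame(1.7, 1.7)
    (n_att, n_lv), cls = mofj_classify(fr, reference_bond_length=1.7, pauling_b=0.6)
    assert n_att == pytest.approx(1.0) and n_lv == pytest.approx(1.0)
    assert cls == "tight"
    far = _pt_frame(4.0, 4.0)
    (n_att, n_lv), cls = mofj_classify(far)
    assert n_att + n_lv < 0.1 and cls == "loose"


def test_mofj_boundary_matches_formula_sweep():
    """Classification flips exactly where n_att + n_lv crosses 1 ± τ."""
    xis = np.linspace(-1.5, 1.5, 61)
    frames = make_pt_frames(xis, donor_acceptor_distance=4.5)
    r0, b, tau = 1.7, 0.6, 0.1
    for fr in frames:
        rep = geometry_report(fr, r0, b, tau)
        total = rep.bond_order_attack + rep.bond_order_leave
        d_att = np.linalg.norm(fr.position("O_attacking") - fr.position("P_T"))
        d_lv = np.linalg.norm(fr.position("O_leaving") - fr.position("P_T"))
        expected_total = np.exp((r0 - d_att) / b) + np.exp((r0 - d_lv) / b)
        assert total == pytest.approx(expected_total, abs=1e-12)
        expected_cls = ("tight" if total > 1 + tau
                        else "loose" if total < 1 - tau else "synchronous")
        assert rep.mofj_class == expected_cls


def test_kabsch_identity_and_rigid_copy():
    fr = make_pt_frames([0.1], include_mg=True)[0]
    aligned, rmsd = kabsch_superpose([fr, fr])
    assert rmsd == pytest.approx([0.0, 0.0], abs=1e-12)
    R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = fr.with_coordinates(fr.coordinates @ R.T + np.array([3.0, -2.0, 0.5]))
    aligned, rmsd = kabsch_superpose([fr, moved])
    assert rmsd[1] < 1e-9
    assert np.abs(aligned[1].coordinates - fr.coordinates).max() < 1e-9


def test_kabsch_matches_independent_alignment():
    """RMSD agrees with scipy's independent rotation alignment."""
    rng = np.random.default_rng(3)
    fr = make_pt_frames([0.0], include_mg=True)[0]
    noisy = fr.with_coordinates(fr.coordinates + rng.normal(0, 0.1, fr.coordinates.shape))
    _, rmsd = kabsch_superpose([fr, noisy])
    P = noisy.coordinates - noisy.coordinates.mean(0)
    Q = fr.coordinates - fr.coordinates.mean(0)
    rot, rssd = Rotation.align_vectors(Q, P)
    assert rmsd[1] == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-9)


def test_kabsch_rejects_collinear_alignment_set():
    fr = make_pt_frames([0.0])[0]
    with pytest.raises(ValueError):
        kabsch_superpose([fr], align_roles=["O_leaving", "O_attacking", "P_T"])


def test_tse_width_degenerate_cases():
    fr = make_pt_frames([0.0])[0]
    assert tse_width([fr, fr]) == (0.0, 0.0)
    up = fr.with_coordinates(fr.coordinates + np.array([0.0, 0.0, 0.2]))
    down = fr.with_coordinates(fr.coordinates - np.array([0.0, 0.0, 0.2]))
    mean, sd = tse_width([up, down])
    assert mean == pytest.approx(0.2, abs=1e-12)
    assert sd == pytest.approx(0.0, abs=1e-12)


def test_tse_width_matches_chi_distribution_mean():
    """Isotropic 3D jitter of the P atom gives mean displacement
    σ·2·√(2/π)·Γ(2)/Γ(3/2) — the chi(3) mean — within 5% at n = 1000."""
    rng = np.random.default_rng(9)
    base = make_pt_frames([0.0])[0]
    sigma = 0.1
    frames = []
    for _ in range(1000):
        c = base.coordinates.copy()
        c[base.roles["P_T"]] += rng.normal(0, sigma, 3)
        frames.append(base.with_coordinates(c))
    mean, _ = tse_width(frames)
    chi3_mean = sigma * np.sqrt(2) * 2.0 / np.sqrt(np.pi)  # = σ·Γ(2)/Γ(3/2)·√2
    assert mean == pytest.approx(chi3_mean, rel=0.05)


def test_pca_single_axis_and_variance_conservation():
    base = make_pt_frames([0.0])[0]
    rng = np.random.default_rng(4)
    shifts = rng.normal(0, 0.3, 20)
    frames = [base.with_coordinates(base.coordinates + np.array([s, 0, 0]))
              for s in shifts]
    res = pca_tse(frames, ["P_T", "O_nb1", "O_nb2", "O_nb3"])
    assert res.rank == 1
    assert res.eigenvalues[0] > 0 and np.all(res.eigenvalues[1:] < 1e-12)
    pc1 = res.components[0].reshape(-1, 3)
    assert np.abs(np.abs(pc1[:, 0]) - 0.5).max() < 1e-9  # uniform x direction

    jittered = [base.with_coordinates(base.coordinates + rng.normal(0, 0.05, base.coordinates.shape))
                for _ in range(30)]
    res = pca_tse(jittered, ["P_T", "O_nb1", "O_nb2", "O_nb3"])
    X = np.array([f.coordinates[[f.roles[r] for r in ["P_T", "O_nb1", "O_nb2", "O_nb3"]]].ravel()
                  for f in jittered])
    assert res.eigenvalues.sum() == pytest.approx(X.var(axis=0, ddof=1).sum(), abs=1e-9)
    # orthonormal components
    G = res.components @ res.components.T
    assert np.abs(G - np.eye(len(G))).max() < 1e-9


def test_pca_recovers_known_covariance():
    rng = np.random.default_rng(11)
    base = make_pt_frames([0.0])[0]
    cov = np.array([[0.04, 0.018], [0.018, 0.01]])
    L = np.linalg.cholesky(cov)
    frames = []
    for _ in range(3000):
        xy = L @ rng.standard_normal(2)
        c = base.coordinates.copy()
        c[base.roles["P_T"], 0] += xy[0]
        c[base.roles["P_T"], 1] += xy[1]
        frames.append(base.with_coordinates(c))
    res = pca_tse(frames, ["P_T"])
    expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
    assert np.allclose(res.eigenvalues[:2], expected, rtol=0.1)


def test_frame_validation():
    with pytest.raises(ValueError):
        _frame([[0, 0, 0], [0, 0, 0.05], [1, 1, 1], [2, 2, 2], [3, 3, 3], [4, 4, 4]])
    with pytest.raises(ValueError):
        MolecularFrame(["A", "B"], np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]],
                       {"P_T": 0, "O_leaving": 0})
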