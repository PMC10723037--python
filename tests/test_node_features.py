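import numpy as np
import pytest

from gtbind.node_features import (
    DSSP_DIM,
    MAX_ASA,
    SS_COLUMNS,
    assemble_node_features,
    backbone_torsions,
    coarse_ss_from_torsions,
    dihedral,
    dssp_feature_group,
    fit_minmax_stats,
    minmax_normalize,
    read_dssp_file,
    relative_solvent_accessibility,
    secondary_structure_onehot,
    ss_onehot_from_string,
)
from gtbind.structure_io import ProteinRecord
from gtbind.synthetic import helix_backbone, synthetic_full_backbone
from gtbind._rng import rng_for


class TestMinMaxNormalize:
    stats = (np.array([2.0]), np.array([6.0]))

    @pytest.mark.parametrize("value,expected", [
        (2.0, 0.0), (6.0, 1.0), (4.0, 0.5), (8.0, 1.0), (0.0, 0.0),
    ])
    def test_mapping_and_clipping(self, value, expected):
        out = minmax_normalize(np.array([[value]]), self.stats)
        assert out[0, 0] == pytest.approx(expected)

    def test_constant_column_maps_to_zero(self):
        out = minmax_normalize(np.array([[5.0], [7.0]]),
                               (np.array([3.0]), np.array([3.0])))
        np.testing.assert_array_equal(out, 0.0)

    def test_column_mismatch(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.zeros((2, 3)), self.stats)

    def test_idempotent_on_unit_stats(self):
        rng = np.random.default_rng(0)
        M = rng.random((20, 4))
        stats = (np.zeros(4), np.ones(4))
        once = minmax_normalize(M, stats)
        np.testing.assert_allclose(minmax_normalize(once, stats), once)

    def test_fit_stats_cover_all_matrices(self):
        rng = np.random.default_rng(1)
        mats = [rng.normal(size=(10, 3)) for _ in range(4)]
        lo, hi = fit_minmax_stats(mats)
        stacked = np.vstack(mats)
        np.testing.assert_allclose(lo, stacked.min(axis=0))
        np.testing.assert_allclose(hi, stacked.max(axis=0))


def _dihedral_oracle(p0, p1, p2, p3):
    """Two-plane normal-vector formula with explicit sign from the triple
    product (independent of the atan2 implementation); IUPAC convention."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.arccos(np.clip(cosang, -1, 1))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestTorsions:
    def test_trans_planar_is_180(self):
        p = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], float)
        ang = dihedral(*p)
        assert abs(abs(ang) - np.pi) < 1e-12
        assert np.sin(ang) == pytest.approx(0.0, abs=1e-12)
        assert np.cos(ang) == pytest.approx(-1.0)

    def test_cis_planar_is_0(self):
        p = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        ang = dihedral(*p)
        assert np.sin(ang) == pytest.approx(0.0, abs=1e-12)
        assert np.cos(ang) == pytest.approx(1.0)

    def test_random_quadruples_match_two_plane_oracle(self):
        import biotite.structure as struc

        rng = np.random.default_rng(42)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            got = dihedral(*pts)
            assert got == pytest.approx(_dihedral_oracle(*pts), abs=1e-10)
            # independent reference implementation agrees on the convention
            ref = float(struc.dihedral(*(pts[i] for i in range(4))))
            assert got == pytest.approx(ref, abs=1e-5)

    def test_collinear_quadruple_is_nan(self):
        p = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        assert np.isnan(dihedral(*p))

    def test_backbone_termini_encode_zero(self):
        bb = synthetic_full_backbone(helix_backbone(8), rng_for(0, "bb"))
        tors = backbone_torsions(bb)
        assert tors.shape == (8, 4)
        np.testing.assert_array_equal(tors[0, :2], 0.0)   # no phi at N-term
        np.testing.assert_array_equal(tors[-1, 2:], 0.0)  # no psi at C-term
        # interior angles are well-defined unit (sin, cos) pairs
        norms = np.hypot(tors[1:-1, 0], tors[1:-1, 1])
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)


class TestRSA:
    def test_isolated_residues_fully_exposed(self):
        rec = ProteinRecord(id="iso", sequence="GG",
                            ca_coords=np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        rsa = relative_solvent_accessibility(rec)
        np.testing.assert_allclose(rsa, 1.0)

    def test_buried_residue_near_zero(self):
        # one residue at the center of a dense shell of others
        rng = np.random.default_rng(0)
        shell = rng.normal(size=(80, 3))
        shell = 3.9 * shell / np.linalg.norm(shell, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0, 0], shell])
        rec = ProteinRecord(id="bury", sequence="G" * 81, ca_coords=coords)
        rsa = relative_solvent_accessibility(rec)
        assert rsa[0] < 0.05

    def test_refined_sampling_oracle(self):
        rec = ProteinRecord(id="two", sequence="AG",
                            ca_coords=np.array([[0.0, 0, 0], [3.8, 0, 0]]))
        coarse = relative_solvent_accessibility(rec, sphere_points=100)
        fine = relative_solvent_accessibility(rec, sphere_points=1000)
        np.testing.assert_allclose(coarse, fine, rtol=0.05)

    def test_unknown_residue_uses_glycine_max(self):
        rec = ProteinRecord(id="unk", sequence="XG",
                            ca_coords=np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        with pytest.warns(UserWarning, match="glycine"):
            rsa = relative_solvent_accessibility(rec)
        assert rsa[0] == pytest.approx(1.0)


def _dssp_line(idx, resnum, aa, ss, acc=100, phi=-60.0, psi=-45.0):
    line = [" "] * 120
    line[0:5] = f"{idx:5d}"
    line[5:10] = f"{resnum:5d}"
    line[11] = "A"
    line[13] = aa
    line[16] = ss
    line[34:38] = f"{acc:4d}"
    line[38:45] = f"{0:7d}"
    line[46:50] = "0.0 "
    line[50:56] = f"{0:6d}"
    line[57:61] = "0.0 "
    line[61:67] = f"{0:6d}"
    line[68:72] = "0.0 "
    line[72:78] = f"{0:6d}"
    line[79:83] = "0.0 "
    line[103:109] = f"{phi:6.1f}"
    line[109:115] = f"{psi:6.1f}"
    return "".join(line)


def make_dssp_file(path, rows):
    header = "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
    lines = [header]
    for i, row in enumerate(rows):
        lines.append(_dssp_line(i + 1, i + 1, *row))
    path.write_text("\n".join(lines) + "\n")


class TestSecondaryStructure:
    def test_dssp_all_helix(self, tmp_path):
        p = tmp_path / "h.dssp"
        make_dssp_file(p, [("A", "H")] * 5)
        onehot = secondary_structure_onehot(5, dssp_path=p)
        np.testing.assert_array_equal(onehot[:, SS_COLUMNS.index("H")], 1.0)
        assert onehot.sum() == 5

    def test_blank_ss_maps_to_dash(self, tmp_path):
        p = tmp_path / "b.dssp"
        make_dssp_file(p, [("A", " "), ("G", "E")])
        ss, acc, angles = read_dssp_file(p)
        assert ss == "-E"
        onehot = ss_onehot_from_string(ss)
        assert onehot[0, SS_COLUMNS.index("-")] == 1

    def test_residue_count_mismatch(self, tmp_path):
        p = tmp_path / "m.dssp"
        make_dssp_file(p, [("A", "H")] * 3)
        with pytest.raises(ValueError):
            secondary_structure_onehot(5, dssp_path=p)

    def test_fallback_assigns_helix_on_alpha_torsions(self):
        # ideal alpha region: phi = -60, psi = -45
        phi, psi = np.radians(-60.0), np.radians(-45.0)
        tors = np.tile([np.sin(phi), np.cos(phi), np.sin(psi), np.cos(psi)],
                       (6, 1))
        assert coarse_ss_from_torsions(tors) == "H" * 6

    def test_fallback_assigns_sheet_on_beta_torsions(self):
        phi, psi = np.radians(-120.0), np.radians(130.0)
        tors = np.tile([np.sin(phi), np.cos(phi), np.sin(psi), np.cos(psi)],
                       (4, 1))
        assert coarse_ss_from_torsions(tors) == "E" * 4

    def test_no_source_gives_unassigned(self):
        onehot = secondary_structure_onehot(3)
        np.testing.assert_array_equal(onehot[:, -1], 1.0)

    def test_one_hot_rows_sum_to_one(self, tmp_path):
        p = tmp_path / "mix.dssp"
        make_dssp_file(p, [("A", c) for c in "HBEGITS- "])
        onehot = secondary_structure_onehot(9, dssp_path=p)
        np.testing.assert_array_equal(onehot.sum(axis=1), 1.0)


class TestAssembly:
    def test_published_dimensions(self):
        emb = np.zeros((5, 1024))
        dssp = np.zeros((5, DSSP_DIM))
        nfm = assemble_node_features(emb, dssp)
        assert nfm.d == 1038
        assert nfm.block_spans == {"embedding": (0, 1024),
                                   "dssp": (1024, 1038)}

    def test_synthetic_dimensions(self):
        nfm = assemble_node_features(np.zeros((4, 8)), np.zeros((4, DSSP_DIM)))
        assert nfm.d == 22

    def test_row_permutation_is_local(self):
        rng = np.random.default_rng(5)
        emb = rng.random((6, 8))
        dssp = rng.random((6, DSSP_DIM))
        perm = rng.permutation(6)
        a = assemble_node_features(emb, dssp).H[perm]
        b = assemble_node_features(emb[perm], dssp[perm]).H
        np.testing.assert_array_equal(a, b)

    def test_row_mismatch(self):
        with pytest.raises(ValueError):
            assemble_node_features(np.zeros((3, 8)), np.zeros((4, DSSP_DIM)))


def test_dssp_group_rigid_invariance():
    """Structural features depend only on internal geometry."""
    ca = helix_backbone(20)
    bb = synthetic_full_backbone(ca, rng_for(1, "bb"))
    rec = ProteinRecord(id="h", sequence="A" * 20, ca_coords=ca, backbone=bb)
    base = dssp_feature_group(rec, sphere_points=500)
    assert base.shape == (20, DSSP_DIM)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    t = np.array([5.0, -3.0, 11.0])
    rec2 = ProteinRecord(id="h2", sequence="A" * 20, ca_coords=ca @ R.T + t,
                         backbone=bb @ R.T + t)
    rot = dssp_feature_group(rec2, sphere_points=500)
    # SS one-hot and torsions are exactly invariant; RSA is invariant up to
    # the resolution of the sphere sampling (the point lattice is laid out
    # in the global frame)
    np.testing.assert_allclose(rot[:, 1:], base[:, 1:], atol=1e-9)
    np.testing.assert_allclose(rot[:, 0], base[:, 0], atol=0.03)
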