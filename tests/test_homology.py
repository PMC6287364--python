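"""Alignment, rigid superposition and homologous bridge mapping."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from acidbridge.bridges import detect_salt_bridges
from acidbridge.homology import (
    AlignmentResult,
    align_sequences,
    map_bridge_positions,
    superpose,
    superpose_structures,
)
from acidbridge.synth import ToyStructureSpec, make_toy_structure


def gotoh_score(a, b, matrix, open_pen=10.0, ext_pen=0.5):
    """Independent affine-gap global alignment DP (gap of length L costs
    open + (L-1)*ext, the same convention as the implementation's aligner)."""
    n, m = len(a), len(b)
    neg = -1e30
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_pen - (i - 1) * ext_pen
    for j in range(1, m + 1):
        Y[0][j] = -open_pen - (j - 1) * ext_pen
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_pen, X[i - 1][j] - ext_pen,
                          Y[i - 1][j] - open_pen)
            Y[i][j] = max(M[i][j - 1] - open_pen, Y[i][j - 1] - ext_pen,
                          X[i][j - 1] - open_pen)
    return max(M[n][m], X[n][m], Y[n][m])


def quaternion_superpose_rmsd(a, b):
    """Horn's quaternion method for the least-squares rigid fit (oracle)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    S = ac.T @ bc
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    K = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(ac ** 2) + np.sum(bc ** 2) - 2.0 * lam) / a.shape[0]
    return np.sqrt(max(msd, 0.0))


class TestAlignSequences:
    def test_identical_sequences(self):
        res = align_sequences("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY")
        assert res.identity == 100.0
        assert res.similarity == 100.0
        assert "-" not in res.aligned_a + res.aligned_b

    def test_score_matches_dp_oracle_on_classic_pair(self):
        res = align_sequences("HEAGAWGHEE", "PAWHEAE")
        blosum = substitution_matrices.load("BLOSUM62")
        assert res.score == pytest.approx(
            gotoh_score("HEAGAWGHEE", "PAWHEAE", blosum))

    def test_score_symmetric_under_swap(self):
        a, b = "MKVLATTLLAGW", "MKILSTTLAW"
        assert align_sequences(a, b).score == pytest.approx(
            align_sequences(b, a).score)

    def test_identity_never_exceeds_similarity(self):
        res = align_sequences("MKVLATTLLAGW", "MKILSTTLAW")
        assert res.identity <= res.similarity <= 100.0

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError):
            align_sequences("ACDB2", "ACD")
        with pytest.raises(ValueError):
            align_sequences("", "ACD")

    def test_position_map_indices_consistent(self):
        a, b = "MKVLATTLLAGW", "KVLTTLAG"
        res = align_sequences(a, b)
        for ia, ib in res.position_map:
            assert 0 <= ia < len(a) and 0 <= ib < len(b)


class TestSuperpose:
    def _points(self, n=8, seed=0):
        return np.random.default_rng(seed).uniform(-10, 10, size=(n, 3))

    def test_self_superposition_is_identity(self):
        pts = self._points()
        sup = superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_recovers_exactly(self):
        pts = self._points()
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg z
        moved = pts @ rot.T + np.array([5.0, -3.0, 12.0])
        sup = superpose(pts, moved)
        assert sup.rmsd < 1e-6
        np.testing.assert_allclose(sup.apply(pts), moved, atol=1e-6)

    def test_rotation_is_proper_orthonormal(self):
        pts = self._points(seed=3)
        noisy = pts + np.random.default_rng(4).normal(0, 0.5, pts.shape)
        sup = superpose(pts, noisy)
        np.testing.assert_allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_reflection_corrected(self):
        pts = self._points(seed=5)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        sup = superpose(pts, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_quaternion_oracle(self):
        pts = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 4.0, 0], [1.0, 1.0, 5.0]])
        noisy = pts + np.random.default_rng(1).normal(0, 0.1, pts.shape)
        sup = superpose(pts, noisy)
        assert sup.rmsd == pytest.approx(quaternion_superpose_rmsd(pts, noisy), abs=1e-8)

    def test_rmsd_symmetric(self):
        a = self._points(seed=7)
        b = a + np.random.default_rng(8).normal(0, 0.3, a.shape)
        assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            superpose(line, line)

    def test_structure_superposition_on_rigid_copy(self, arg_glu_structure):
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("zyx", [40, 10, -70], degrees=True).as_matrix()
        moved = arg_glu_structure.transformed(rot, np.array([1.0, 2.0, 3.0]))
        sup = superpose_structures(arg_glu_structure, moved)
        assert sup.rmsd < 1e-6


def strip_charges(structure, resnums, new_names=("ALA", "ASN")):
    """Neutralise planted pair residues (the grafting targets)."""
    out = structure.copy()
    for resnum, name in zip(resnums, new_names):
        res = out.get_residue("A", resnum)
        res.residue_name = name
        res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")]
        for a in res.atoms:
            a.residue_name = name
    return out


class TestMapBridgePositions:
    def _donor(self):
        return make_toy_structure(ToyStructureSpec(planted_pairs=[("ARG", "GLU", 3.5)]))

    def test_identical_acceptor_conserved(self):
        donor = self._donor()
        bridges = detect_salt_bridges(donor)
        aln = align_sequences(donor.sequence("A"), donor.sequence("A"))
        calls = map_bridge_positions(bridges, aln, donor, donor)
        assert [c.call for c in calls] == ["conserved"]
        assert calls[0].mutation_targets is None

    def test_neutral_acceptor_incompatible_both_sides(self):
        donor = self._donor()
        acceptor = strip_charges(donor, (2, 3))
        bridges = detect_salt_bridges(donor)
        aln = align_sequences(donor.sequence("A"), acceptor.sequence("A"))
        calls = map_bridge_positions(bridges, aln, acceptor, donor)
        assert calls[0].call == "incompatible"
        targets = {(t[1], t[2], t[3]) for t in calls[0].mutation_targets}
        assert targets == {(2, "ALA", "ARG"), (3, "ASN", "GLU")}

    def test_one_sided_incompatibility(self):
        donor = self._donor()
        acceptor = donor.copy()
        res = acceptor.get_residue("A", 2)
        res.residue_name = "LYS"  # still positive: conserved on that side
        for a in res.atoms:
            a.residue_name = "LYS"
        bridges = detect_salt_bridges(donor)
        aln = align_sequences(donor.sequence("A"), acceptor.sequence("A"))
        calls = map_bridge_positions(bridges, aln, acceptor, donor)
        assert calls[0].call == "conserved"

    def test_gap_column_unmappable(self):
        donor = self._donor()
        bridges = detect_salt_bridges(donor)
        # hand-crafted alignment mapping the bridge residues to gaps
        seq = donor.sequence("A")
        aln = AlignmentResult(
            aligned_a=seq, aligned_b="-" * len(seq), score=0.0,
            identity=0.0, similarity=0.0, position_map=[],
        )
        calls = map_bridge_positions(bridges, aln, donor, donor)
        assert [c.call for c in calls] == ["unmappable"]

    def test_calls_partition_donor_bridges(self):
        donor = make_toy_structure(ToyStructureSpec(planted_pairs=[
            ("ARG", "GLU", 3.5), ("LYS", "ASP", 3.2), ("HIS", "GLU", 3.9)]))
        acceptor = strip_charges(donor, (10, 11))
        bridges = detect_salt_bridges(donor)
        aln = align_sequences(donor.sequence("A"), acceptor.sequence("A"))
        calls = map_bridge_positions(bridges, aln, acceptor, donor)
        assert len(calls) == len(bridges)
        counts = {
            "conserved": sum(c.call == "conserved" for c in calls),
            "incompatible": sum(c.call == "incompatible" for c in calls),
            "unmappable": sum(c.call == "unmappable" for c in calls),
        }
        assert sum(counts.values()) == len(bridges)
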