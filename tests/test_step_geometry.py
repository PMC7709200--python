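"""Torsion measurement, step dissection and superposition, checked against
independent closed-form and quaternion oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ntckit._nerf import build_strand
from ntckit.step_geometry import (
    LINKAGE_CUTOFF,
    TORSION_NAMES,
    TorsionVector,
    UndefinedTorsionError,
    circular_distance,
    dihedral,
    dissect_steps,
    rmsd_structures,
    step_atoms,
    step_torsions,
    superpose,
    wrap_degrees,
)
from ntckit.synthetic import FORMS, BuildSpec, build_duplex


# --- independent oracles ----------------------------------------------------


def dihedral_oracle(p1, p2, p3, p4):
    """Closed-form atan2 formula written independently of the implementation."""
    b0 = np.asarray(p1) - np.asarray(p2)
    b1 = np.asarray(p3) - np.asarray(p2)
    b2 = np.asarray(p4) - np.asarray(p3)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


def quaternion_superpose_rmsd(P, Q):
    """Horn's quaternion method for optimal proper superposition r.m.s.d."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = max((P**2).sum() + (Q**2).sum() - 2.0 * lam, 0.0)
    return np.sqrt(e2 / len(P))


# --- dihedral ---------------------------------------------------------------


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([1, 1, 0], [0, 0, 0], [0, 0, 1], [1, -1, 1]) != 0  # sanity: generic
        assert dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], [1, 0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        val = dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], [-1, 0, 1])
        assert val == pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [-150, -90, -60, -30, 30, 60, 90, 150, 179])
    def test_constructed_angle_family(self, theta):
        # four points built so that the torsion equals theta by construction
        t = np.radians(theta)
        p4 = [np.cos(t), np.sin(t), 1.0]
        val = dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], p4)
        assert val == pytest.approx(theta, abs=1e-9)

    @pytest.mark.parametrize("pts", [
        ([0, 0, 0], [0, 0, 0], [0, 0, 1], [1, 0, 1]),   # degenerate bond
        ([0, 0, 2], [0, 0, 1], [0, 0, 0], [1, 0, 0]),   # collinear p1 p2 p3
    ])
    def test_degenerate_raises(self, pts):
        with pytest.raises(UndefinedTorsionError):
            dihedral(*pts)

    @given(st.lists(st.floats(-10, 10), min_size=12, max_size=12),
           st.lists(st.floats(-1, 1), min_size=3, max_size=3),
           st.integers(0, 1000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_oracle_and_rigid_motion_invariance(self, flat, axis, seed):
        pts = np.array(flat).reshape(4, 3)
        try:
            ref = dihedral(*pts)
        except UndefinedTorsionError:
            return
        assert ref == pytest.approx(dihedral_oracle(*pts), abs=1e-6)
        # arbitrary rotation + translation leaves the torsion unchanged
        rng = np.random.default_rng(seed)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 5
        moved = pts @ R.T + t
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-6)
        # mirror reflection flips the sign
        mirrored = pts * np.array([1, 1, -1])
        if abs(abs(ref) - 180.0) > 1e-6:
            assert dihedral(*mirrored) == pytest.approx(-ref, abs=1e-6)

    def test_range_is_half_open(self):
        assert wrap_degrees(-180.0) == 180.0
        assert wrap_degrees(180.0) == 180.0
        assert wrap_degrees(540.0) == 180.0


# --- dissection and torsions ------------------------------------------------


class TestDissectSteps:
    def test_intact_18mer_gives_17_steps(self):
        tv = FORMS["A"].torsions
        strand = build_strand("G" * 18, [tv] * 17)
        assert len(dissect_steps(strand)) == 17

    def test_chain_break_skips_step(self):
        tv = FORMS["A"].torsions
        strand = build_strand("G" * 18, [tv] * 17)
        # open a gap between residues 9 and 10
        for nt in strand[9:]:
            for a in nt.atoms.values():
                a.pos = a.pos + np.array([5.0, 0.0, 0.0])
        assert len(dissect_steps(strand)) == 16

    def test_single_nucleotide_no_steps(self):
        tv = FORMS["A"].torsions
        strand = build_strand("GG", [tv])
        assert dissect_steps(strand[:1]) == []

    def test_linkage_cutoff_is_generous_but_finite(self):
        assert 1.6 < LINKAGE_CUTOFF <= 3.0


class TestStepTorsions:
    def test_builder_roundtrip_identity(self):
        # the builder's input torsions are recovered exactly at zero noise
        for form in ("A", "B"):
            tv_in = FORMS[form].torsions
            strand = build_strand("GATC", [tv_in] * 3)
            for step in dissect_steps(strand):
                tv = step_torsions(step)
                assert circular_distance(tv, tv_in) < 1e-6

    def test_a_and_b_form_delta_ranges_distinct(self):
        a = FORMS["A"].torsions.delta1
        b = FORMS["B"].torsions.delta1
        assert 80 <= a <= 88 and 128 <= b <= 144

    def test_missing_atom_flags_incomplete(self):
        tv = FORMS["A"].torsions
        strand = build_strand("GG", [tv])
        del strand[0].atoms["O3'"]
        steps = dissect_steps(strand)
        assert steps == []  # linkage atom gone -> no step at all
        strand = build_strand("GG", [tv])
        del strand[1].atoms["C1'"]
        tv_meas = step_torsions(dissect_steps(strand)[0])
        assert not tv_meas.complete
        assert "C1'" in tv_meas.missing

    def test_step_atoms_is_18_and_resolves_glycosidic(self):
        tv = FORMS["B"].torsions
        strand = build_strand("GT", [tv])
        sa = step_atoms(dissect_steps(strand)[0])
        assert sa.complete and len(sa.coords) == 18


# --- superposition ----------------------------------------------------------


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(1)
        pts = {f"p{i}": rng.normal(size=3) for i in range(5)}
        res = superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-6)

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(6, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ R.T + [1.0, -2.0, 3.0]
        labels = [str(i) for i in range(6)]
        res = superpose((labels, P), (labels, Q))
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, R, atol=1e-6)
        assert np.allclose(res.apply(P), Q, atol=1e-9)

    def test_matches_quaternion_oracle_on_step_sets(self, catalog):
        A = catalog["AA00"].rep_atoms
        B = catalog["BB00"].rep_atoms
        res = superpose(A, (A.labels, B.coords))
        oracle = quaternion_superpose_rmsd(np.array(A.coords), np.array(B.coords))
        assert res.rmsd == pytest.approx(oracle, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetric_rmsd(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(8, 3))
        Q = rng.normal(size=(8, 3))
        labels = [str(i) for i in range(8)]
        ab = superpose((labels, P), (labels, Q)).rmsd
        ba = superpose((labels, Q), (labels, P)).rmsd
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_no_reflections(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(5, 3))
        labels = [str(i) for i in range(5)]
        res = superpose((labels, P), (labels, P * np.array([1, 1, -1])))
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_label_mismatch_raises(self):
        with pytest.raises(ValueError):
            superpose((["a", "b", "c"], np.eye(3)), (["a", "b", "d"], np.eye(3)))

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            superpose((["a", "b"], np.zeros((2, 3))), (["a", "b"], np.zeros((2, 3))))


class TestRmsdStructures:
    def test_self_is_zero(self, chom_duplex):
        assert rmsd_structures(chom_duplex, chom_duplex) == pytest.approx(0.0, abs=1e-9)

    def test_cross_sequence_uses_shared_atom_names(self):
        # two duplexes differing at 4 sequence positions still compare over
        # the shared backbone + common base atoms
        from conftest import CHOM18, HPAR18
        a = build_duplex(BuildSpec(sequence=CHOM18, form="A", mismatch_positions=(9, 10)))
        b = build_duplex(BuildSpec(sequence=HPAR18, form="A", mismatch_positions=(9, 10)))
        val = rmsd_structures(a, b)
        assert 0.0 <= val < 2.0  # idealized geometry: same helix, different bases

    def test_perturbed_copy_has_positive_rmsd(self, chom_duplex_plain):
        from ntckit.synthetic import perturb_torsions
        noisy = perturb_torsions(chom_duplex_plain, 5.0, seed=11)
        val = rmsd_structures(chom_duplex_plain, noisy)
        assert val > 0.05

    def test_empty_match_raises(self, chom_duplex):
        with pytest.raises(ValueError):
            rmsd_structures(chom_duplex, chom_duplex, selection=lambda a: False)


def test_torsion_vector_array_roundtrip():
    v = np.array([83, -143.3, -80, -59.9, 153.3, 55.1, 83, -162.2, -162.2])
    tv = TorsionVector.from_array(v)
    assert tv.complete
    assert np.allclose(tv.as_array(), v)
    assert list(TORSION_NAMES)[0] == "delta1"
    incomplete = TorsionVector(delta1=83.0, missing=("O3'",))
    assert not incomplete.complete
    with pytest.raises(ValueError):
        incomplete.as_array()
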