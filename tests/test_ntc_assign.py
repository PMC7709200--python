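"""Conformer-class catalog and step assignment."""

import numpy as np
import pytest

from ntckit._nerf import build_strand
from ntckit.ntc_assign import (
    NANT,
    Catalog,
    NtCClass,
    assign_step,
    annotate_structure,
    builtin_catalog,
    confal_like,
    export_restraints,
    nearest_class_rmsd,
    parse_restraints,
)
from ntckit.step_geometry import (
    StepAtoms,
    TorsionVector,
    circular_distance,
    dissect_steps,
    step_atoms,
    step_torsions,
    superpose,
    wrap_degrees,
)
from ntckit.synthetic import BuildSpec, build_duplex, build_strand_of_classes


class TestCatalog:
    def test_contains_expected_classes(self, catalog):
        for name in ("AA00", "AA08", "AA06", "AA10", "AA11", "AA12",
                     "BB00", "BB01", "BB07", "BA05", "AB01"):
            assert name in catalog

    def test_cana_grouping(self, catalog):
        assert catalog.cana("AA00") == catalog.cana("AA08")
        assert catalog.cana("AA00") != catalog.cana("BB00")

    def test_rep_atoms_reproduce_centroids(self, catalog):
        for cls in catalog:
            strand = build_strand("GG", [cls.centroid])
            tv = step_torsions(dissect_steps(strand)[0])
            assert circular_distance(tv, cls.centroid) < 0.5
            assert cls.rep_atoms.complete

    def test_classes_well_separated(self, catalog):
        # pairwise centroid separation large enough for noisy recovery
        M = catalog.centroid_matrix()
        for i in range(len(M)):
            for j in range(i + 1, len(M)):
                assert np.linalg.norm(wrap_degrees(M[i] - M[j])) > 50

    def test_user_extensible(self, catalog):
        extra = NtCClass("ZZ99", "ZZZ", TorsionVector.from_array([10] * 9))
        cat = Catalog(list(catalog))
        cat.add(extra)
        assert "ZZ99" in cat and len(cat) == len(catalog) + 1
        with pytest.raises(ValueError):
            cat.add(extra)

    def test_tsv_roundtrip(self, catalog, tmp_path):
        path = tmp_path / "cat.tsv"
        catalog.to_tsv(path)
        back = Catalog.from_tsv(path)
        assert back.names == catalog.names
        for name in back.names:
            assert circular_distance(back[name].centroid, catalog[name].centroid) < 1e-9

    def test_corrupt_catalog_raises(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("name\tcana\n x\ty\n")
        with pytest.raises(ValueError):
            Catalog.from_tsv(bad)


class TestAssignStep:
    def test_centroid_assigns_to_own_class_distance_zero(self, catalog):
        for cls in catalog:
            a = assign_step(cls.centroid, cls.rep_atoms, catalog)
            assert a.ntc == cls.name
            assert a.torsion_distance == pytest.approx(0.0, abs=1e-9)
            assert a.cart_rmsd == pytest.approx(0.0, abs=1e-6)
            assert a.confal_like == pytest.approx(100.0)

    def test_far_torsions_give_nant(self, catalog):
        tv = TorsionVector.from_array(catalog["AA00"].centroid.as_array() + 90.0)
        a = assign_step(tv, None, catalog)
        # every torsion is 90 deg from AA00; whichever class is nearest, the
        # per-torsion cap or aggregate threshold must reject it
        if a.ntc == NANT:
            assert a.reason
        else:  # the +90 shift could in principle land near another class: it must not
            pytest.fail(f"expected NANT, got {a.ntc}")

    def test_incomplete_vector_nant_with_reason(self, catalog):
        tv = TorsionVector(delta1=80.0, missing=("O3'",))
        a = assign_step(tv, None, catalog)
        assert a.ntc == NANT and "missing" in a.reason

    def test_noise_free_bform_assigns_bb00(self, catalog):
        strand = build_strand("G" * 18, [catalog["BB00"].centroid] * 17)
        for step in dissect_steps(strand):
            a = assign_step(step_torsions(step), None, catalog)
            assert a.ntc == "BB00"

    def test_confal_monotone_decreasing(self, catalog):
        base = catalog["AA00"].centroid.as_array()
        last = 101.0
        for shift in (0, 5, 10, 20, 40):
            tv = TorsionVector.from_array(base + shift / 3.0)
            a = assign_step(tv, None, catalog)
            assert a.confal_like < last
            last = a.confal_like
        assert confal_like(0.0) == 100.0

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            Catalog([])


class TestRecovery:
    def test_recovery_at_sigma8_geq_95pct(self, catalog):
        # wrapped-Gaussian torsion noise, sigma 8 deg, 1000 trials across classes
        rng = np.random.default_rng(20240917)
        names = catalog.names
        n_ok = 0
        trials = 1000
        for k in range(trials):
            cls = catalog[names[k % len(names)]]
            tv = TorsionVector.from_array(
                cls.centroid.as_array() + rng.normal(0.0, 8.0, size=9))
            a = assign_step(tv, None, catalog)
            n_ok += a.ntc == cls.name
        assert n_ok / trials >= 0.95

    def test_exact_recovery_at_sigma0(self, catalog):
        # generator output at zero noise is never NANT and always recovers
        for cls in catalog:
            strand = build_strand("GG", [cls.centroid])
            tv = step_torsions(dissect_steps(strand)[0])
            a = assign_step(tv, None, catalog)
            assert a.ntc == cls.name


class TestAnnotateStructure:
    def test_noise_free_duplex_all_assigned(self, chom_duplex_plain, catalog):
        annotated, summary = annotate_structure(chom_duplex_plain, catalog)
        assert summary["n_steps"] == 34  # 17 per strand
        assert summary["n_outliers"] == 0
        assert all(r.assignment.ntc == "AA00" for r in annotated)

    def test_randomized_step_becomes_outlier(self, catalog):
        from ntckit.synthetic import FORMS
        strand = build_strand("G" * 18, [FORMS["A"].torsions] * 17)
        # scramble the backbone of residue 10 far from every class while
        # keeping the O3'-P linkages intact
        rng = np.random.default_rng(5)
        for name in ("O5'", "C5'"):
            strand[10].atoms[name].pos = strand[10].atoms[name].pos + rng.normal(0, 3.0, 3)
        from ntckit.structure_io import Structure
        st = Structure("noisy", {"A": strand}, cell=(80, 80, 80, 90, 90, 90))
        _, summary = annotate_structure(st, catalog)
        assert summary["n_outliers"] >= 1
        assert summary["n_assigned"] + summary["n_outliers"] == summary["n_steps"]

    def test_mixed_form_strand_matches_construction(self, catalog):
        classes = ["BB00"] * 9 + ["AA00"] * 8
        st = build_strand_of_classes("G" * 18, classes)
        annotated, summary = annotate_structure(st, catalog)
        got = [r.assignment.ntc for r in annotated]
        # interior steps follow the construction; the two B/A junction steps
        # mix torsions of both forms and may legitimately differ
        assert got[:8] == ["BB00"] * 8
        assert got[10:] == ["AA00"] * 7
        assert summary["n_steps"] == 17


class TestNearestClassRmsd:
    def test_rep_atoms_give_zero(self, catalog):
        name, val = nearest_class_rmsd(catalog["BB00"].rep_atoms, catalog)
        assert name == "BB00" and val == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_rigid_motion(self, catalog):
        from scipy.spatial.transform import Rotation
        rep = catalog["AA00"].rep_atoms
        R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        moved = StepAtoms(rep.labels, np.asarray(rep.coords) @ R.T + [3.0, -2.0, 7.0])
        name, val = nearest_class_rmsd(moved, catalog)
        assert name == "AA00" and val == pytest.approx(0.0, abs=1e-9)

    def test_interpolated_matches_exhaustive_oracle(self, catalog):
        a = np.asarray(catalog["AA00"].rep_atoms.coords)
        b = np.asarray(catalog["BB00"].rep_atoms.coords)
        labels = catalog["AA00"].rep_atoms.labels
        mid = StepAtoms(labels, 0.5 * (a + b))
        name, val = nearest_class_rmsd(mid, catalog)
        # brute force over every representative
        brute = min(
            (superpose(mid, c.rep_atoms).rmsd, c.name) for c in catalog
        )
        assert val == pytest.approx(brute[0], abs=1e-9)
        assert name == brute[1]

    def test_nant_steps_still_get_finite_value(self, catalog):
        # Cartesian closeness is defined even when torsion assignment fails
        tv = TorsionVector.from_array(catalog["AA00"].centroid.as_array() + 90.0)
        strand = build_strand("GG", [tv])
        sa = step_atoms(dissect_steps(strand)[0])
        a = assign_step(step_torsions(dissect_steps(strand)[0]), sa, catalog)
        _, val = nearest_class_rmsd(sa, catalog)
        assert np.isfinite(val)
        assert a.cart_rmsd is not None and np.isfinite(a.cart_rmsd)

    def test_incomplete_step_raises(self, catalog):
        with pytest.raises(ValueError):
            nearest_class_rmsd(StepAtoms(("1:P",), np.zeros((1, 3))), catalog)


class TestRestraints:
    def test_assigned_step_emits_nine_records(self, catalog):
        strand = build_strand("GG", [catalog["AA00"].centroid])
        from ntckit.structure_io import Structure
        st = Structure("s", {"A": strand}, cell=(60, 60, 60, 90, 90, 90))
        annotated, _ = annotate_structure(st, catalog)
        text = export_restraints(annotated, catalog)
        df = parse_restraints(text)
        assert len(df) == 9
        assert set(df["ntc"]) == {"AA00"}

    def test_targets_roundtrip_to_centroid_exactly(self, catalog):
        strand = build_strand("GG", [catalog["BB00"].centroid])
        from ntckit.structure_io import Structure
        st = Structure("s", {"A": strand}, cell=(60, 60, 60, 90, 90, 90))
        annotated, _ = annotate_structure(st, catalog)
        df = parse_restraints(export_restraints(annotated, catalog))
        cen = catalog["BB00"].centroid
        for _, row in df.iterrows():
            assert row["target"] == pytest.approx(getattr(cen, row["torsion"]), abs=0.005)

    def test_sigma_scale_applied(self, catalog):
        strand = build_strand("GG", [catalog["AA00"].centroid])
        from ntckit.structure_io import Structure
        st = Structure("s", {"A": strand}, cell=(60, 60, 60, 90, 90, 90))
        annotated, _ = annotate_structure(st, catalog)
        df1 = parse_restraints(export_restraints(annotated, catalog, sigma_scale=1.0))
        df2 = parse_restraints(export_restraints(annotated, catalog, sigma_scale=2.0))
        assert np.allclose(df2["sigma"], 2.0 * df1["sigma"])

    def test_all_nant_input_empty_output(self, catalog, caplog):
        tv = TorsionVector.from_array(catalog["AA00"].centroid.as_array() + 90.0)
        strand = build_strand("GG", [tv])
        from ntckit.structure_io import Structure
        st = Structure("s", {"A": strand}, cell=(60, 60, 60, 90, 90, 90))
        annotated, _ = annotate_structure(st, catalog)
        import logging
        with caplog.at_level(logging.WARNING):
            text = export_restraints(annotated, catalog)
        assert parse_restraints(text).empty
        assert any("NANT" in r.message for r in caplog.records)
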