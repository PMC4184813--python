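"""Torsion-grid potential: interpolation, table I/O, torsion resolution, forces."""

import numpy as np
import pytest

from fbrefine.fixtures import FixtureSpec, build_polypeptide, perturb
from fbrefine.structure import AtomRecord, StructureModel, dihedral
from fbrefine.torsiongrid import (PAIR_KINDS, RESIDUE_CLASSES,
                                  TorsionEvaluator, TorsionGridTable,
                                  generate_synthetic_tables, load_tables,
                                  residue_torsion_atoms, save_tables,
                                  torsion_energy)


def _bilinear_oracle(grid, bw, t1, t2):
    """Independent periodic bilinear interpolation via an extended lattice."""
    from scipy.interpolate import RegularGridInterpolator
    n = grid.shape[0]
    ext = np.pad(grid, ((0, 1), (0, 1)), mode="wrap")
    axis = -180.0 + bw * np.arange(n + 1)
    f = RegularGridInterpolator((axis, axis), ext, method="linear")
    u = (t1 + 180.0) % 360.0 - 180.0
    v = (t2 + 180.0) % 360.0 - 180.0
    return float(f((u, v)))


class TestInterpolation:
    def test_exact_at_grid_nodes(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(36, 36))
        tab = TorsionGridTable("ALA", "phi-psi", grid, 10.0)
        for i, j in ((0, 0), (5, 7), (35, 35), (17, 2)):
            t1, t2 = -180.0 + 10.0 * i, -180.0 + 10.0 * j
            e, _, _ = tab.interpolate(t1, t2)
            assert e == pytest.approx(grid[i, j], abs=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        grid = rng.normal(size=(36, 36))
        tab = TorsionGridTable("ALA", "phi-psi", grid, 10.0)
        for _ in range(200):
            t1 = rng.uniform(-180, 180)
            t2 = rng.uniform(-180, 180)
            e, _, _ = tab.interpolate(t1, t2)
            assert e == pytest.approx(_bilinear_oracle(grid, 10.0, t1, t2),
                                      abs=1e-10)

    def test_periodic_wrap(self):
        rng = np.random.default_rng(2)
        grid = rng.normal(size=(36, 36))
        tab = TorsionGridTable("ALA", "phi-psi", grid, 10.0)
        e_lo, _, _ = tab.interpolate(-180.0, 50.0)
        e_hi, _, _ = tab.interpolate(180.0, 50.0)
        assert e_lo == pytest.approx(e_hi, abs=1e-12)
        # near-seam interpolation stays finite and continuous
        e1, _, _ = tab.interpolate(179.999, 0.0)
        e2, _, _ = tab.interpolate(-179.999, 0.0)
        assert abs(e1 - e2) < 1e-2

    def test_slopes_match_finite_difference(self):
        rng = np.random.default_rng(3)
        grid = rng.normal(size=(36, 36))
        tab = TorsionGridTable("ALA", "phi-psi", grid, 10.0)
        h = 1e-5
        for _ in range(50):
            # stay inside a cell so the piecewise slope is smooth
            t1 = rng.uniform(-179, 179)
            t2 = rng.uniform(-179, 179)
            if min((t1 + 180.0) % 10.0, 10.0 - (t1 + 180.0) % 10.0) < 10 * h:
                continue
            if min((t2 + 180.0) % 10.0, 10.0 - (t2 + 180.0) % 10.0) < 10 * h:
                continue
            _, d1, d2 = tab.interpolate(t1, t2)
            fd1 = (tab.interpolate(t1 + h, t2)[0] - tab.interpolate(t1 - h, t2)[0]) / (2 * h)
            fd2 = (tab.interpolate(t1, t2 + h)[0] - tab.interpolate(t1, t2 - h)[0]) / (2 * h)
            assert d1 == pytest.approx(fd1, abs=1e-6)
            assert d2 == pytest.approx(fd2, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TorsionGridTable("ALA", "phi-psi", np.zeros((10, 10)), 10.0)

    def test_non_finite_rejected(self):
        g = np.zeros((36, 36))
        g[0, 0] = np.nan
        with pytest.raises(ValueError):
            TorsionGridTable("ALA", "phi-psi", g, 10.0)


class TestTableIO:
    def test_round_trip(self, tmp_path):
        tables = generate_synthetic_tables(seed=4, classes=["ALA", "GLY"],
                                           pair_kinds=("phi-psi", "phi-chi1"))
        path = tmp_path / "tables.txt"
        save_tables(tables, str(path))
        back = load_tables(str(path))
        assert set(back) == set(tables)
        for key in tables:
            assert back[key].bin_width == tables[key].bin_width
            assert np.allclose(back[key].grid, tables[key].grid, atol=1e-5)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("NOT_A_TABLE ALA phi-psi 10\n")
        with pytest.raises(ValueError, match="TABLE"):
            load_tables(str(path))

    def test_short_row_rejected(self, tmp_path):
        path = tmp_path / "short.txt"
        path.write_text("TABLE ALA phi-psi 120\n1 2 3\n4 5\n6 7 8\n")
        with pytest.raises(ValueError, match="row"):
            load_tables(str(path))


class TestSyntheticTables:
    def test_well_minimum_at_center_node(self):
        tables = generate_synthetic_tables(wells=[(-60.0, -50.0, 2.0)],
                                           classes=["ALA"])
        tab = tables[("ALA", "phi-psi")]
        i, j = np.unravel_index(np.argmin(tab.grid), tab.grid.shape)
        assert -180.0 + 10.0 * i == pytest.approx(-60.0)
        assert -180.0 + 10.0 * j == pytest.approx(-50.0)
        assert tab.grid[i, j] == pytest.approx(-2.0, abs=1e-12)

    def test_all_classes_and_kinds_generated(self):
        tables = generate_synthetic_tables(seed=0, pair_kinds=PAIR_KINDS)
        assert len(tables) == len(RESIDUE_CLASSES) * len(PAIR_KINDS)

    def test_seed_determinism(self):
        a = generate_synthetic_tables(seed=5, classes=["ALA"])
        b = generate_synthetic_tables(seed=5, classes=["ALA"])
        assert np.array_equal(a[("ALA", "phi-psi")].grid,
                              b[("ALA", "phi-psi")].grid)


def _chain_with_sidechain():
    """Two-residue chain where residue 1 has CG and CD (χ1 and χ2 defined)."""
    def a(serial, name, el, pos, resseq, resname):
        return AtomRecord(serial=serial, name=name, residue_name=resname,
                          chain_id="A", residue_seq=resseq,
                          position=np.array(pos, float), element=el)
    atoms = [
        a(1, "N", "N", [0.0, 0.0, 0.0], 1, "LYS"),
        a(2, "CA", "C", [1.46, 0.0, 0.0], 1, "LYS"),
        a(3, "CB", "C", [2.0, 1.4, 0.3], 1, "LYS"),
        a(4, "CG", "C", [3.5, 1.5, 0.4], 1, "LYS"),
        a(5, "CD", "C", [4.1, 2.9, 0.5], 1, "LYS"),
        a(6, "C", "C", [2.0, -1.2, 0.8], 1, "LYS"),
        a(7, "N", "N", [3.3, -1.3, 0.9], 2, "PRO"),
        a(8, "CA", "C", [4.0, -2.5, 1.2], 2, "PRO"),
        a(9, "C", "C", [5.5, -2.3, 1.4], 2, "PRO"),
    ]
    return StructureModel(atoms=atoms)


class TestTorsionResolution:
    def test_helix_backbone_torsions(self, helix10):
        info = residue_torsion_atoms(helix10)
        assert len(info) == 10
        # terminal residues miss phi (first) / psi (last)
        assert "phi" not in info[0][3] and "psi" in info[0][3]
        assert "psi" not in info[-1][3] and "phi" in info[-1][3]
        coords = helix10.coords()
        for key, rname, _, torsions in info:
            if "phi" in torsions:
                val = dihedral(*(coords[i] for i in torsions["phi"]))
                assert val == pytest.approx(-57.0, abs=1e-6)
            if "psi" in torsions:
                val = dihedral(*(coords[i] for i in torsions["psi"]))
                assert val == pytest.approx(-47.0, abs=1e-6)

    def test_alanine_has_no_chi(self, helix10):
        for _, _, _, torsions in residue_torsion_atoms(helix10):
            assert "chi1" not in torsions and "chi2" not in torsions

    def test_sidechain_chi_and_preproline_flag(self):
        info = residue_torsion_atoms(_chain_with_sidechain())
        key, rname, next_is_pro, torsions = info[0]
        assert rname == "LYS" and next_is_pro
        assert "chi1" in torsions and "chi2" in torsions
        assert not info[1][2]  # PRO itself is not pre-proline


class TestEvaluator:
    def test_energy_at_well_center_is_exact(self):
        # place the well on a grid node matching the builder's exact torsions
        spec = FixtureSpec(n_residues=10, conformation="helix",
                           phi=-60.0, psi=-50.0)
        s = build_polypeptide(spec)
        tables = generate_synthetic_tables(wells=[(-60.0, -50.0, 2.0)],
                                           classes=["ALA"])
        e, forces = torsion_energy(s, tables)
        # residues 2..9 have both phi and psi -> 8 terms at exactly -2.0
        assert e == pytest.approx(-16.0, abs=1e-9)
        assert forces.shape == (len(s.atoms), 3)

    def test_missing_class_is_zero_energy(self, helix10):
        tables = generate_synthetic_tables(seed=0, classes=["GLY"])
        e, forces = torsion_energy(helix10, tables)
        assert e == 0.0
        assert np.all(forces == 0.0)

    def test_forces_match_finite_difference(self, helix10):
        tables = generate_synthetic_tables(seed=0, classes=["ALA"])
        ev = TorsionEvaluator(helix10, tables)
        c = perturb(helix10, 0.3, 5).coords()
        _, f = ev(c)
        rng = np.random.default_rng(6)
        h = 1e-6
        for _ in range(30):
            i = rng.integers(c.shape[0])
            k = rng.integers(3)
            cp = c.copy(); cp[i, k] += h
            cm = c.copy(); cm[i, k] -= h
            fd = -(ev(cp)[0] - ev(cm)[0]) / (2 * h)
            assert f[i, k] == pytest.approx(fd, abs=1e-6)

    def test_deterministic(self, helix10):
        tables = generate_synthetic_tables(seed=0, classes=["ALA"])
        e1, f1 = torsion_energy(helix10, tables)
        e2, f2 = torsion_energy(helix10, tables)
        assert e1 == e2 and np.array_equal(f1, f2)

    def test_energy_lowered_toward_well(self):
        tables = generate_synthetic_tables(wells=[(-60.0, -50.0, 2.0)],
                                           classes=["ALA"])
        at_well = build_polypeptide(FixtureSpec(10, "helix", phi=-60.0, psi=-50.0))
        away = build_polypeptide(FixtureSpec(10, "helix", phi=60.0, psi=120.0))
        e_well, _ = torsion_energy(at_well, tables)
        e_away, _ = torsion_energy(away, tables)
        assert e_well < e_away
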