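"""Refinement engine: base force field, integrators, annealing, width sweep."""

import numpy as np
import pytest

from fbrefine.engine import (ACCEL_UNIT, KB, AnnealSchedule, EnergySystem,
                             _maxwell_velocities, md_run, minimize, sa_refine,
                             total_energy, width_sweep)
from fbrefine.fixtures import FixtureSpec, build_polypeptide, perturb
from fbrefine.forcefield import BaseForceField, infer_bonds
from fbrefine.restraints import build_restraints
from fbrefine.similarity import kabsch_rmsd
from fbrefine.structure import AtomRecord, StructureModel


def _a(serial, name, el, pos, resseq=1):
    return AtomRecord(serial=serial, name=name, residue_name="ALA",
                      chain_id="A", residue_seq=resseq,
                      position=np.array(pos, float), element=el)


def _ch_pair(sep=1.09):
    return StructureModel(atoms=[_a(1, "C", "C", [0, 0, 0]),
                                 _a(2, "H", "H", [sep, 0, 0])])


class TestInferBonds:
    def test_ch_bond_found(self):
        assert infer_bonds(_ch_pair()) == [(0, 1)]

    def test_no_hh_bonds(self):
        s = StructureModel(atoms=[_a(1, "H1", "H", [0, 0, 0]),
                                  _a(2, "H2", "H", [0.8, 0, 0])])
        assert infer_bonds(s) == []

    def test_heavy_heavy_cutoff(self):
        near = StructureModel(atoms=[_a(1, "CA", "C", [0, 0, 0]),
                                     _a(2, "CB", "C", [1.5, 0, 0])])
        far = StructureModel(atoms=[_a(1, "CA", "C", [0, 0, 0]),
                                    _a(2, "CB", "C", [2.5, 0, 0])])
        assert infer_bonds(near) == [(0, 1)]
        assert infer_bonds(far) == []


class TestBaseForceField:
    def test_input_structure_scores_zero(self, helix10):
        ff = BaseForceField(helix10)
        e, forces = ff(helix10.coords())
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(forces).max() < 1e-9

    def test_stretched_bond_energy(self):
        s = _ch_pair(1.0)
        ff = BaseForceField(s)
        c = s.coords()
        c[1, 0] = 1.1  # stretch by 0.1 Å: k_b·0.1² = 300·0.01
        e, forces = ff(c)
        assert e == pytest.approx(3.0, rel=1e-9)
        # restoring force pulls the H back toward the C
        assert forces[1, 0] < 0 < forces[0, 0]

    def test_bent_angle_energy(self):
        s = StructureModel(atoms=[_a(1, "H1", "H", [1.0, 0, 0]),
                                  _a(2, "C", "C", [0, 0, 0]),
                                  _a(3, "H2", "H", [0, 1.0, 0])])
        ff = BaseForceField(s)
        c = s.coords()
        # rotate H2 by 0.1 rad about z: angle becomes pi/2 + 0.1
        t = np.pi / 2 + 0.1
        c[2] = [np.cos(t), np.sin(t), 0.0]
        e, _ = ff(c)
        assert e == pytest.approx(50.0 * 0.1**2, rel=1e-6)

    def test_repulsion_when_nonbonded_atoms_approach(self):
        s = StructureModel(atoms=[_a(1, "CA", "C", [0, 0, 0], 1),
                                  _a(2, "CA", "C", [4.0, 0, 0], 2)])
        with pytest.warns(UserWarning):  # disconnected atoms
            ff = BaseForceField(s)
        c = s.coords()
        c[1, 0] = 3.0  # below the 3.2 Å cap: k_r·(3.2−3.0)²
        e, _ = ff(c)
        assert e == pytest.approx(10.0 * 0.2**2, rel=1e-9)

    def test_net_force_and_torque_vanish(self, helix10, perturbed_helix):
        ff = BaseForceField(helix10)
        c = perturbed_helix.coords()
        _, f = ff(c)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-8)
        torque = np.sum(np.cross(c - c.mean(axis=0), f), axis=0)
        assert np.allclose(torque, 0.0, atol=1e-6)

    def test_forces_match_finite_difference(self, helix10, perturbed_helix):
        ff = BaseForceField(helix10)
        c = perturbed_helix.coords()
        _, f = ff(c)
        rng = np.random.default_rng(3)
        h = 1e-6
        for _ in range(30):
            i = rng.integers(c.shape[0])
            k = rng.integers(3)
            cp = c.copy(); cp[i, k] += h
            cm = c.copy(); cm[i, k] -= h
            fd = -(ff(cp)[0] - ff(cm)[0]) / (2 * h)
            assert f[i, k] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestEnergySystem:
    def test_breakdown_components_sum(self, helix10, rset_shortest):
        tables = __import__("fbrefine.torsiongrid", fromlist=["x"]) \
            .generate_synthetic_tables(seed=0, classes=["ALA"])
        system = EnergySystem.build(helix10, restraint_set=rset_shortest,
                                    w=2.0, stap_tables=tables)
        bd, _ = system(perturb(helix10, 0.3, 1).coords())
        assert bd.e_total == pytest.approx(bd.e_base + bd.e_stap + bd.e_flat)

    def test_source_structure_base_and_flat_are_zero(self, helix10, rset_shortest):
        bd = total_energy(helix10, restraints=rset_shortest, w=0.0)
        assert bd.e_base == pytest.approx(0.0, abs=1e-9)
        assert bd.e_flat == pytest.approx(0.0, abs=1e-9)

    def test_combined_forces_match_finite_difference(self, helix10, rset_shortest,
                                                     perturbed_helix):
        system = EnergySystem.build(helix10, restraint_set=rset_shortest, w=1.0)
        c = perturbed_helix.coords()
        _, f = system(c)
        rng = np.random.default_rng(8)
        h = 1e-6
        for _ in range(20):
            i = rng.integers(c.shape[0])
            k = rng.integers(3)
            cp = c.copy(); cp[i, k] += h
            cm = c.copy(); cm[i, k] -= h
            fd = -(system(cp)[0].e_total - system(cm)[0].e_total) / (2 * h)
            assert f[i, k] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestMinimize:
    def test_recovers_small_perturbation(self, helix10, rset_shortest):
        system = EnergySystem.build(helix10, restraint_set=rset_shortest, w=0.0)
        start = perturb(helix10, 0.1, 11).coords()
        out, bd = minimize(start, system, steps=500)
        e0, _ = system(start)
        assert bd.e_total < 1e-2 < e0.e_total
        assert kabsch_rmsd(helix10.coords(), out) < 0.05

    def test_already_minimal_is_fixed_point(self, helix10):
        system = EnergySystem.build(helix10)
        out, bd = minimize(helix10.coords(), system, steps=50)
        assert bd.e_total == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(out, helix10.coords(), atol=1e-6)


class TestMDRun:
    def test_nve_energy_conservation(self):
        s = _ch_pair(1.09)
        ff = BaseForceField(s)
        system = EnergySystem(base=ff)
        masses = np.array([12.011, 1.008])
        x = s.coords()
        x[1, 0] += 0.02  # small stretch -> oscillation
        v = np.zeros_like(x)

        def etot(x, v):
            bd, _ = system(x)
            ke = 0.5 * float(np.sum(masses[:, None] * v**2)) / ACCEL_UNIT
            return bd.e_total + ke

        e0 = etot(x, v)
        x1, v1, _ = md_run(x, v, masses, system, steps=2000, dt_fs=0.25,
                           target_t=None)
        e1 = etot(x1, v1)
        assert abs(e1 - e0) / max(abs(e0), 1e-12) < 0.01

    def test_thermostat_holds_temperature(self, helix10):
        system = EnergySystem.build(helix10)
        masses = np.array([12.011 if not a.is_hydrogen else 1.008
                           for a in helix10.atoms])
        rng = np.random.default_rng(0)
        v = _maxwell_velocities(rng, masses, 300.0)
        x1, v1, _ = md_run(helix10.coords(), v, masses, system, steps=50,
                           dt_fs=1.0, target_t=300.0)
        ke = 0.5 * float(np.sum(masses[:, None] * v1**2)) / ACCEL_UNIT
        t = 2.0 * ke / (3 * len(masses) * KB)
        assert t == pytest.approx(300.0, rel=1e-6)

    def test_divergence_raises(self):
        s = _ch_pair(1.09)
        system = EnergySystem(base=BaseForceField(s))
        masses = np.array([12.011, 1.008])
        x = s.coords()
        v = np.zeros_like(x)
        v[1] = 1e6
        with pytest.raises(RuntimeError, match="diverged|MD step"):
            md_run(x, v, masses, system, steps=1000, dt_fs=100.0, target_t=None)


class TestAnnealSchedule:
    def test_scaled_divides_md_stages_only(self):
        s = AnnealSchedule().scaled(10.0)
        assert s.heat_steps == 160
        assert s.anneal_steps == 200
        assert s.cool_steps == 400
        assert s.initial_min_steps == 200 and s.final_min_steps == 100

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(anneal_steps=-1)
        with pytest.raises(ValueError):
            AnnealSchedule(anneal_t=0.0)


def _quick_schedule(seed=0):
    return AnnealSchedule(seed=seed).scaled(40.0)


class TestSARefine:
    def test_lowers_restraint_energy_and_rmsd(self, helix10, rset_shortest):
        system = EnergySystem.build(helix10, restraint_set=rset_shortest, w=0.0)
        start = perturb(helix10, 0.8, 7)
        result = sa_refine(start, _quick_schedule(), system)
        assert result.final.e_flat < result.initial.e_flat
        rmsd0 = kabsch_rmsd(helix10.coords(), start.coords())
        rmsd1 = kabsch_rmsd(helix10.coords(), result.refined.coords())
        assert rmsd1 < rmsd0

    def test_deterministic_given_seed(self, helix10, rset_shortest):
        start = perturb(helix10, 0.8, 7)
        outs = []
        for _ in range(2):
            system = EnergySystem.build(helix10, restraint_set=rset_shortest, w=0.0)
            outs.append(sa_refine(start, _quick_schedule(seed=3), system))
        assert np.array_equal(outs[0].refined.coords(), outs[1].refined.coords())

    def test_trace_and_width_recorded(self, helix10, rset_shortest):
        system = EnergySystem.build(helix10, restraint_set=rset_shortest, w=2.0)
        result = sa_refine(perturb(helix10, 0.5, 1), _quick_schedule(), system)
        assert result.width == 2.0
        assert len(result.energy_trace) >= 3
        assert result.initial is result.energy_trace[0]
        assert result.final is result.energy_trace[-1]


class TestWidthSweep:
    def test_returns_one_result_per_width_and_best(self, helix10, rset_shortest):
        def scorer(result):
            # deterministic toy score: prefer low final restraint energy
            return -result.final.e_flat, {"e_flat": result.final.e_flat}

        results, best = width_sweep(helix10, [0.0, 4.0], _quick_schedule(),
                                    restraint_set=rset_shortest, scorer=scorer)
        assert [r.width for r in results] == [0.0, 4.0]
        assert best in (0, 1)
        assert all(r.total_score is not None for r in results)

    def test_tie_prefers_smaller_width(self, helix10, rset_shortest):
        results, best = width_sweep(helix10, [4.0, 0.0],
                                    _quick_schedule(), restraint_set=rset_shortest,
                                    scorer=lambda r: (1.0, {}))
        assert results[best].width == 0.0

    def test_no_scorer_gives_no_best(self, helix10, rset_shortest):
        results, best = width_sweep(helix10, [0.0],
                                    _quick_schedule(), restraint_set=rset_shortest)
        assert best is None and len(results) == 1

    def test_empty_widths_rejected(self, helix10):
        with pytest.raises(ValueError):
            width_sweep(helix10, [], _quick_schedule())
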