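"""Minimal self-parameterized base force field.

The refinement needs a base energy that keeps covalent geometry and sterics
sane while the restraint and torsion-grid terms do the real work.  Rather
than a transferable force field, this provider parameterizes itself on the
input structure: harmonic bonds and angles take their reference values from
the input geometry (so the unperturbed input has exactly zero base energy and
force), plus a soft-core repulsion that switches on when non-bonded heavy
atoms approach closer than they were in the input (capped at 3.2 Å).

It is a pluggable provider: anything callable as ``coords -> (energy,
forces)`` can replace it in the refinement engine.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import StructureModel

__all__ = ["BaseForceField", "base_forcefield", "infer_bonds"]

H_HEAVY_CUTOFF = 1.2   # Å
HEAVY_HEAVY_CUTOFF = 1.9  # Å
REPULSION_RADIUS = 3.2  # Å

DEFAULT_K_BOND = 300.0   # kcal/mol/Å²
DEFAULT_K_ANGLE = 50.0   # kcal/mol/rad²
DEFAULT_K_REP = 10.0     # kcal/mol/Å²


def infer_bonds(structure: StructureModel) -> list[tuple[int, int]]:
    """Distance-based bond perception: H–heavy ≤ 1.2 Å, heavy–heavy ≤ 1.9 Å."""
    coords = structure.coords()
    n = len(structure.atoms)
    is_h = np.array([a.is_hydrogen for a in structure.atoms])
    dmat = squareform(pdist(coords))
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            if is_h[i] and is_h[j]:
                continue
            cut = H_HEAVY_CUTOFF if (is_h[i] or is_h[j]) else HEAVY_HEAVY_CUTOFF
            if dmat[i, j] <= cut:
                bonds.append((i, j))
    return bonds


class BaseForceField:
    """Harmonic bonds/angles at input values + soft-core heavy-atom repulsion.

    Bond term k_b·(r−r0)², angle term k_a·(θ−θ0)² with r0/θ0 taken from the
    input structure; repulsion k_r·(r_c−r)² for non-bonded (and non-1-3)
    heavy-atom pairs below their pair-specific radius r_c = min(3.2 Å,
    input distance), so the input structure itself scores exactly zero.
    Deterministic given the structure.
    """

    def __init__(self, structure: StructureModel, k_bond: float = DEFAULT_K_BOND,
                 k_angle: float = DEFAULT_K_ANGLE, k_rep: float = DEFAULT_K_REP,
                 repulsion_radius: float = REPULSION_RADIUS):
        coords = structure.coords()
        self.n_atoms = len(structure.atoms)
        self.k_bond, self.k_angle, self.k_rep = k_bond, k_angle, k_rep

        self.bonds = infer_bonds(structure)
        neighbours: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.bonds:
            neighbours[i].add(j)
            neighbours[j].add(i)
        for i, nb in neighbours.items():
            if not nb:
                a = structure.atoms[i]
                warnings.warn(
                    f"atom {a.chain_id}/{a.residue_seq}/{a.name} has no inferred "
                    "bonds; repulsion-only")

        self.bond_idx = np.array(self.bonds, dtype=int).reshape(-1, 2)
        self.bond_r0 = np.linalg.norm(
            coords[self.bond_idx[:, 0]] - coords[self.bond_idx[:, 1]], axis=1
        ) if len(self.bonds) else np.zeros(0)

        angles = []
        for j, nb in neighbours.items():
            nb_sorted = sorted(nb)
            for a in range(len(nb_sorted)):
                for b in range(a + 1, len(nb_sorted)):
                    angles.append((nb_sorted[a], j, nb_sorted[b]))
        self.angle_idx = np.array(angles, dtype=int).reshape(-1, 3)
        self.angle_t0 = self._angles(coords) if len(angles) else np.zeros(0)

        # heavy-atom pairs eligible for repulsion: not bonded, not 1-3
        heavy = [i for i, a in enumerate(structure.atoms) if not a.is_hydrogen]
        excluded = {tuple(sorted(b)) for b in self.bonds}
        excluded |= {tuple(sorted((a, c))) for a, j, c in angles}
        rep_i, rep_j, rep_rc = [], [], []
        for ai in range(len(heavy)):
            for bi in range(ai + 1, len(heavy)):
                i, j = heavy[ai], heavy[bi]
                if (i, j) in excluded:
                    continue
                d0 = float(np.linalg.norm(coords[i] - coords[j]))
                rep_i.append(i)
                rep_j.append(j)
                rep_rc.append(min(repulsion_radius, d0))
        self.rep_i = np.array(rep_i, dtype=int)
        self.rep_j = np.array(rep_j, dtype=int)
        self.rep_rc = np.array(rep_rc)

    def _angles(self, coords: np.ndarray) -> np.ndarray:
        a = coords[self.angle_idx[:, 0]]
        b = coords[self.angle_idx[:, 1]]
        c = coords[self.angle_idx[:, 2]]
        u = a - b
        v = c - b
        cosang = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        return np.arccos(np.clip(cosang, -1.0, 1.0))

    def __call__(self, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        forces = np.zeros_like(coords)
        e = 0.0

        if len(self.bond_idx):
            i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
            diff = coords[i] - coords[j]
            r = np.linalg.norm(diff, axis=1)
            dr = r - self.bond_r0
            e += float(self.k_bond * np.sum(dr**2))
            coef = (2.0 * self.k_bond * dr / np.maximum(r, 1e-12))[:, None]
            fvec = coef * diff
            np.subtract.at(forces, i, fvec)
            np.add.at(forces, j, fvec)

        if len(self.angle_idx):
            ia, ij, ic = self.angle_idx[:, 0], self.angle_idx[:, 1], self.angle_idx[:, 2]
            u = coords[ia] - coords[ij]
            v = coords[ic] - coords[ij]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cosang = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            theta = np.arccos(cosang)
            sin = np.sqrt(np.maximum(1.0 - cosang**2, 1e-12))
            dt = theta - self.angle_t0
            e += float(self.k_angle * np.sum(dt**2))
            dU = 2.0 * self.k_angle * dt
            ga = (cosang[:, None] * uh - vh) / (nu * sin)[:, None]
            gc = (cosang[:, None] * vh - uh) / (nv * sin)[:, None]
            np.add.at(forces, ia, -dU[:, None] * ga)
            np.add.at(forces, ic, -dU[:, None] * gc)
            np.add.at(forces, ij, dU[:, None] * (ga + gc))

        if len(self.rep_i):
            diff = coords[self.rep_i] - coords[self.rep_j]
            r = np.linalg.norm(diff, axis=1)
            pen = self.rep_rc - r
            active = pen > 0
            if np.any(active):
                e += float(self.k_rep * np.sum(pen[active] ** 2))
                coef = np.zeros_like(r)
                coef[active] = -2.0 * self.k_rep * pen[active] / np.maximum(r[active], 1e-12)
                fvec = coef[:, None] * diff
                np.subtract.at(forces, self.rep_i, fvec)
                np.add.at(forces, self.rep_j, fvec)

        return e, forces


def base_forcefield(structure: StructureModel, **stiffness) -> BaseForceField:
    """Build the self-parameterized base energy/force provider."""
    return BaseForceField(structure, **stiffness)
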