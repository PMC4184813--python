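"""Synthetic polypeptide fixtures: ideal-geometry poly-alanine with hydrogens.

Structures are grown from internal coordinates (NeRF chain extension) at a
chosen φ/ψ, so every stage of the pipeline — grouping, restraints, energy,
annealing, scoring — is testable without downloading anything.  Seeded
Gaussian perturbation emulates the coordinate noise the refinement is meant
to clean up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import AtomRecord, StructureModel

__all__ = ["FixtureSpec", "build_polypeptide", "perturb", "CONFORMATIONS"]

# ideal bond lengths (Å) and angles (deg) for a peptide backbone
_B = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "CA-CB": 1.521, "N-H": 1.010, "CA-HA": 1.090, "CB-HB": 1.090,
}
_A = {
    "N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
    "CA-C-O": 120.8, "C-N-H": 119.0, "CA-CB-HB": 109.5,
}

CONFORMATIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "extended": (-180.0, 180.0),
}


@dataclass
class FixtureSpec:
    n_residues: int = 10
    conformation: str = "helix"
    phi: float | None = None
    psi: float | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.conformation not in CONFORMATIONS:
            raise ValueError(
                f"unsupported conformation {self.conformation!r}; "
                f"choose from {sorted(CONFORMATIONS)}")
        if self.phi is None:
            self.phi = CONFORMATIONS[self.conformation][0]
        if self.psi is None:
            self.psi = CONFORMATIONS[self.conformation][1]


def _nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A, B, C with |C−D|, ∠(B,C,D) and dihedral(A,B,C,D)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_polypeptide(spec: FixtureSpec) -> StructureModel:
    """Poly-alanine at the requested φ/ψ with HN/HA/HB1-3 hydrogens.

    Backbone torsions are exact by construction; ω is 180° (trans).  The
    optional Gaussian noise is applied after the ideal build.
    """
    n_res = spec.n_residues
    phi, psi, omega = spec.phi, spec.psi, 180.0

    # backbone N-CA-C chain
    bb: list[list[np.ndarray]] = []  # bb[i] = [N, CA, C]
    n0 = np.zeros(3)
    ca0 = np.array([_B["N-CA"], 0.0, 0.0])
    ang = np.radians(_A["N-CA-C"])
    c0 = ca0 + _B["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    bb.append([n0, ca0, c0])
    for i in range(1, n_res):
        pn, pca, pc = bb[i - 1]
        n = _nerf(pn, pca, pc, _B["C-N"], _A["CA-C-N"], psi)
        ca = _nerf(pca, pc, n, _B["N-CA"], _A["C-N-CA"], omega)
        c = _nerf(pc, n, ca, _B["CA-C"], _A["N-CA-C"], phi)
        bb.append([n, ca, c])

    atoms: list[AtomRecord] = []
    serial = 0

    def add(name: str, pos: np.ndarray, resseq: int, element: str) -> None:
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(serial=serial, name=name, residue_name="ALA",
                                chain_id="A", residue_seq=resseq,
                                position=pos, element=element))

    for i in range(n_res):
        n, ca, c = bb[i]
        resseq = i + 1
        add("N", n, resseq, "N")
        if i > 0:
            # amide H anti to the carbonyl O across the peptide plane
            h = _nerf(bb[i - 1][1], bb[i - 1][2], n, _B["N-H"], _A["C-N-H"], 0.0)
            add("H", h, resseq, "H")
        add("CA", ca, resseq, "C")
        # HA and CB complete the tetrahedron around CA with N and C
        u_n = (n - ca) / np.linalg.norm(n - ca)
        u_c = (c - ca) / np.linalg.norm(c - ca)
        bisec = -(u_n + u_c)
        bisec /= np.linalg.norm(bisec)
        perp = np.cross(u_c, u_n)
        perp /= np.linalg.norm(perp)
        half = np.radians(108.7 / 2.0)  # HA-CA-CB split around the bisector
        # L-amino acid: CB on the +perp side (CORN rule)
        cb = ca + _B["CA-CB"] * (np.cos(half) * bisec + np.sin(half) * perp)
        ha = ca + _B["CA-HA"] * (np.cos(half) * bisec - np.sin(half) * perp)
        add("HA", ha, resseq, "H")
        add("CB", cb, resseq, "C")
        for k, chi in enumerate((60.0, 180.0, 300.0), start=1):
            hb = _nerf(n, ca, cb, _B["CB-HB"], _A["CA-CB-HB"], chi)
            add(f"HB{k}", hb, resseq, "H")
        add("C", c, resseq, "C")
        if i + 1 < n_res:
            o = _nerf(n, ca, c, _B["C-O"], _A["CA-C-O"], psi + 180.0)
        else:
            o = _nerf(n, ca, c, _B["C-O"], _A["CA-C-O"], psi + 180.0)
        add("O", o, resseq, "O")

    structure = StructureModel(atoms=atoms)
    if spec.noise_sigma > 0:
        structure = perturb(structure, spec.noise_sigma, spec.seed)
    return structure


def perturb(structure: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Add zero-mean Gaussian noise (std ``sigma`` Å per coordinate), seeded."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return structure.with_coords(structure.coords())
    rng = np.random.default_rng(seed)
    coords = structure.coords()
    return structure.with_coords(coords + rng.normal(0.0, sigma, size=coords.shape))
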