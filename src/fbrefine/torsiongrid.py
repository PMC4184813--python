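"""Knowledge-based torsion-angle grid potential (STAP-style evaluation).

Per-residue-class 2D energy tables over torsion-angle pairs — φ-ψ, φ-χ1,
ψ-χ1 and χ1-χ2 — are evaluated by periodic bilinear interpolation at each
residue's current torsions and summed; forces follow by the chain rule
through the analytic dihedral gradient.  There are 21 residue classes: the
20 standard amino acids plus pre-proline (a residue whose successor is
proline, which has distinct backbone statistics).

Tables are consumed, not derived: a plain-text loader reads them, and a
synthetic-table generator builds smooth periodic surfaces with known minima
so the evaluator is testable without any external statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import StructureModel, dihedral_gradient

logger = logging.getLogger(__name__)

__all__ = [
    "TorsionGridTable",
    "load_tables",
    "save_tables",
    "generate_synthetic_tables",
    "torsion_energy",
    "residue_torsion_atoms",
    "RESIDUE_CLASSES",
    "PAIR_KINDS",
]

AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
RESIDUE_CLASSES = AMINO_ACIDS + ["PREPRO"]
PAIR_KINDS = ("phi-psi", "phi-chi1", "psi-chi1", "chi1-chi2")

# first side-chain torsion atom beyond CB / CG per residue type (common cases)
_CHI1_G = ("CG", "CG1", "OG", "OG1", "SG")
_CHI2_D = ("CD", "CD1", "SD", "OD1", "ND1")


@dataclass
class TorsionGridTable:
    """One 2D periodic energy surface on a uniform angular lattice.

    grid[i, j] is the energy at (−180 + i·bin_width, −180 + j·bin_width);
    the lattice wraps at 360° in both directions.
    """

    residue_class: str
    pair_kind: str
    grid: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        n = int(round(360.0 / self.bin_width))
        if self.grid.shape != (n, n):
            raise ValueError(
                f"{self.residue_class}/{self.pair_kind}: grid shape {self.grid.shape} "
                f"inconsistent with bin width {self.bin_width}° (expected {(n, n)})")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError(f"{self.residue_class}/{self.pair_kind}: non-finite grid values")

    def interpolate(self, t1: float, t2: float):
        """Bilinear periodic interpolation; returns (E, dE/dt1, dE/dt2) per degree."""
        n = self.grid.shape[0]
        u = (t1 + 180.0) / self.bin_width
        v = (t2 + 180.0) / self.bin_width
        i0 = int(np.floor(u)) % n
        j0 = int(np.floor(v)) % n
        fu = u - np.floor(u)
        fv = v - np.floor(v)
        i1 = (i0 + 1) % n
        j1 = (j0 + 1) % n
        g = self.grid
        e00, e01, e10, e11 = g[i0, j0], g[i0, j1], g[i1, j0], g[i1, j1]
        e = ((1 - fu) * (1 - fv) * e00 + (1 - fu) * fv * e01
             + fu * (1 - fv) * e10 + fu * fv * e11)
        de_du = ((1 - fv) * (e10 - e00) + fv * (e11 - e01)) / self.bin_width
        de_dv = ((1 - fu) * (e01 - e00) + fu * (e11 - e10)) / self.bin_width
        return float(e), float(de_du), float(de_dv)


# ---------------------------------------------------------------------------
# Table file format: blocks of
#   TABLE <class> <pair_kind> <bin_width>
#   <n rows of n whitespace-separated values>

def save_tables(tables: dict, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# torsion grid tables: TABLE <class> <pair-kind> <bin-width>\n")
        for (cls, kind), tab in sorted(tables.items()):
            fh.write(f"TABLE {cls} {kind} {tab.bin_width:g}\n")
            for row in tab.grid:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def load_tables(path: str) -> dict:
    """Load grid tables keyed by (residue_class, pair_kind).

    Classes absent from the file simply evaluate to zero later (a warning is
    logged per missing class at evaluation time).
    """
    tables: dict = {}
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("TABLE"):
            raise ValueError(f"{path}: expected TABLE header, got {line!r}")
        _, cls, kind, bw = line.split()
        bw = float(bw)
        n = int(round(360.0 / bw))
        rows = []
        for k in range(n):
            vals = lines[i].split()
            if len(vals) != n:
                raise ValueError(
                    f"{path}: table {cls}/{kind} row {k} has {len(vals)} values, expected {n}")
            rows.append([float(v) for v in vals])
            i += 1
        tables[(cls, kind)] = TorsionGridTable(cls, kind, np.array(rows), bw)
    return tables


def generate_synthetic_tables(seed: int = 0, wells=None, classes=None,
                              pair_kinds=("phi-psi",), bin_width: float = 10.0,
                              kappa: float = 2.0) -> dict:
    """Smooth periodic test surfaces: sums of von Mises wells with known minima.

    ``wells`` is a list of (center1°, center2°, depth) shared by every table,
    or None to draw 2 random wells per table from ``seed``.  Each well
    contributes −depth·exp(κ(cos Δ1 − 1))·exp(κ(cos Δ2 − 1)), so an isolated
    well's minimum sits exactly at its center with energy ≈ −depth.
    """
    rng = np.random.default_rng(seed)
    classes = list(classes) if classes is not None else RESIDUE_CLASSES
    n = int(round(360.0 / bin_width))
    axis = -180.0 + bin_width * np.arange(n)
    t1, t2 = np.meshgrid(axis, axis, indexing="ij")
    tables = {}
    for cls in classes:
        for kind in pair_kinds:
            ws = wells
            if ws is None:
                ws = [(rng.uniform(-180, 180), rng.uniform(-180, 180),
                       rng.uniform(1.0, 3.0)) for _ in range(2)]
            grid = np.zeros((n, n))
            for c1, c2, depth in ws:
                grid -= depth * np.exp(
                    kappa * (np.cos(np.radians(t1 - c1)) - 1.0)
                ) * np.exp(kappa * (np.cos(np.radians(t2 - c2)) - 1.0))
            tables[(cls, kind)] = TorsionGridTable(cls, kind, grid, bin_width)
    return tables


# ---------------------------------------------------------------------------
# Structure evaluation

def _residues_in_order(structure: StructureModel):
    """Ordered (chain, resseq) residue list with atom-name → index maps."""
    residues: list[tuple[tuple[str, int], str, dict]] = []
    seen: dict[tuple[str, int], dict] = {}
    for idx, a in enumerate(structure.atoms):
        key = (a.chain_id, a.residue_seq)
        if key not in seen:
            seen[key] = {}
            residues.append((key, a.residue_name, seen[key]))
        seen[key].setdefault(a.name, idx)
    return residues


def residue_torsion_atoms(structure: StructureModel):
    """Per residue: class name and atom-index quadruples for φ/ψ/χ1/χ2.

    φ needs the previous residue's C, ψ the next residue's N; a torsion whose
    atoms are incomplete is simply absent from the dict.  Residue class is
    the residue name, except GLY side-chain torsions (none) and the
    pre-proline override applied by the caller.
    """
    residues = _residues_in_order(structure)
    out = []
    for ridx, (key, rname, amap) in enumerate(residues):
        torsions: dict[str, tuple[int, int, int, int]] = {}
        prev_amap = residues[ridx - 1][2] if ridx > 0 and \
            residues[ridx - 1][0][0] == key[0] else None
        next_entry = residues[ridx + 1] if ridx + 1 < len(residues) and \
            residues[ridx + 1][0][0] == key[0] else None
        n, ca, c, cb = (amap.get(x) for x in ("N", "CA", "C", "CB"))
        if prev_amap is not None and prev_amap.get("C") is not None and \
                None not in (n, ca, c):
            torsions["phi"] = (prev_amap["C"], n, ca, c)
        if next_entry is not None and next_entry[2].get("N") is not None and \
                None not in (n, ca, c):
            torsions["psi"] = (n, ca, c, next_entry[2]["N"])
        g = next((amap[x] for x in _CHI1_G if x in amap), None)
        if None not in (n, ca, cb) and g is not None:
            torsions["chi1"] = (n, ca, cb, g)
            d = next((amap[x] for x in _CHI2_D if x in amap), None)
            if d is not None:
                torsions["chi2"] = (ca, cb, g, d)
        next_is_pro = next_entry is not None and next_entry[1] == "PRO"
        out.append((key, rname, next_is_pro, torsions))
    return out


_PAIR_TO_TORSIONS = {
    "phi-psi": ("phi", "psi"),
    "phi-chi1": ("phi", "chi1"),
    "psi-chi1": ("psi", "chi1"),
    "chi1-chi2": ("chi1", "chi2"),
}

class TorsionEvaluator:
    """Pre-resolved grid-potential terms, evaluated on bare coordinates.

    Resolves every (residue, pair-kind) term with an available table to the
    four atom indices of each contributing dihedral once, so the annealing
    loop can call it on plain (N, 3) arrays.
    """

    def __init__(self, structure: StructureModel, tables: dict,
                 pre_proline_rule: bool = True):
        self.n_atoms = len(structure.atoms)
        # terms: (table, idx quadruple of torsion 1, idx quadruple of torsion 2)
        self.terms: list[tuple[TorsionGridTable, tuple, tuple]] = []
        warned: set = set()
        for key, rname, next_is_pro, torsions in residue_torsion_atoms(structure):
            cls = "PREPRO" if (pre_proline_rule and next_is_pro) else rname
            if not any(k[0] == cls for k in tables) and cls not in warned:
                warned.add(cls)
                logger.warning("no torsion tables for residue class %s; zero energy", cls)
            for kind in PAIR_KINDS:
                tab = tables.get((cls, kind))
                if tab is None:
                    continue
                name1, name2 = _PAIR_TO_TORSIONS[kind]
                if name1 not in torsions or name2 not in torsions:
                    logger.debug("residue %s: torsion atoms for %s missing; term skipped",
                                 key, kind)
                    continue
                self.terms.append((tab, torsions[name1], torsions[name2]))

    def __call__(self, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        forces = np.zeros_like(coords)
        total = 0.0
        cache: dict[tuple, tuple] = {}
        for tab, idx1, idx2 in self.terms:
            for idx in (idx1, idx2):
                if idx not in cache:
                    cache[idx] = dihedral_gradient(*(coords[i] for i in idx))
            t1, g1 = cache[idx1]
            t2, g2 = cache[idx2]
            e, de_dt1, de_dt2 = tab.interpolate(t1, t2)
            total += e
            # dE/dx = dE/dθ° · (180/π) · dθ_rad/dx
            for idx, grads, de in ((idx1, g1, de_dt1), (idx2, g2, de_dt2)):
                c = de * 180.0 / np.pi
                for atom_i, gvec in zip(idx, grads):
                    forces[atom_i] -= c * gvec
        return total, forces


def torsion_energy(structure: StructureModel, tables: dict,
                   pre_proline_rule: bool = True):
    """Total grid-potential energy and per-atom forces for a structure.

    For every residue and every pair kind with a table for the residue's
    class, the table is interpolated at the current torsion pair; forces
    propagate through both dihedrals' analytic gradients.  Missing torsion
    atoms skip the term (debug log).
    """
    return TorsionEvaluator(structure, tables, pre_proline_rule)(structure.coords())
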