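"""Coordinate data model, PDB I/O, hydrogen-equivalence grouping and geometry.

The refinement operates on plain coordinate arrays; this module provides the
atom bookkeeping around them: parsing/writing PDB files (via gemmi), grouping
chemically equivalent hydrogens (methyl, methylene) under their bonded heavy
atom, and the signed-dihedral primitive consumed by the torsion potential.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "HydrogenGroup",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "find_hydrogen_groups",
    "dihedral",
]


class PDBParseError(ValueError):
    """Raised for malformed coordinate records; message names the line."""


_ELEMENT_FROM_NAME = {
    "H": "H", "C": "C", "N": "N", "O": "O", "S": "S", "P": "P",
}


def _infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name (column-aligned or not)."""
    stripped = atom_name.strip()
    if not stripped:
        return ""
    # digits may prefix hydrogen names like 1HB2
    for ch in stripped:
        if ch.isalpha():
            return _ELEMENT_FROM_NAME.get(ch.upper(), ch.upper())
    return ""


@dataclass
class AtomRecord:
    """One atom: identity plus a Cartesian position in Å."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    position: np.ndarray
    element: str
    model_index: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(
                f"atom {self.name} serial {self.serial}: position must be a finite 3-vector"
            )
        if not self.element:
            self.element = _infer_element(self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def key(self) -> tuple:
        return (self.chain_id, self.residue_seq, self.name, self.model_index)


@dataclass
class StructureModel:
    """An ordered collection of atoms, possibly spanning several NMR models."""

    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def models(self) -> int:
        return len({a.model_index for a in self.atoms}) if self.atoms else 0

    def model(self, index: int = 1) -> "StructureModel":
        """Return the sub-structure holding coordinate model ``index``."""
        sel = [a for a in self.atoms if a.model_index == index]
        if not sel:
            raise KeyError(f"model {index} not present (models: {sorted({a.model_index for a in self.atoms})})")
        return StructureModel(atoms=sel)

    def sequence(self) -> dict[str, list[tuple[int, str]]]:
        """Per-chain ordered list of (residue_seq, residue_name) for model 1 atoms."""
        first = min(a.model_index for a in self.atoms) if self.atoms else 1
        seq: dict[str, list[tuple[int, str]]] = {}
        for a in self.atoms:
            if a.model_index != first:
                continue
            entry = (a.residue_seq, a.residue_name)
            chain = seq.setdefault(a.chain_id, [])
            if not chain or chain[-1] != entry:
                if entry not in chain:
                    chain.append(entry)
        return seq

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of the structure with positions replaced (same atom roster)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coords of shape {(len(self.atoms), 3)}, got {coords.shape}")
        return StructureModel(
            atoms=[replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        )

    def find_atom(self, chain_id: str, residue_seq: int, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_seq == residue_seq and a.name == name:
                return a
        raise KeyError(f"atom {chain_id}/{residue_seq}/{name} not found")

    def validate(self) -> None:
        keys = [a.key() for a in self.atoms]
        if len(keys) != len(set(keys)):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom identifier {dup}")


@dataclass
class HydrogenGroup:
    """Chemically equivalent hydrogens bonded to one heavy atom.

    Methyl hydrogens form a size-3 group, methylene size-2, all other
    hydrogens size-1.  ``orphan`` marks a hydrogen with no heavy atom
    within the bonding cutoff.
    """

    heavy_atom: AtomRecord | None
    hydrogens: list[AtomRecord]
    group_id: str
    orphan: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.hydrogens) <= 3:
            raise ValueError(f"group {self.group_id}: size must be 1-3, got {len(self.hydrogens)}")

    @property
    def size(self) -> int:
        return len(self.hydrogens)


# ---------------------------------------------------------------------------
# PDB I/O

def _prevalidate_pdb(path: str) -> None:
    """Check ATOM/HETATM coordinate fields so errors can name the line."""
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n_atoms += 1
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"line {lineno}: coordinate record too short")
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fld = line[lo:hi]
                    try:
                        float(fld)
                    except ValueError:
                        raise PDBParseError(
                            f"line {lineno}: malformed {what} coordinate field {fld!r}"
                        ) from None
    if n_atoms == 0:
        raise PDBParseError(f"{path}: no ATOM records found")


def read_pdb(path: str, model_selector: int | str = "all",
             keep_hetatm: bool = False) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM record; hydrogens expected for the
        restraint stages but not required here.
    model_selector:
        ``"all"`` to keep every MODEL block, or a 1-based model index.
    keep_hetatm:
        Keep non-water HETATM records.  Water is always skipped.

    Alternate locations other than '' / 'A' are dropped; occupancy is ignored.
    """
    _prevalidate_pdb(path)
    st = gemmi.read_pdb(str(path))
    atoms: list[AtomRecord] = []
    serial = 0
    for mi, model in enumerate(st, start=1):
        if model_selector != "all" and mi != int(model_selector):
            continue
        for chain in model:
            for res in chain:
                if res.is_water():
                    continue
                if res.het_flag == "H" and not keep_hetatm:
                    continue
                for atom in res:
                    if atom.altloc not in ("", "\0", "A"):
                        continue
                    serial += 1
                    atoms.append(AtomRecord(
                        serial=serial,
                        name=atom.name,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_seq=res.seqid.num,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        element=atom.element.name if atom.element.name != "X" else "",
                        model_index=mi,
                    ))
    if model_selector != "all" and not atoms:
        raise KeyError(f"model {model_selector} not present in {path}")
    out = StructureModel(atoms=atoms)
    out.validate()
    return out


def write_pdb(structure: StructureModel, path: str,
              force_model_records: bool = False) -> None:
    """Write standard fixed-column ATOM records (coordinates %8.3f).

    MODEL/ENDMDL records are emitted only for multi-model structures unless
    ``force_model_records`` is set.
    """
    if not structure.atoms:
        raise ValueError("cannot write an empty structure")
    st = gemmi.Structure()
    st.name = "fbrefine"
    model_indices = sorted({a.model_index for a in structure.atoms})
    for mi in model_indices:
        model = gemmi.Model(mi)
        chains: dict[str, gemmi.Chain] = {}
        for a in structure.atoms:
            if a.model_index != mi:
                continue
            if a.chain_id not in chains:
                chains[a.chain_id] = gemmi.Chain(a.chain_id)
            chain = chains[a.chain_id]
            if (len(chain) == 0 or chain[-1].seqid.num != a.residue_seq
                    or chain[-1].name != a.residue_name):
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_seq, " ")
                chain.add_residue(res)
            res = chain[-1]
            atom = gemmi.Atom()
            atom.name = a.name
            atom.pos = gemmi.Position(*a.position)
            atom.element = gemmi.Element(a.element or _infer_element(a.name))
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    # entity heuristics can demote short synthetic chains to HETATM; these
    # are coordinate models, so always emit ATOM records
    for model in st:
        for chain in model:
            for res in chain:
                res.het_flag = "A"
    multi = len(model_indices) > 1 or force_model_records
    opts = gemmi.PdbWriteOptions(minimal=True)
    doc = st.make_pdb_string(opts)
    if not multi:
        doc = "\n".join(l for l in doc.splitlines()
                        if not l.startswith(("MODEL", "ENDMDL"))) + "\n"
    with open(path, "w") as fh:
        fh.write(doc)


# ---------------------------------------------------------------------------
# Hydrogen grouping

def find_hydrogen_groups(structure: StructureModel,
                         bond_cutoff: float = 1.2) -> list[HydrogenGroup]:
    """Partition the structure's hydrogens into equivalence groups.

    Each hydrogen attaches to the nearest heavy atom within ``bond_cutoff``
    (distance-based bonding, so arbitrary or synthetic inputs work without
    name templates); hydrogens sharing a heavy atom form one group.
    Hydrogens with no heavy atom in range become singleton groups flagged
    ``orphan`` with a warning.
    """
    hydrogens = [a for a in structure.atoms if a.is_hydrogen]
    heavies = [a for a in structure.atoms if not a.is_hydrogen]
    groups: list[HydrogenGroup] = []
    if not hydrogens:
        return groups
    by_heavy: dict[int, list[AtomRecord]] = {}
    orphans: list[AtomRecord] = []
    if heavies:
        hpos = np.array([a.position for a in heavies])
        for h in hydrogens:
            dist = np.linalg.norm(hpos - h.position, axis=1)
            j = int(np.argmin(dist))
            if dist[j] <= bond_cutoff:
                by_heavy.setdefault(j, []).append(h)
            else:
                orphans.append(h)
    else:
        orphans = list(hydrogens)
    for j in sorted(by_heavy):
        heavy = heavies[j]
        hs = sorted(by_heavy[j], key=lambda a: a.name)
        gid = f"{heavy.chain_id}/{heavy.residue_seq}/{heavy.name}"
        if len(hs) > 3:  # spurious close contacts; keep chemically sane sizes
            warnings.warn(f"{gid}: {len(hs)} hydrogens within {bond_cutoff} Å; splitting")
            for h in hs[3:]:
                orphans.append(h)
            hs = hs[:3]
        groups.append(HydrogenGroup(heavy_atom=heavy, hydrogens=hs, group_id=gid))
    for h in orphans:
        gid = f"{h.chain_id}/{h.residue_seq}/{h.name}(orphan)"
        warnings.warn(f"hydrogen {gid} has no heavy atom within {bond_cutoff} Å")
        groups.append(HydrogenGroup(heavy_atom=None, hydrogens=[h], group_id=gid, orphan=True))
    groups.sort(key=lambda g: g.group_id)
    return groups


# ---------------------------------------------------------------------------
# Geometry

def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees on (−180, 180], IUPAC convention.

    Looking down the p2→p3 axis, the angle is positive for a clockwise
    rotation carrying p1 onto p4; planar-cis is 0°.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * max(np.linalg.norm(b1) * nb2, 1e-30) or \
       np.linalg.norm(n2) < 1e-10 * max(np.linalg.norm(b3) * nb2, 1e-30):
        raise ValueError("dihedral undefined: three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedral_gradient(p1, p2, p3, p4):
    """Analytic gradient of the dihedral (in radians) w.r.t. the four points.

    Returns (value_degrees, (g1, g2, g3, g4)) where each g is dφ/dp in
    radians per Å.  Uses the standard normal-vector formulas, which are
    exact away from collinear degeneracies.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    if n1sq < 1e-20 or n2sq < 1e-20:
        raise ValueError("dihedral gradient undefined: collinear points")
    g1 = -nb2 / n1sq * n1
    g4 = nb2 / n2sq * n2
    s12 = float(np.dot(b1, b2)) / nb2**2
    s32 = float(np.dot(b3, b2)) / nb2**2
    g2 = -(1.0 + s12) * g1 + s32 * g4
    g3 = s12 * g1 - (1.0 + s32) * g4
    return dihedral(p1, p2, p3, p4), (g1, g2, g3, g4)
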