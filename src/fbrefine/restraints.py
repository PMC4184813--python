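"""Distance-restraint generation from a structure's own hydrogen geometry.

Instead of experimental NOE peak lists, restraints are manufactured from the
input structure: every pair of hydrogen-equivalence groups with an
inter-hydrogen distance under a cutoff (default 7 Å) yields one restraint
whose equilibrium distance is either the r6-summed effective distance over
all member pairs (mimicking NOE intensity averaging over indistinguishable
hydrogens) or simply the shortest member distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure import HydrogenGroup, StructureModel, find_hydrogen_groups

__all__ = [
    "DistanceRestraint",
    "RestraintSet",
    "enumerate_pairs",
    "r6_effective_distance",
    "shortest_effective_distance",
    "build_restraints",
    "write_restraints",
    "read_restraints",
]

DEFAULT_CUTOFF = 7.0  # Å; heuristic long-range limit for inter-hydrogen pairs


def r6_effective_distance(member_distances) -> float:
    """Effective distance (Σ_i r_i⁻⁶)^(−1/6) over all member pair distances.

    Always ≤ min(r_i), with equality only for a single pair: summing NOE-like
    r⁻⁶ intensities over equivalent hydrogens shortens the apparent distance.
    """
    r = np.asarray(member_distances, dtype=float)
    if r.size == 0:
        raise ValueError("member_distances must be non-empty")
    if np.any(r <= 0):
        raise ValueError("member distances must be positive")
    return float(np.sum(r ** -6.0) ** (-1.0 / 6.0))


def shortest_effective_distance(member_distances) -> float:
    """Shortest member pair distance."""
    r = np.asarray(member_distances, dtype=float)
    if r.size == 0:
        raise ValueError("member_distances must be non-empty")
    return float(r.min())


_EFFECTIVE = {"r6": r6_effective_distance, "shortest": shortest_effective_distance}


@dataclass
class DistanceRestraint:
    """A restrained hydrogen-group pair with its equilibrium distance d (Å)."""

    group_a: str
    group_b: str
    atoms_a: list[tuple[str, int, str]]  # (chain, resseq, atom name)
    atoms_b: list[tuple[str, int, str]]
    equilibrium_d: float
    member_distances: list[float] = field(default_factory=list)
    method: str = "shortest"

    def __post_init__(self) -> None:
        if self.equilibrium_d <= 0:
            raise ValueError("equilibrium distance must be positive")
        if self.member_distances:
            if len(self.member_distances) != len(self.atoms_a) * len(self.atoms_b):
                raise ValueError("member_distances must cover the full pair product")
            if self.equilibrium_d > min(self.member_distances) + 1e-9:
                raise ValueError("equilibrium distance exceeds the shortest member pair")


@dataclass
class RestraintSet:
    restraints: list[DistanceRestraint]
    cutoff: float = DEFAULT_CUTOFF
    source_model: int = 1
    method: str = "shortest"

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)


def _groups_share_heavy(a: HydrogenGroup, b: HydrogenGroup) -> bool:
    return (a.heavy_atom is not None and b.heavy_atom is not None
            and a.heavy_atom.key() == b.heavy_atom.key())


def enumerate_pairs(structure: StructureModel, groups: list[HydrogenGroup],
                    cutoff: float = DEFAULT_CUTOFF,
                    exclusion: str = "same-heavy-atom"):
    """Unordered group pairs with at least one member H–H distance < cutoff.

    A pair qualifies when ANY of its size_a × size_b member distances is
    strictly below the cutoff; all member distances are returned regardless
    (they all enter the r6 sum).  Intra-group pairs are never emitted.

    exclusion: 'none' | 'same-heavy-atom' (default) | 'bonded'
      'bonded' additionally drops pairs whose heavy atoms are within 1.9 Å
      (1-2/1-3 geminal neighbours).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if exclusion not in ("none", "same-heavy-atom", "bonded"):
        raise ValueError(f"unknown exclusion policy {exclusion!r}")
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ga, gb = groups[i], groups[j]
            if exclusion in ("same-heavy-atom", "bonded") and _groups_share_heavy(ga, gb):
                continue
            if (exclusion == "bonded" and ga.heavy_atom is not None
                    and gb.heavy_atom is not None
                    and np.linalg.norm(ga.heavy_atom.position - gb.heavy_atom.position) <= 1.9):
                continue
            member = [float(np.linalg.norm(ha.position - hb.position))
                      for ha in ga.hydrogens for hb in gb.hydrogens]
            if min(member) < cutoff:
                out.append(((ga, gb), member))
    return out


def build_restraints(structure: StructureModel, method: str = "shortest",
                     cutoff: float = DEFAULT_CUTOFF,
                     exclusion: str = "same-heavy-atom",
                     bond_cutoff: float = 1.2,
                     model: int | None = None) -> RestraintSet:
    """Generate the full self-restraint set for one coordinate model.

    Restraints are ordered deterministically by group id.  The equilibrium
    distance is recomputable from ``member_distances`` with the named method.
    """
    if method not in _EFFECTIVE:
        raise ValueError(f"unknown method {method!r}; expected r6|shortest")
    if model is not None:
        structure = structure.model(model)
    elif structure.atoms and structure.models > 1:
        structure = structure.model(min(a.model_index for a in structure.atoms))
    groups = find_hydrogen_groups(structure, bond_cutoff=bond_cutoff)
    pairs = enumerate_pairs(structure, groups, cutoff=cutoff, exclusion=exclusion)
    restraints = []
    for (ga, gb), member in pairs:
        restraints.append(DistanceRestraint(
            group_a=ga.group_id,
            group_b=gb.group_id,
            atoms_a=[(h.chain_id, h.residue_seq, h.name) for h in ga.hydrogens],
            atoms_b=[(h.chain_id, h.residue_seq, h.name) for h in gb.hydrogens],
            equilibrium_d=_EFFECTIVE[method](member),
            member_distances=member,
            method=method,
        ))
    restraints.sort(key=lambda r: (r.group_a, r.group_b))
    if not restraints:
        warnings.warn(f"no hydrogen pairs under {cutoff} Å; empty restraint set")
    src = structure.atoms[0].model_index if structure.atoms else 1
    return RestraintSet(restraints=restraints, cutoff=cutoff,
                        source_model=src, method=method)


# ---------------------------------------------------------------------------
# Serialization

_TSV_HEADER = "chain_a\tresseq_a\tatoms_a\tchain_b\tresseq_b\tatoms_b\td\tmethod"


def _sel_fields(atoms):
    chain = atoms[0][0]
    resseq = atoms[0][1]
    names = ",".join(a[2] for a in atoms)
    return chain, resseq, names


def write_restraints(rset: RestraintSet, path: str, dialect: str = "tsv",
                     width: float | None = None) -> None:
    """Write a restraint table.

    tsv: one line per restraint (selection pair, d, method).
    xplor: NOE ``assign`` statements; requires ``width`` to derive the
    symmetric bounds dminus = dplus = width/2 around d.
    """
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write(_TSV_HEADER + "\n")
            for r in rset:
                ca, ra, na = _sel_fields(r.atoms_a)
                cb, rb, nb = _sel_fields(r.atoms_b)
                fh.write(f"{ca}\t{ra}\t{na}\t{cb}\t{rb}\t{nb}\t{r.equilibrium_d:.4f}\t{r.method}\n")
    elif dialect == "xplor":
        if width is None:
            raise ValueError("xplor dialect requires a flat-bottom width")
        half = width / 2.0
        with open(path, "w") as fh:
            for r in rset:
                ca, ra, na = _sel_fields(r.atoms_a)
                cb, rb, nb = _sel_fields(r.atoms_b)
                sa = " or ".join(f"name {n}" for n in na.split(","))
                sb = " or ".join(f"name {n}" for n in nb.split(","))
                fh.write(
                    f"assign (segid {ca} and resid {ra} and ({sa}))"
                    f" (segid {cb} and resid {rb} and ({sb}))"
                    f" {r.equilibrium_d:.3f} {half:.3f} {half:.3f}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_restraints(path: str, dialect: str = "tsv") -> RestraintSet:
    """Read a TSV restraint table back (xplor reading is not supported)."""
    if dialect != "tsv":
        raise ValueError(f"unknown or unreadable dialect {dialect!r}")
    restraints = []
    method = "shortest"
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != _TSV_HEADER.strip():
            raise ValueError(f"{path}: unrecognized restraint table header")
        for line in fh:
            if not line.strip():
                continue
            ca, ra, na, cb, rb, nb, d, method = line.rstrip("\n").split("\t")
            restraints.append(DistanceRestraint(
                group_a=f"{ca}/{ra}", group_b=f"{cb}/{rb}",
                atoms_a=[(ca, int(ra), n) for n in na.split(",")],
                atoms_b=[(cb, int(rb), n) for n in nb.split(",")],
                equilibrium_d=float(d), member_distances=[], method=method,
            ))
    return RestraintSet(restraints=restraints, method=method)
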