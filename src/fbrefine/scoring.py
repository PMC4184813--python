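"""Quality assessment: the weighted normalized total score and NOE violations.

Each quality metric x is normalized against a (good, bad) pair — the values
at which the normalized score is 1 and 0 respectively — and the total score
is the weight-summed normalized value over every metric present in both the
score table and the observed metric vector:

    total = Σ_i  weight_i · (x_i − bad_i) / (good_i − bad_i)

The highest total score marks the best structure.  Scores produced by
external validators (clash, nDOPE, dDFIRE, Ramachandran percentages,
WHAT_CHECK Z-scores) are inputs here, never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .restraints import r6_effective_distance
from .structure import StructureModel

__all__ = [
    "ScoreTable",
    "total_score",
    "NOEUpperBound",
    "NOEViolationStats",
    "noe_violations",
    "read_noe_restraints",
    "write_noe_restraints",
    "noe_list_from_restraint_set",
    "read_metrics",
    "DEFAULT_SCORE_TABLE",
]

NOE_THRESHOLDS = (0.5, 1.0, 2.0)  # Å; violation-count bins


@dataclass
class ScoreTable:
    """Per-metric (good, bad, weight) normalization table.

    ``good`` is the metric value scoring 1, ``bad`` the value scoring 0; the
    direction is implied by their ordering (good < bad works for
    lower-is-better metrics such as clash).
    """

    entries: dict[str, tuple[float, float, float]]  # name -> (good, bad, weight)

    def __post_init__(self) -> None:
        for name, (good, bad, weight) in self.entries.items():
            if good == bad:
                raise ValueError(f"metric {name!r}: good and bad must differ")
            if not np.isfinite(weight):
                raise ValueError(f"metric {name!r}: weight must be finite")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ScoreTable":
        entries = {}
        for name, spec in mapping.items():
            if isinstance(spec, dict):
                entries[name] = (float(spec["good"]), float(spec["bad"]),
                                 float(spec.get("weight", 1.0)))
            else:
                g, b, w = spec
                entries[name] = (float(g), float(b), float(w))
        return cls(entries=entries)


# A usable default normalization table for the 12 quality metrics.  These
# good/bad/weight values are this package's own choices (ranges a structural
# biologist would consider clearly good or clearly poor), NOT a published
# benchmark table.
DEFAULT_SCORE_TABLE = ScoreTable(entries={
    "tm_score":      (1.0, 0.0, 1.0),
    "noe_violation": (0.0, 2.0, 1.0),
    "ndope":         (-1.0, 1.0, 1.0),
    "ddfire":        (-300.0, 0.0, 1.0),
    "clash":         (0.0, 100.0, 1.0),
    "rama_mol":      (100.0, 0.0, 1.0),
    "rama_pro":      (100.0, 0.0, 1.0),
    "pack1":         (0.0, -5.0, 1.0),
    "pack2":         (0.0, -5.0, 1.0),
    "rama_what":     (0.0, -5.0, 1.0),
    "rotamer":       (0.0, -5.0, 1.0),
    "backbone":      (0.0, -5.0, 1.0),
})


def total_score(values: dict, table: ScoreTable, clip: bool = False) -> float:
    """Weighted sum of normalized metric values over the table∩values overlap.

    With ``clip`` each normalized term is clamped to [0, 1] before weighting.
    """
    overlap = [name for name in table.entries if name in values]
    if not overlap:
        raise ValueError("no metric overlaps the score table")
    total = 0.0
    for name in overlap:
        good, bad, weight = table.entries[name]
        norm = (float(values[name]) - bad) / (good - bad)
        if clip:
            norm = min(max(norm, 0.0), 1.0)
        total += weight * norm
    return total


# ---------------------------------------------------------------------------
# NOE violations

@dataclass
class NOEUpperBound:
    """One upper-bound distance restraint between two hydrogen selections."""

    atoms_a: list[tuple[str, int, str]]
    atoms_b: list[tuple[str, int, str]]
    upper: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.upper <= 0:
            raise ValueError("upper bound must be positive")


@dataclass
class NOEViolationStats:
    mean: float                 # mean violation in Å
    counts: tuple[int, ...]     # violations exceeding each threshold
    thresholds: tuple[float, ...] = NOE_THRESHOLDS
    n_restraints: int = 0
    n_skipped: int = 0
    violations: list[float] = field(default_factory=list)


def noe_violations(structure: StructureModel, restraints,
                   thresholds=NOE_THRESHOLDS,
                   mean_over: str = "all") -> NOEViolationStats:
    """Violation statistics of upper-bound restraints on a structure.

    Per restraint the effective distance is the r6 sum over all member H–H
    pairs of the two selections; the violation is max(0, d_eff − upper).
    ``mean_over`` is 'all' (default: average over every evaluated restraint)
    or 'violated'.  Restraints whose atoms cannot be resolved are skipped and
    counted.
    """
    restraints = list(restraints)
    if not restraints:
        raise ValueError("empty NOE restraint list")
    index = {(a.chain_id, a.residue_seq, a.name): i
             for i, a in enumerate(structure.atoms)}
    coords = structure.coords()
    violations = []
    skipped = 0
    for r in restraints:
        try:
            ia = [index[a] for a in r.atoms_a]
            ib = [index[b] for b in r.atoms_b]
        except KeyError:
            skipped += 1
            continue
        member = [float(np.linalg.norm(coords[i] - coords[j]))
                  for i in ia for j in ib]
        deff = r6_effective_distance(member)
        violations.append(max(0.0, deff - r.upper))
    if not violations:
        return NOEViolationStats(mean=0.0, counts=tuple(0 for _ in thresholds),
                                 thresholds=tuple(thresholds),
                                 n_restraints=0, n_skipped=skipped)
    arr = np.array(violations)
    if mean_over == "violated":
        pos = arr[arr > 0]
        mean = float(pos.mean()) if len(pos) else 0.0
    elif mean_over == "all":
        mean = float(arr.mean())
    else:
        raise ValueError(f"mean_over must be 'all' or 'violated', got {mean_over!r}")
    counts = tuple(int(np.sum(arr > t)) for t in thresholds)
    return NOEViolationStats(mean=mean, counts=counts,
                             thresholds=tuple(thresholds),
                             n_restraints=len(arr), n_skipped=skipped,
                             violations=violations)


def noe_list_from_restraint_set(rset, slack: float = 0.0) -> list[NOEUpperBound]:
    """Treat a self-derived restraint set as NOE uppers at d (+ slack).

    Used to measure how far a refined structure drifted from the distances
    of the structure its restraints were generated from.
    """
    return [NOEUpperBound(atoms_a=r.atoms_a, atoms_b=r.atoms_b,
                          upper=r.equilibrium_d + slack, source="self")
            for r in rset]


_NOE_HEADER = "chain_a\tresseq_a\tatoms_a\tchain_b\tresseq_b\tatoms_b\tupper"


def write_noe_restraints(restraints, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_NOE_HEADER + "\n")
        for r in restraints:
            ca, ra = r.atoms_a[0][0], r.atoms_a[0][1]
            cb, rb = r.atoms_b[0][0], r.atoms_b[0][1]
            na = ",".join(a[2] for a in r.atoms_a)
            nb = ",".join(b[2] for b in r.atoms_b)
            fh.write(f"{ca}\t{ra}\t{na}\t{cb}\t{rb}\t{nb}\t{r.upper:.4f}\n")


def read_noe_restraints(path: str) -> list[NOEUpperBound]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != _NOE_HEADER.strip():
            raise ValueError(f"{path}: unrecognized NOE table header")
        for line in fh:
            if not line.strip():
                continue
            ca, ra, na, cb, rb, nb, upper = line.rstrip("\n").split("\t")
            out.append(NOEUpperBound(
                atoms_a=[(ca, int(ra), n) for n in na.split(",")],
                atoms_b=[(cb, int(rb), n) for n in nb.split(",")],
                upper=float(upper), source=path))
    return out


def read_metrics(path: str) -> dict:
    """Read observed metric values: 'name = value' or 'name<TAB>value' lines."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                name, _, val = line.partition("=")
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'name value'")
                name, val = parts
            values[name.strip()] = float(val)
    return values
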