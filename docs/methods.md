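# Methods

This note states precisely what `fbrefine` computes. Symbols: distances in
Å, energies in kcal/mol, angles in degrees unless noted.

## 1. Structure model and hydrogen equivalence groups

A structure is an ordered list of atoms (chain, residue number, atom name,
element, Cartesian position), possibly spanning several coordinate models.
PDB I/O goes through gemmi; alternate locations other than blank/'A' and
water are dropped, and malformed coordinate records are reported with their
line number before parsing.

Hydrogens are partitioned into equivalence groups by bonding: each hydrogen
attaches to the nearest heavy atom within 1.2 Å, and hydrogens sharing a
heavy atom form one group (methyl = 3, methylene = 2, amide/alpha = 1).
Perception is purely geometric, so synthetic or nonstandard residues need no
name templates. A hydrogen with no heavy atom in range becomes a flagged
singleton group with a warning.

## 2. Restraint generation

For every unordered pair of groups not sharing a heavy atom, the member
distances are all H–H distances between the two groups. The pair becomes a
restraint if any member distance is strictly below the cutoff (default 7 Å).
Its equilibrium distance d is either

* **shortest** — min over member distances, or
* **r6** — (Σᵢ rᵢ⁻⁶)^(−1/6), the NOE-style intensity-weighted sum, which is
  ≤ the shortest member distance with equality only for single-pair groups.

Restraints serialize to a TSV table or to XPLOR-style `assign` statements
with bounds d ± w/2.

## 3. Flat-bottom potential

With bottom [r_min, r_max] = [d − w/2, d + w/2] (r_min clamped at 0) and
displacement x = r − r_max (upper side) or r_min − r (lower side):

* U = 0 for r ∈ [r_min, r_max];
* U = k·x² for 0 < x ≤ r_sw (quadratic wall);
* U = A + B/x^SE + f·x for x > r_sw (soft asymptote, bounded force → f).

A and B come from C0/C1 matching at x = r_sw:

    B = (f − 2·k·r_sw) · r_sw^(SE+1) / SE
    A = k·r_sw² − B/r_sw^SE − f·r_sw

Defaults SE = 1, f = 1, k = 0.5, r_sw = 3 give A = 7.5, B = −18; the wall at
x = 1 contributes 0.5 and the asymptote at x = 5 contributes 8.9. Upper and
lower sides are parameterized independently (the lower asymptote is only
reachable when r_min − r_sw > 0).

Per-restraint energy is evaluated at the effective distance of the current
coordinates, recomputed with the same method used at generation time. For
the shortest method the gradient acts on the minimal member pair; for r6 the
chain rule through the sum gives ∂d_eff/∂rᵢ = d_eff⁷·rᵢ⁻⁷ applied to every
member pair. The term enters the total energy as scale · Σ U (scale = 10).

## 4. Torsion-grid potential

For each residue with class c (its residue name, or PREPRO when the next
residue is proline) and each torsion pair kind (φ-ψ, φ-χ1, ψ-χ1, χ1-χ2) with
an available table, the energy is the periodic bilinear interpolation of the
class's 2D grid at the current torsion values. Forces propagate through both
dihedrals' analytic gradients (degrees converted to radians). Torsions with
missing atoms (chain termini, missing side chains) skip the term. Tables are
plain text (`TABLE <class> <kind> <bin-width>` followed by the matrix); a
synthetic generator builds sums of periodic von Mises-shaped wells with
known minima for testing.

## 5. Base force field

A self-parameterized term replaces a transferable force field: bonds
(k_b (r−r₀)², k_b = 300) and angles (k_a (θ−θ₀)², k_a = 50) take r₀/θ₀ from
the input structure under distance-based bond perception (H–heavy ≤ 1.2 Å,
heavy–heavy ≤ 1.9 Å); non-bonded, non-1-3 heavy-atom pairs get a soft
repulsion k_r (r_c − r)² (k_r = 10) with r_c = min(3.2 Å, input distance),
so the input structure scores exactly zero energy and force. The refinement
engine accepts any callable `coords -> (energy, forces)` in its place.

The energy system (base + torsion grid + restraints) is parameterized on the
restraint-source structure; refinement may then start from any conformation
of the same atom roster.

## 6. Annealing protocol

1. initial minimization (L-BFGS on the analytic gradient, ≤ 200 iterations);
2. heating, linear 100 → 500 K over 1600 steps;
3. constant 500 K sampling, 2000 steps;
4. cooling, linear 500 → 25 K over 4000 steps;
5. final minimization (≤ 100 iterations).

Dynamics is velocity Verlet at 1 fs with per-step velocity rescaling to the
stage's target temperature, masses by element, initial velocities
Maxwell-distributed from the schedule's seed. Units: Å, kcal/mol, amu, with
acceleration conversion 418.4 (Å/ps² per kcal/mol/Å/amu) and
k_B = 1.9872041·10⁻³ kcal/mol/K. Non-finite energies abort with the failing
step. A schedule can be scaled down (MD stages only) for fast smoke runs;
a fixed seed makes the whole trajectory reproducible.

The width sweep runs one independent refinement per flat-bottom width and
selects the argmax of a pluggable quality score, ties to the smaller width.

## 7. Similarity and quality scoring

**Superposition** is closed-form least squares via SVD with a determinant
correction restricting to proper rotations. **GDT-TS / GDT-HA** average the
maximal superposable Cα fraction over cutoffs {1, 2, 4, 8} / {0.5, 1, 2, 4} Å,
maximized by a seed-and-extend search (windows of length L, L/2, L/4,
iterative re-superposition on the in-cutoff subset). **TM-score** uses the
same search with d₀(L) = 1.24·(L−15)^⅓ − 1.8 (fallback 0.5 for L ≤ 15).
**Secondary structure** collapses 8-state assignments to helix/strand/coil
({H,G,I} → H, {E,B} → E) and reports overall plus per-class match
percentages against the reference.

**NOE-style violations**: for a list of upper bounds, the violation is
max(0, d_eff − upper) with d_eff the r6 sum over the selection's member
pairs; reported as the mean (over all restraints, or over violated ones) and
counts exceeding 0.5 / 1.0 / 2.0 Å. A structure's own restraint set can be
converted to upper bounds at d (+ slack) to measure drift from the input
distances.

**Total score**: Σᵢ wᵢ·(xᵢ − badᵢ)/(goodᵢ − badᵢ) over the metrics present
in a (good, bad, weight) normalization table, optionally clamped to [0, 1]
per term. The shipped default table covers twelve common quality metrics
with this package's own good/bad anchors; it is a usable default, not a
published benchmark.

## 8. Verification

Every numerical component is tested against an independent oracle: the
asymptote coefficients against a numeric 2×2 solve, interpolation against
scipy's `RegularGridInterpolator` on a wrapped lattice, superposition against
Horn's quaternion method, restraint enumeration against a brute-force
all-pairs scan, and all analytic forces against central finite differences.
Nine acceptance properties (potential continuity at every branch boundary,
the r6 inequality on 10⁴ random lists, perturbation-recovery over 20
annealing seeds, monotone violation-versus-width trend, similarity
invariances, scoring extremes) run in the normal test suite with stated
tolerances and runtime budgets; `scripts/acceptance.py` records the same
quantities headlessly.
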