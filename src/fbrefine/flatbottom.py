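"""Flat-bottom distance restraint potential with soft asymptotes.

The restraint energy is zero over a flat bottom [r_min, r_max] centred on the
equilibrium distance d with width w (r_min = d − w/2, r_max = d + w/2).
Immediately outside the bottom the walls are quadratic, k·x² in the
displacement x beyond the flat edge; beyond a switching range rsw each wall
joins a soft asymptote

    U(x) = A + B / x^SE + f·x

whose coefficients A, B are solved from C0/C1 matching at x = rsw, so the
restoring force stays bounded (→ f) at large violation — the "soft-square"
construction used in restrained MD to avoid huge forces on badly violated
restraints.  Defaults: SE = 1, f = 1, k = 1/2, rsw = 3 (energies kcal/mol,
distances Å).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "FlatBottomParams",
    "solve_asymptote_coeffs",
    "make_params",
    "energy",
    "gradient",
    "restraint_energy",
]

DEFAULT_SE = 1.0
DEFAULT_F = 1.0
DEFAULT_K = 0.5
DEFAULT_RSW = 3.0
DEFAULT_SCALE = 10.0


def solve_asymptote_coeffs(SE: float, f: float, k: float, rsw: float):
    """Closed-form (A, B) matching asymptote to quadratic wall at x = rsw.

    Matching U(rsw) = k·rsw² and U'(rsw) = 2k·rsw for U(x) = A + B/x^SE + f·x
    gives B = (f − 2k·rsw)·rsw^(SE+1)/SE and A = k·rsw² − B/rsw^SE − f·rsw.
    With the defaults (1, 1, 1/2, 3): B = −18, A = 7.5.
    """
    if SE <= 0 or k <= 0 or rsw <= 0:
        raise ValueError("SE, k and rsw must all be positive")
    B = (f - 2.0 * k * rsw) * rsw ** (SE + 1.0) / SE
    A = k * rsw**2 - B / rsw**SE - f * rsw
    return A, B


@dataclass
class FlatBottomParams:
    """Resolved parameters of one flat-bottom restraint potential."""

    d: float
    w: float
    SE: float = DEFAULT_SE
    f: float = DEFAULT_F
    k: float = DEFAULT_K
    rsw: float = DEFAULT_RSW
    A_u: float = 0.0
    B_u: float = 0.0
    A_l: float = 0.0
    B_l: float = 0.0
    r_min: float = 0.0
    r_max: float = 0.0


def make_params(d: float, w: float, *, SE: float = DEFAULT_SE, f: float = DEFAULT_F,
                k: float = DEFAULT_K, rsw: float = DEFAULT_RSW,
                warn_clamp: bool = True) -> FlatBottomParams:
    """Build a parameter set for equilibrium distance d and flat width w.

    The upper and lower walls share SE/f/k/rsw (one value of each parameter),
    so A_l = A_u and B_l = B_u.  r_min below zero is clamped to 0 with a
    warning (distances cannot be negative).
    """
    if d <= 0:
        raise ValueError("equilibrium distance d must be positive")
    if w < 0:
        raise ValueError("flat-bottom width w must be non-negative")
    r_min = d - w / 2.0
    r_max = d + w / 2.0
    if r_min < 0:
        if warn_clamp:
            warnings.warn(f"r_min = {r_min:.3f} Å < 0 clamped to 0 (d={d}, w={w})")
        r_min = 0.0
    A, B = solve_asymptote_coeffs(SE, f, k, rsw)
    return FlatBottomParams(d=d, w=w, SE=SE, f=f, k=k, rsw=rsw,
                            A_u=A, B_u=B, A_l=A, B_l=B,
                            r_min=r_min, r_max=r_max)


def energy(r, p: FlatBottomParams):
    """Restraint energy U_fb(r); vectorized over r.

    Zero on [r_min, r_max]; k·x² on the quadratic walls (x = displacement
    past the flat edge, up to rsw); soft asymptote A + B/x^SE + f·x beyond.
    The lower branch exists only where r_min − rsw > 0 leaves room for it.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    u = np.zeros_like(r)

    xu = r - p.r_max
    quad_u = xu > 0
    near = quad_u & (xu <= p.rsw)
    far = quad_u & (xu > p.rsw)
    u[near] = p.k * xu[near] ** 2
    u[far] = p.A_u + p.B_u / xu[far] ** p.SE + p.f * xu[far]

    xl = p.r_min - r
    quad_l = (xl > 0) & (r >= 0)
    near = quad_l & (xl <= p.rsw)
    far = quad_l & (xl > p.rsw)
    u[near] = p.k * xl[near] ** 2
    u[far] = p.A_l + p.B_l / xl[far] ** p.SE + p.f * xl[far]

    return float(u[0]) if scalar else u


def gradient(r, p: FlatBottomParams):
    """Analytic dU/dr; vectorized over r.  → +f as r → ∞ (bounded force)."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    g = np.zeros_like(r)

    xu = r - p.r_max
    near = (xu > 0) & (xu <= p.rsw)
    far = xu > p.rsw
    g[near] = 2.0 * p.k * xu[near]
    g[far] = -p.SE * p.B_u / xu[far] ** (p.SE + 1.0) + p.f

    xl = p.r_min - r
    near = (xl > 0) & (xl <= p.rsw) & (r >= 0)
    far = (xl > p.rsw) & (r >= 0)
    # dU/dr = −dU/dx on the lower side
    g[near] = -2.0 * p.k * xl[near]
    g[far] = -(-p.SE * p.B_l / xl[far] ** (p.SE + 1.0) + p.f)

    return float(g[0]) if scalar else g


# ---------------------------------------------------------------------------
# Structure-level restraint energy and forces


class RestraintEvaluator:
    """Pre-indexed flat-bottom restraint energy/forces on coordinate arrays.

    Resolves every restraint's atom selections against a structure's atom
    order once, then evaluates E_flat = scale · Σ U_fb(d_eff) and the
    per-atom force array on bare (N, 3) coordinates — the hot path of the
    annealing loop.

    The effective distance is recomputed from the current coordinates with
    the restraint's own method: r6 uses the smooth (Σ r⁻⁶)^(−1/6) with its
    analytic chain rule ∂d_eff/∂r_i = d_eff⁷ r_i⁻⁷; shortest applies the
    gradient to the currently minimal pair only (a soft-min variant with
    temperature ``softmin_beta`` smooths the pair switch when set).
    """

    def __init__(self, structure, restraint_set, w: float,
                 scale: float = DEFAULT_SCALE, softmin_beta: float | None = None,
                 **fb_overrides):
        index = {(a.chain_id, a.residue_seq, a.name): i
                 for i, a in enumerate(structure.atoms)}
        self.scale = scale
        self.softmin_beta = softmin_beta
        self.params: list[FlatBottomParams] = []
        pairs_i: list[int] = []
        pairs_j: list[int] = []
        seg_len: list[int] = []
        methods: list[bool] = []  # True → r6
        for r in restraint_set:
            try:
                ia = [index[a] for a in r.atoms_a]
                ib = [index[b] for b in r.atoms_b]
            except KeyError as exc:
                raise KeyError(
                    f"restraint {r.group_a} -- {r.group_b}: atom {exc.args[0]} "
                    "not present in structure") from None
            for i in ia:
                for j in ib:
                    pairs_i.append(i)
                    pairs_j.append(j)
            seg_len.append(len(ia) * len(ib))
            methods.append(r.method == "r6")
            self.params.append(make_params(r.equilibrium_d, w,
                                           warn_clamp=False, **fb_overrides))
        n_clamped = sum(1 for p, r in zip(self.params, restraint_set)
                        if r.equilibrium_d - w / 2.0 < 0)
        if n_clamped:
            warnings.warn(
                f"{n_clamped} restraint(s) with d < w/2: r_min clamped to 0")
        self.pair_i = np.array(pairs_i, dtype=int)
        self.pair_j = np.array(pairs_j, dtype=int)
        self.seg_start = np.concatenate([[0], np.cumsum(seg_len)]).astype(int)
        self.seg_id = np.repeat(np.arange(len(seg_len)), seg_len)
        self.is_r6 = np.array(methods, dtype=bool)
        # one shared parameter template (SE/f/k/rsw identical per evaluator)
        self._p0 = self.params[0] if self.params else make_params(1.0, w, **fb_overrides)
        self.r_min = np.array([p.r_min for p in self.params])
        self.r_max = np.array([p.r_max for p in self.params])

    def _energy_grad(self, deff: np.ndarray):
        """Vectorized U_fb and dU/dr over all restraints at their d_eff."""
        p = self._p0
        u = np.zeros_like(deff)
        g = np.zeros_like(deff)
        xu = deff - self.r_max
        near = (xu > 0) & (xu <= p.rsw)
        far = xu > p.rsw
        u[near] = p.k * xu[near] ** 2
        g[near] = 2.0 * p.k * xu[near]
        u[far] = p.A_u + p.B_u / xu[far] ** p.SE + p.f * xu[far]
        g[far] = -p.SE * p.B_u / xu[far] ** (p.SE + 1.0) + p.f
        xl = self.r_min - deff
        near = (xl > 0) & (xl <= p.rsw)
        far = xl > p.rsw
        u[near] = p.k * xl[near] ** 2
        g[near] = -2.0 * p.k * xl[near]
        u[far] = p.A_l + p.B_l / xl[far] ** p.SE + p.f * xl[far]
        g[far] = -(-p.SE * p.B_l / xl[far] ** (p.SE + 1.0) + p.f)
        return u, g

    def __call__(self, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        forces = np.zeros_like(coords)
        if not self.params:
            return 0.0, forces
        diff = coords[self.pair_i] - coords[self.pair_j]
        rij = np.maximum(np.linalg.norm(diff, axis=1), 1e-8)
        starts = self.seg_start[:-1]
        # effective distance and its partials per member pair
        dd_dr = np.zeros_like(rij)
        deff = np.empty(len(self.params))
        if np.any(self.is_r6):
            s = np.add.reduceat(rij ** -6.0, starts)
            d_r6 = s ** (-1.0 / 6.0)
            deff[self.is_r6] = d_r6[self.is_r6]
            mask = self.is_r6[self.seg_id]
            dd_dr[mask] = (d_r6[self.seg_id] ** 7 * rij ** -7.0)[mask]
        if not np.all(self.is_r6):
            sh = ~self.is_r6
            if self.softmin_beta:
                b = self.softmin_beta
                rmin_seg = np.minimum.reduceat(rij, starts)
                wgt = np.exp(-b * (rij - rmin_seg[self.seg_id]))
                wsum = np.add.reduceat(wgt, starts)
                wgt = wgt / wsum[self.seg_id]
                d_soft = np.add.reduceat(wgt * rij, starts)
                deff[sh] = d_soft[sh]
                mask = sh[self.seg_id]
                dd = wgt * (1.0 + b * (d_soft[self.seg_id] - rij))
                dd_dr[mask] = dd[mask]
            else:
                rmin_seg = np.minimum.reduceat(rij, starts)
                deff[sh] = rmin_seg[sh]
                # gradient on the currently minimal pair of each segment only
                is_min = rij <= rmin_seg[self.seg_id] + 0.0
                # keep a single minimal member per segment
                first_min = np.zeros_like(is_min)
                idx = np.flatnonzero(is_min)
                seg_of = self.seg_id[idx]
                _, first_pos = np.unique(seg_of, return_index=True)
                first_min[idx[first_pos]] = True
                mask = sh[self.seg_id] & first_min
                dd_dr[mask] = 1.0
        u, du = self._energy_grad(deff)
        e = float(np.sum(u))
        coef = (self.scale * du[self.seg_id] * dd_dr / rij)[:, None]
        fvec = coef * diff
        np.subtract.at(forces, self.pair_i, fvec)
        np.add.at(forces, self.pair_j, fvec)
        return self.scale * e, forces


def restraint_energy(structure, restraint_set, w: float,
                     scale: float = DEFAULT_SCALE, **kw):
    """E_flat and per-atom forces of a restraint set on a structure.

    Convenience wrapper: builds a :class:`RestraintEvaluator` and evaluates
    it on the structure's own coordinates.  Returns (energy, forces) with
    forces shaped (N_atoms, 3).
    """
    ev = RestraintEvaluator(structure, restraint_set, w, scale=scale, **kw)
    return ev(structure.coords())
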