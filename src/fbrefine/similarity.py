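"""Backbone similarity: Kabsch superposition, RMSD, GDT-TS/GDT-HA, TM-score,
and 3-state secondary-structure match percentages.

GDT and TM-score use a seed-and-extend superposition search: contiguous seed
windows are superposed, then the aligned subset is iteratively re-selected by
the distance criterion and re-superposed.  This is the standard documented
approximation to the exhaustive LGA search; identical structures and rigid
motions are handled exactly.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "superpose",
    "kabsch_rmsd",
    "gdt_scores",
    "gdt_from_deviations",
    "tm_score",
    "tm_d0",
    "ss_similarity",
    "ss3_from_dssp",
    "assign_ss",
]

GDT_TS_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
GDT_HA_CUTOFFS = (0.5, 1.0, 2.0, 4.0)


def superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares rigid superposition of b onto a (Kabsch).

    Returns (rotation, translation) with det(rotation) = +1 such that
    ``coords_b @ rotation.T + translation`` best fits ``coords_a``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("rank-deficient point sets: superposition ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    return rot, trans


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (proper rotation only)."""
    rot, trans = superpose(coords_a, coords_b)
    moved = np.asarray(coords_b) @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((np.asarray(coords_a) - moved) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Seed-and-extend deviation search shared by GDT and TM-score

def _seed_windows(n: int):
    lengths = sorted({n, max(n // 2, 4), max(n // 4, 4)}, reverse=True)
    for wl in lengths:
        if wl > n:
            continue
        step = max(1, wl // 2)
        for start in range(0, n - wl + 1, step):
            yield np.arange(start, start + wl)


def _deviations(ref, mod, idx):
    rot, trans = superpose(ref[idx], mod[idx])
    moved = mod @ rot.T + trans
    return np.linalg.norm(ref - moved, axis=1)


def _extend(ref, mod, seed_idx, select, n_iter: int = 5):
    """Iteratively re-superpose on the selected subset; final deviations."""
    idx = seed_idx
    dev = _deviations(ref, mod, idx)
    for _ in range(n_iter):
        new_idx = np.nonzero(select(dev))[0]
        if len(new_idx) < 3 or (len(new_idx) == len(idx) and np.all(new_idx == idx)):
            break
        idx = new_idx
        dev = _deviations(ref, mod, idx)
    return dev


def gdt_from_deviations(deviations, cutoffs) -> float:
    """Mean over cutoffs of the fraction of residues within each cutoff."""
    d = np.asarray(deviations, dtype=float)
    return float(np.mean([(d <= c).mean() for c in cutoffs]))


def _max_fraction_per_cutoff(ref, mod, cutoffs):
    n = len(ref)
    best = {c: 0.0 for c in cutoffs}
    for seed in _seed_windows(n):
        for c in cutoffs:
            dev = _extend(ref, mod, seed, lambda d, c=c: d <= c)
            frac = float((dev <= c).mean())
            if frac > best[c]:
                best[c] = frac
    return best


def gdt_scores(ref_ca: np.ndarray, model_ca: np.ndarray):
    """(GDT-TS, GDT-HA) as fractions in [0, 1].

    GDT-TS averages the maximal superposable fraction over cutoffs
    {1, 2, 4, 8} Å; GDT-HA over {0.5, 1, 2, 4} Å.
    """
    ref = np.asarray(ref_ca, dtype=float)
    mod = np.asarray(model_ca, dtype=float)
    if ref.shape != mod.shape:
        raise ValueError("Cα lists must have equal length")
    cutoffs = sorted(set(GDT_TS_CUTOFFS) | set(GDT_HA_CUTOFFS))
    best = _max_fraction_per_cutoff(ref, mod, cutoffs)
    gdt_ts = float(np.mean([best[c] for c in GDT_TS_CUTOFFS]))
    gdt_ha = float(np.mean([best[c] for c in GDT_HA_CUTOFFS]))
    return gdt_ts, gdt_ha


def tm_d0(length: int) -> float:
    """TM-score distance scale d0(L) = 1.24·(L−15)^⅓ − 1.8 for L > 15."""
    if length <= 15:
        warnings.warn(f"L={length} ≤ 15: using fallback d0 = 0.5")
        return 0.5
    return 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8


def tm_score(ref_ca: np.ndarray, model_ca: np.ndarray) -> float:
    """Length-normalized backbone similarity in (0, 1].

    TM = max over superpositions of (1/L)·Σ 1/(1 + (d_i/d0)²) with the
    published d0(L); the maximization uses the seed-and-extend search with
    the d ≤ d0 selection rule.
    """
    ref = np.asarray(ref_ca, dtype=float)
    mod = np.asarray(model_ca, dtype=float)
    if ref.shape != mod.shape:
        raise ValueError("Cα lists must have equal length")
    n = len(ref)
    d0 = tm_d0(n)
    best = 0.0
    for seed in _seed_windows(n):
        dev = _extend(ref, mod, seed, lambda d: d <= max(d0, 0.5))
        score = float(np.mean(1.0 / (1.0 + (dev / d0) ** 2)))
        best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# Secondary structure

_DSSP_TO_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def ss3_from_dssp(dssp: str) -> str:
    """Collapse 8-state DSSP codes to 3 states: {H,G,I}→H, {E,B}→E, else C."""
    return "".join(_DSSP_TO_3.get(c, "C") for c in dssp)


def ss_similarity(ref_ss: str, model_ss: str):
    """Overall and per-class (α/β/coil) secondary-structure match percentages.

    Per-class percentages are relative to the reference assignment; a class
    absent from the reference is reported as None.
    """
    if len(ref_ss) != len(model_ss):
        raise ValueError("secondary-structure strings must have equal length")
    if not ref_ss:
        raise ValueError("empty secondary-structure strings")
    matches = sum(1 for a, b in zip(ref_ss, model_ss) if a == b)
    overall = 100.0 * matches / len(ref_ss)
    per_class = {}
    for cls in "HEC":
        in_ref = [i for i, c in enumerate(ref_ss) if c == cls]
        if not in_ref:
            per_class[cls] = None
        else:
            hit = sum(1 for i in in_ref if model_ss[i] == cls)
            per_class[cls] = 100.0 * hit / len(in_ref)
    return overall, per_class


def assign_ss(phi_psi) -> str:
    """Crude φ/ψ-window 3-state assigner for synthetic fixtures ONLY.

    Not a DSSP replacement: real assignments should be supplied as strings.
    ``phi_psi`` is a sequence of (φ, ψ) pairs; None entries (chain termini)
    map to coil.
    """
    out = []
    for entry in phi_psi:
        if entry is None or entry[0] is None or entry[1] is None:
            out.append("C")
            continue
        phi, psi = entry
        if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
            out.append("H")
        elif phi < -40.0 and (psi >= 90.0 or psi <= -150.0):
            out.append("E")
        else:
            out.append("C")
    return "".join(out)
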