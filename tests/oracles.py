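"""Independent reference implementations used only to cross-check the
package: a quaternion-eigenvalue rigid superposition, a sliding-window
rule-by-rule motif evaluator, an all-pairs contact search, and the
closed-form accessible area of two overlapping spheres.  These share no
code with the implementations they verify.
"""

from __future__ import annotations

import numpy as np

HYDROPHOBIC = set("ACFILMPVWY")


def quaternion_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Optimal superposition RMSD via the Horn quaternion eigenvalue method."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    n = len(A)
    a = A - A.mean(axis=0)
    b = B - B.mean(axis=0)
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    sq = ((a ** 2).sum() + (b ** 2).sum() - 2.0 * lam) / n
    return float(np.sqrt(max(sq, 0.0)))


def brute_force_cdgsh(sequence: str, max_mismatch: int = 0) -> list[dict]:
    """Sliding-window, position-by-position CDGSH rule evaluation.

    Returns hit dicts with 1-based start, status and mismatch list, with
    the same strict-over-relaxed suppression at a shared C13 position.
    """
    seq = sequence.replace("-", "").upper()
    rules = {1: HYDROPHOBIC, 2: {"C"}, 4: {"C"}, 7: {"S", "T"}, 11: {"P"},
             12: HYDROPHOBIC, 13: {"C"}, 14: {"D"}, 15: {"G"},
             16: {"S", "T", "A"}, 17: {"H"}}
    raw = []
    for start in range(1, len(seq) - 16 + 1):
        window = seq[start - 1:start + 16]
        mism = []
        for pos, allowed in sorted(rules.items()):
            ch = window[pos - 1]
            if ch in "UX" or ch not in allowed:
                mism.append((pos, ch))
        if len(mism) > max_mismatch:
            continue
        if not mism:
            status = "strict"
        elif mism == [(17, "C")]:
            status = "his_to_cys"
        else:
            status = "disrupted"
        raw.append({"start": start, "status": status, "mismatches": mism,
                    "c13": start + 12})
    strict_c13 = {h["c13"] for h in raw if h["status"] == "strict"}
    return [h for h in raw if h["status"] == "strict" or h["c13"] not in strict_c13]


def brute_force_contacts(coords_a: np.ndarray, coords_b: np.ndarray,
                         d_max: float) -> set[tuple[int, int]]:
    """O(n²) all-pairs inter-set contact search."""
    out = set()
    for i, p in enumerate(coords_a):
        for j, q in enumerate(coords_b):
            if np.linalg.norm(p - q) <= d_max:
                out.add((i, j))
    return out


def two_sphere_accessible_area(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Exact accessible areas of two overlapping spheres (radii already
    probe-inflated), by the spherical-cap formula."""
    full1, full2 = 4 * np.pi * r1 ** 2, 4 * np.pi * r2 ** 2
    if d >= r1 + r2:
        return full1, full2
    if d <= abs(r1 - r2):
        if r1 < r2:
            return 0.0, full2
        return full1, 0.0
    h1 = (r2 ** 2 - (d - r1) ** 2) / (2 * d)
    h2 = (r1 ** 2 - (d - r2) ** 2) / (2 * d)
    return full1 - 2 * np.pi * r1 * h1, full2 - 2 * np.pi * r2 * h2
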