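"""Independent oracles used only by the tests.

Deliberately implemented by different algorithms than the library code
they check: quaternion (Horn) superposition vs. the library's SVD-based
Kabsch; exhaustive subset enumeration vs. the seeded GDT search; literal
2^m sign enumeration vs. the library's dynamic-programming Wilcoxon.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata


def quaternion_superpose_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Least-squares superposition RMSD via Horn's quaternion method."""
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    m = moving - moving.mean(axis=0)
    f = fixed - fixed.mean(axis=0)
    s = m.T @ f
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(k)
    w, x, y, z = eigvecs[:, -1]  # quaternion of the optimal proper rotation
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    diff = m @ rot.T - f
    return float(np.sqrt((diff**2).sum() / len(m)))


def _subset_feasible(mob, fix, subset, cutoff) -> bool:
    sub_m, sub_f = mob[list(subset)], fix[list(subset)]
    mc, fc = sub_m.mean(axis=0), sub_f.mean(axis=0)
    h = (sub_m - mc).T @ (sub_f - fc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (sub_m - mc) @ rot.T + fc
    return bool(np.all(np.linalg.norm(moved - sub_f, axis=1) <= cutoff))


def brute_force_gdt_fraction(
    model_coords: np.ndarray, native_coords: np.ndarray, cutoff: float, n_native: int
) -> float:
    """Exact GDT fraction: max |S|, S a residue subset (|S| >= 3) whose
    least-squares superposition keeps every member within the cutoff.

    Enumeration is pruned by a *sound* necessary condition: if residues i
    and j both sit within the cutoff of their native positions under one
    rigid transform, then |d_model(i,j) - d_native(i,j)| <= 2*cutoff.
    Feasible subsets are therefore cliques of the pair-compatibility
    graph, and each clique lies inside one connected component, so the
    exhaustive search runs per component over compatible subsets only.
    """
    model_coords = np.asarray(model_coords, dtype=float)
    native_coords = np.asarray(native_coords, dtype=float)
    n = len(model_coords)
    dm = np.linalg.norm(model_coords[:, None] - model_coords[None], axis=2)
    dn = np.linalg.norm(native_coords[:, None] - native_coords[None], axis=2)
    compatible = np.abs(dm - dn) <= 2 * cutoff

    # connected components of the compatibility graph
    unseen = set(range(n))
    best = 0
    while unseen:
        stack = [unseen.pop()]
        component = []
        while stack:
            i = stack.pop()
            component.append(i)
            neighbours = [j for j in unseen if compatible[i, j]]
            for j in neighbours:
                unseen.remove(j)
            stack.extend(neighbours)
        component = sorted(component)
        for size in range(len(component), max(best, 2), -1):
            found = False
            for subset in combinations(component, size):
                idx = list(subset)
                if not compatible[np.ix_(idx, idx)].all():
                    continue
                if _subset_feasible(model_coords, native_coords, subset, cutoff):
                    best = size
                    found = True
                    break
            if found:
                break
    return best / n_native


def enumerate_wilcoxon(d: np.ndarray) -> tuple[float, float]:
    """(W, exact two-sided p) by literal enumeration of all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = len(d)
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=m)
    ]
    sums = np.array(sums)
    lower = np.mean(sums <= w_obs)
    upper = np.mean(sums >= w_obs)
    return float(w_obs), float(min(1.0, 2 * min(lower, upper)))


def random_proper_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from a random quaternion."""
    quat = rng.normal(size=4)
    w, x, y, z = quat / np.linalg.norm(quat)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
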