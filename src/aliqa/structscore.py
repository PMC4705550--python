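"""GDT-TS structural similarity between a model and its native structure.

The Global Distance Test Total Score is the mean, over distance cutoffs of
1, 2, 4 and 8 Angstrom, of the largest fraction of residues that can be
superposed within the cutoff onto the native structure.  Finding the true
maximum is combinatorial; like LGA, this module uses a seeded
superposition search:

1. pair residues of model and native by residue number;
2. for seed windows of length 3, 5 and 7 sliding along the common
   residues (plus the full common set), superpose model on native over
   the seed, select the pairs within the cutoff, re-superpose on the
   selection and repeat until the selection is stable (at most 10
   iterations); at every superposition, distance-sorted prefixes of the
   residue list are additionally tried as candidate selections (all
   prefixes on chains of up to 20 common residues, prefixes reaching at
   most twice the cutoff beyond that);
3. every candidate selection is verified (superposing on the selection
   keeps all of its members within the cutoff) before being counted, so
   the reported fraction is always attained by an actual superposition;
4. the fraction is the largest verified selection divided by the number
   of native residues (CASP convention: incomplete models are penalized).

Scores are on the 0-1 scale.  Superpositions are least-squares (Kabsch);
rotations are proper (no reflection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.SeqUtils import seq1

__all__ = [
    "CAStructure",
    "Superposition",
    "GDTResult",
    "GDT_CUTOFFS",
    "read_ca_structure",
    "kabsch_superpose",
    "gdt_fraction",
    "gdt_ts",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)

_MAX_ITER = 10
_SEED_LENGTHS = (3, 5, 7)
_EXHAUSTIVE_PREFIX_N = 20  # below this, every distance-sorted prefix is verified


@dataclass(frozen=True)
class CAStructure:
    """CA trace of one chain: residue numbers, one-letter codes, coordinates."""

    structure_id: str
    residue_numbers: np.ndarray  # (n,) int, strictly increasing
    amino_acids: tuple[str, ...]  # one-letter codes, "X" for non-standard
    coords: np.ndarray  # (n, 3) float, Angstrom

    def __post_init__(self) -> None:
        if len(self.residue_numbers) != len(self.coords) or len(self.amino_acids) != len(
            self.coords
        ):
            raise ValueError("residue numbers, amino acids and coordinates differ in length")
        if len(self.residue_numbers) and np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass(frozen=True)
class Superposition:
    """A proper rigid transform (rotation then translation) with its RMSD."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class GDTResult:
    """Per-cutoff fractions and their mean, the GDT-TS score in [0, 1]."""

    p1: float
    p2: float
    p4: float
    p8: float
    gdt_ts: float
    n_common: int


def read_ca_structure(
    path: str | Path, chain: str | None = None, structure_id: str | None = None
) -> CAStructure:
    """Read one CA atom per residue from a PDB file.

    The first CA record wins on altloc duplicates; hetero residues are
    skipped.  ``chain`` selects a chain id, default is the first chain of
    the first model.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise ValueError(f"{path}: malformed PDB record ({exc})") from exc
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no CA atoms found")
    chains = list(models[0])
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValueError(f"{path}: chain {chain!r} not present")
    if not chains:
        raise ValueError(f"{path}: no CA atoms found")
    selected = chains[0]
    numbers, aas, xyz = [], [], []
    for res in selected:
        hetflag, resseq, _icode = res.id
        if hetflag != " " or "CA" not in res:
            continue
        atom = res["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]  # first record in the file wins
        numbers.append(resseq)
        aas.append(seq1(res.get_resname(), undef_code="X"))
        xyz.append(atom.get_coord())
    if not numbers:
        raise ValueError(f"{path}: no CA atoms found")
    return CAStructure(
        structure_id=structure_id or path.stem,
        residue_numbers=np.asarray(numbers, dtype=int),
        amino_acids=tuple(aas),
        coords=np.asarray(xyz, dtype=float),
    )


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares superposition of ``moving`` onto ``fixed`` (Kabsch).

    Returns the proper rotation and translation minimizing the RMSD of the
    transformed moving set to the fixed set.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(f"coordinate shapes differ: {moving.shape} vs {fixed.shape}")
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise ValueError("superposition needs >=3 points of dimension 3")
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = fc - rotation @ mc
    diff = moving @ rotation.T + translation - fixed
    rmsd = float(np.sqrt((diff**2).sum() / len(moving)))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def _common_coords(
    model: CAStructure, native: CAStructure
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of residues shared by residue number, in native order."""
    common, m_idx, n_idx = np.intersect1d(
        model.residue_numbers, native.residue_numbers, return_indices=True
    )
    if len(common) < 3:
        raise ValueError(
            f"need >=3 residues common to model and native, found {len(common)}"
        )
    mismatches = [
        int(num)
        for num, i, j in zip(common, m_idx, n_idx)
        if model.amino_acids[i] != native.amino_acids[j]
    ]
    if mismatches:
        warnings.warn(
            f"amino-acid mismatch at residue number(s) {mismatches[:5]}"
            f"{'...' if len(mismatches) > 5 else ''}; pairing by number anyway",
            stacklevel=3,
        )
    return model.coords[m_idx], native.coords[n_idx]


def _distances(mob: np.ndarray, fix: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Per-residue distances after superposing ``mob`` on ``fix`` over ``sel``."""
    sup = kabsch_superpose(mob[sel], fix[sel])
    return np.linalg.norm(sup.apply(mob) - fix, axis=1)


def _is_feasible(mob: np.ndarray, fix: np.ndarray, sel: np.ndarray, cutoff: float) -> bool:
    """True if superposing on ``sel`` keeps every member of ``sel`` within cutoff."""
    sup = kabsch_superpose(mob[sel], fix[sel])
    dist = np.linalg.norm(sup.apply(mob[sel]) - fix[sel], axis=1)
    return bool(np.all(dist <= cutoff))


def _search(
    mob: np.ndarray,
    fix: np.ndarray,
    cutoff: float,
    extra_seeds: tuple[np.ndarray, ...] = (),
) -> tuple[int, np.ndarray | None]:
    """Best verified selection size (and the selection) for one cutoff."""
    n = len(mob)
    seeds: list[np.ndarray] = [np.arange(n), *extra_seeds]
    for length in _SEED_LENGTHS:
        for start in range(0, n - length + 1):
            seeds.append(np.arange(start, start + length))
    if n <= _EXHAUSTIVE_PREFIX_N:
        # small chains: every residue triple becomes a seed, which makes the
        # search exhaustive enough to recover the exact subset maximum
        seeds.extend(np.array(t) for t in combinations(range(n), 3))
    best_size, best_sel = 0, None
    checked: set[frozenset] = set()

    def consider(cand: np.ndarray) -> None:
        nonlocal best_size, best_sel
        key = frozenset(cand.tolist())
        if len(cand) >= 3 and len(cand) > best_size and key not in checked:
            checked.add(key)
            if _is_feasible(mob, fix, cand, cutoff):
                best_size, best_sel = len(cand), cand

    # on small chains every sorted prefix is worth verifying; on large ones
    # only prefixes whose farthest member is already near the cutoff
    prefix_limit = np.inf if n <= _EXHAUSTIVE_PREFIX_N else 2.0 * cutoff

    for seed in extra_seeds:  # a carried-in selection is itself a candidate
        consider(seed)
    for seed in seeds:
        sel = seed
        for _ in range(_MAX_ITER):
            key = frozenset(sel.tolist())
            dist = _distances(mob, fix, sel)
            order = np.argsort(dist, kind="stable")
            for k in range(max(best_size + 1, 3), n + 1):
                if dist[order[k - 1]] > prefix_limit:
                    break
                consider(np.sort(order[:k]))
            new = np.flatnonzero(dist <= cutoff)
            if len(new) >= 3:
                consider(new)
            if len(new) < 3 or frozenset(new.tolist()) == key:
                break
            sel = new
    return best_size, best_sel


def gdt_fraction(model: CAStructure, native: CAStructure, cutoff: float) -> float:
    """Largest verified fraction of native residues superposable within ``cutoff``."""
    mob, fix = _common_coords(model, native)
    best_size, _sel = _search(mob, fix, cutoff)
    return best_size / len(native)


def gdt_ts(model: CAStructure, native: CAStructure) -> GDTResult:
    """GDT-TS: mean of the within-cutoff fractions at 1, 2, 4 and 8 Angstrom.

    Cutoffs are searched in ascending order and each cutoff's best
    selection seeds the next (a selection within 1 A is trivially within
    2 A), which makes the per-cutoff fractions monotone by construction.
    """
    mob, fix = _common_coords(model, native)
    fractions: list[float] = []
    carry: tuple[np.ndarray, ...] = ()
    for cutoff in GDT_CUTOFFS:
        best_size, best_sel = _search(mob, fix, cutoff, extra_seeds=carry)
        fractions.append(best_size / len(native))
        if best_sel is not None:
            carry = (best_sel,)
    p1, p2, p4, p8 = fractions
    return GDTResult(
        p1=p1, p2=p2, p4=p4, p8=p8,
        gdt_ts=(p1 + p2 + p4 + p8) / 4.0,
        n_common=len(mob),
    )
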