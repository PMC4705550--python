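"""CA structure parsing, Kabsch superposition and the GDT-TS search."""

import numpy as np
import pytest

from aliqa.structscore import (
    CAStructure,
    gdt_fraction,
    gdt_ts,
    kabsch_superpose,
    read_ca_structure,
)
from aliqa.synthetic import simulate_structure_pair
from oracles import brute_force_gdt_fraction, quaternion_superpose_rmsd, random_proper_rotation


def _structure(coords, start=1, structure_id="s"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return CAStructure(
        structure_id=structure_id,
        residue_numbers=np.arange(start, start + n),
        amino_acids=tuple("A" * n),
        coords=coords,
    )


class TestReadCAStructure:
    def test_toy_file(self, toy_pdb):
        struct = read_ca_structure(toy_pdb)
        assert len(struct) == 5
        assert list(struct.residue_numbers) == [1, 2, 3, 4, 5]
        assert struct.amino_acids == ("A", "G", "S", "L", "K")
        assert struct.coords[0] == pytest.approx([1.458, 0.0, 0.0])

    def test_altloc_first_record_wins(self, altloc_pdb):
        struct = read_ca_structure(altloc_pdb)
        assert len(struct) == 3
        assert struct.coords[0] == pytest.approx([1.0, 0.0, 0.0])  # altloc A, not B

    def test_empty_file_is_an_error(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("END\n")
        with pytest.raises(ValueError, match="no CA atoms"):
            read_ca_structure(empty)

    def test_missing_chain_is_an_error(self, toy_pdb):
        with pytest.raises(ValueError, match="chain 'B'"):
            read_ca_structure(toy_pdb, chain="B")


class TestKabsch:
    def test_identical_sets(self):
        coords = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch_superpose(coords, coords)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered(self):
        coords = np.random.default_rng(1).normal(size=(8, 3))
        sup = kabsch_superpose(coords, coords + [1.0, 1.0, 1.0])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert sup.translation == pytest.approx([1.0, 1.0, 1.0], abs=1e-10)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            moving = rng.normal(scale=10.0, size=(n, 3))
            fixed = rng.normal(scale=10.0, size=(n, 3))
            sup = kabsch_superpose(moving, fixed)
            assert sup.rmsd == pytest.approx(
                quaternion_superpose_rmsd(moving, fixed), abs=1e-8
            )
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_length_mismatch_and_too_few_points(self):
        with pytest.raises(ValueError, match="shapes differ"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError, match=">=3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _chain(n, rng):
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.cumsum(3.8 * steps, axis=0)


class TestGDT:
    def test_identical_structures_score_one(self):
        coords = _chain(15, np.random.default_rng(3))
        native, model = _structure(coords), _structure(coords.copy())
        result = gdt_ts(model, native)
        assert result.gdt_ts == 1.0
        assert (result.p1, result.p2, result.p4, result.p8) == (1.0, 1.0, 1.0, 1.0)

    def test_half_displaced_matches_brute_force(self):
        """10 good + 10 rigidly displaced residues: exactly 0.5 at every cutoff."""
        coords = _chain(20, np.random.default_rng(4))
        model_coords = coords.copy()
        model_coords[10:] += 100.0
        native, model = _structure(coords), _structure(model_coords)
        for cutoff in (1.0, 2.0, 4.0, 8.0):
            frac = gdt_fraction(model, native, cutoff)
            assert frac == 0.5
            assert frac == brute_force_gdt_fraction(model_coords, coords, cutoff, 20)
        assert gdt_ts(model, native).gdt_ts == 0.5

    def test_rigid_transform_of_model_scores_one(self):
        rng = np.random.default_rng(5)
        coords = _chain(12, rng)
        rot = random_proper_rotation(rng)
        native = _structure(coords)
        model = _structure(coords @ rot.T + [5.0, -3.0, 8.0])
        assert gdt_ts(model, native).gdt_ts == 1.0

    def test_rigid_invariance_of_score(self):
        rng = np.random.default_rng(6)
        native, model = simulate_structure_pair(15, 0.6, seed=9)
        reference = gdt_ts(model, native).gdt_ts
        for _ in range(5):
            rot = random_proper_rotation(rng)
            shift = rng.normal(scale=20.0, size=3)
            moved = CAStructure(
                structure_id="m",
                residue_numbers=model.residue_numbers.copy(),
                amino_acids=model.amino_acids,
                coords=model.coords @ rot.T + shift,
            )
            assert gdt_ts(moved, native).gdt_ts == pytest.approx(reference, abs=1e-9)

    def test_small_perturbation_keeps_score_one(self):
        rng = np.random.default_rng(7)
        coords = _chain(25, rng)
        jitter = rng.uniform(-0.25, 0.25, size=(25, 3))  # max displacement < 0.5 A
        native, model = _structure(coords), _structure(coords + jitter)
        assert gdt_ts(model, native).gdt_ts == 1.0

    def test_monotone_in_cutoff(self):
        for seed in range(4):
            native, model = simulate_structure_pair(14, 0.5, seed=seed)
            res = gdt_ts(model, native)
            assert res.p1 <= res.p2 <= res.p4 <= res.p8
            assert res.gdt_ts == pytest.approx((res.p1 + res.p2 + res.p4 + res.p8) / 4)

    def test_missing_residues_bound_the_score(self):
        coords = _chain(20, np.random.default_rng(8))
        native = _structure(coords)
        truncated = CAStructure(
            structure_id="m",
            residue_numbers=np.arange(1, 13),
            amino_acids=tuple("A" * 12),
            coords=coords[:12].copy(),
        )
        res = gdt_ts(truncated, native)
        assert res.gdt_ts <= 12 / 20 + 1e-12
        assert res.n_common == 12

    def test_too_few_common_residues(self):
        a = _structure(np.zeros((5, 3)), start=1)
        b = _structure(np.ones((5, 3)), start=100)
        with pytest.raises(ValueError, match=">=3 residues common"):
            gdt_ts(a, b)

    def test_mismatched_amino_acids_warn_not_fail(self):
        coords = _chain(10, np.random.default_rng(9))
        native = _structure(coords)
        renamed = CAStructure(
            structure_id="m",
            residue_numbers=native.residue_numbers.copy(),
            amino_acids=tuple("G" * 10),
            coords=coords.copy(),
        )
        with pytest.warns(UserWarning, match="amino-acid mismatch"):
            assert gdt_ts(renamed, native).gdt_ts == 1.0
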