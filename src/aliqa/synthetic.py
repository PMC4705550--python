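"""Seeded synthetic alignments, labelled datasets and structure pairs.

Real training corpora for alignment-based quality assessment are built
from structure-prediction experiments (hundreds of query-template
alignments per target set, with models scored against solved natives).
This module emulates such corpora at desk scale so that every other
module is testable end to end:

* each record carries a latent alignment quality ``q`` drawn uniformly
  from ``quality_range``; the template is the query with per-residue
  substitution probability ``1 - q`` (substitutions sampled with
  probability proportional to ``exp`` of the BLOSUM62 row, so identity
  and mean substitution score co-vary with ``q``), coverage tracks ``q``
  by trimming template coverage at the alignment ends, and the header
  e-value is ``10 ** (-100 * q * u)`` with ``u ~ U(0.8, 1.0)``;
* the GDT-TS label is ``logistic(6 (q - 1/2))`` plus Gaussian noise of
  standard deviation ``noise_sigma``, clipped to [0, 1] — an invented
  link whose sole purpose is to give parameter-recovery tests a known
  noise floor;
* structure pairs are smooth self-avoiding CA chains with 3.8 A
  consecutive spacing; the model copies the native with small thermal
  noise except for a contiguous segment covering a fraction
  ``1 - target_quality`` of residues, which is replaced by a freshly
  generated chain displaced 50 A away (replacing, not rigidly moving,
  the segment destroys its internal geometry so the displaced part
  cannot superpose onto its native counterpart).

One global seed drives everything; each record uses a deterministic
substream, so growing ``n`` never reshuffles earlier records.  None of
this mimics real CASP score distributions or e-value statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment_io import MultiAlignment, PairwiseAlignment
from .features import multi_features, pairwise_features
from .matrices import load_matrix
from .qa_model import LabeledDataset

__all__ = [
    "SimulationParams",
    "pairwise_alignment_at",
    "simulate_pairwise_dataset",
    "simulate_multi_dataset",
    "simulate_structure_pair",
    "simulate_end_to_end_dataset",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
CA_SPACING = 3.8  # Angstrom between consecutive CA atoms
DISPLACEMENT = 50.0  # Angstrom offset of the wrong segment
THERMAL_SIGMA = 0.2  # Angstrom per-coordinate noise on the good part


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic corpus generator.

    ``n`` records are produced; ``quality_range`` bounds the latent
    alignment quality; ``noise_sigma`` is the label noise standard
    deviation; ``n_res`` the residues per synthetic protein;
    ``n_templates`` the templates per multi-template alignment;
    ``models_per_target`` groups consecutive records under one pseudo
    target id so ranking has something to rank.
    """

    n: int = 500
    seed: int = 0
    quality_range: tuple[float, float] = (0.2, 0.9)
    noise_sigma: float = 0.05
    n_res: int = 60
    n_templates: int = 3
    models_per_target: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.quality_range
        if not (0 <= lo < hi <= 1):
            raise ValueError(f"quality_range must satisfy 0 <= lo < hi <= 1, got {self.quality_range}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_res < 10:
            raise ValueError("n_res must be >= 10")
        if self.n < 1 or self.n_templates < 1 or self.models_per_target < 1:
            raise ValueError("counts must be positive")


def _record_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _label(q: float, noise_sigma: float, rng: np.random.Generator) -> float:
    value = logistic(6.0 * (q - 0.5))
    if noise_sigma > 0:
        value += rng.normal(0.0, noise_sigma)
    return float(min(1.0, max(0.0, value)))


def _substitution_tables() -> np.ndarray:
    """Row-stochastic substitution table: P(b | a) ∝ exp(BLOSUM62[a, b]), b != a."""
    blosum = load_matrix("BLOSUM62")
    table = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        weights = np.array(
            [0.0 if b == a else math.exp(blosum.scores[(a, b)]) for b in AA_ORDER]
        )
        table[i] = weights / weights.sum()
    return table


_SUBST = None


def _subst() -> np.ndarray:
    global _SUBST
    if _SUBST is None:
        _SUBST = _substitution_tables()
    return _SUBST


def _mutate(query: np.ndarray, q: float, rng: np.random.Generator) -> np.ndarray:
    """Template residues: keep with probability q, else BLOSUM-weighted substitute."""
    out = query.copy()
    sub = _subst()
    for i in np.flatnonzero(rng.random(len(query)) >= q):
        out[i] = rng.choice(20, p=sub[query[i]])
    return out


def _coverage_window(n_res: int, q: float, rng: np.random.Generator) -> tuple[int, int]:
    """[start, stop) of the template-covered region, length ~ q * n_res."""
    length = max(3, int(round(q * n_res)))
    trim = n_res - length
    left = int(rng.integers(0, trim + 1)) if trim > 0 else 0
    return left, left + length


def pairwise_alignment_at(
    q: float, n_res: int, rng: np.random.Generator, index: int = 0
) -> PairwiseAlignment:
    """One pairwise alignment whose identity/coverage/e-value track quality ``q``."""
    query = rng.integers(0, 20, size=n_res)
    template = _mutate(query, q, rng)
    start, stop = _coverage_window(n_res, q, rng)
    q_row = "".join(AA_ORDER[a] for a in query)
    t_row = "".join(
        AA_ORDER[a] if start <= i < stop else "-" for i, a in enumerate(template)
    )
    u = float(rng.uniform(0.8, 1.0))
    evalue = 10.0 ** (-100.0 * q * u)
    return PairwiseAlignment(
        query_id=f"query_{index:04d}",
        template_id=f"tmpl_{index:04d}",
        query_row=q_row,
        template_row=t_row,
        evalue=evalue,
    )


def _simulate_pairwise_record(
    params: SimulationParams, index: int
) -> tuple[PairwiseAlignment, float, float]:
    rng = _record_rng(params.seed, index)
    lo, hi = params.quality_range
    q = float(rng.uniform(lo, hi))
    aln = pairwise_alignment_at(q, params.n_res, rng, index)
    label = _label(q, params.noise_sigma, rng)
    return aln, label, q


def _dataset_from(
    records, labels, params: SimulationParams, schema: str, feature_fn
) -> LabeledDataset:
    vectors = [feature_fn(rec) for rec in records]
    return LabeledDataset(
        record_ids=tuple(f"rec_{i:04d}" for i in range(len(records))),
        target_ids=tuple(
            f"T{i // params.models_per_target:03d}" for i in range(len(records))
        ),
        X=np.vstack([v.as_array() for v in vectors]),
        y=np.asarray(labels, dtype=float),
        schema=schema,
        feature_names=vectors[0].feature_names,
    )


def simulate_pairwise_dataset(
    params: SimulationParams, out_dir: str | Path | None = None
) -> tuple[list[PairwiseAlignment], LabeledDataset]:
    """Generate ``params.n`` pairwise alignments with GDT-TS-like labels.

    When ``out_dir`` is given, each alignment is also written as
    ``pairwise_<i>.fasta`` in the canonical dialect (query first, e-value
    in the template header).
    """
    blosum = load_matrix("BLOSUM62")
    alignments, labels = [], []
    for i in range(params.n):
        aln, label, _q = _simulate_pairwise_record(params, i)
        alignments.append(aln)
        labels.append(label)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, aln in enumerate(alignments):
            text = (
                f">{aln.query_id}\n{aln.query_row}\n"
                f">{aln.template_id} EVALUE={aln.evalue:.6e}\n{aln.template_row}\n"
            )
            (out_dir / f"pairwise_{i:04d}.fasta").write_text(text)
    dataset = _dataset_from(
        alignments, labels, params, "pairwise", lambda a: pairwise_features(a, blosum)
    )
    return alignments, dataset


def simulate_multi_dataset(
    params: SimulationParams, out_dir: str | Path | None = None
) -> tuple[list[MultiAlignment], LabeledDataset]:
    """Generate multi-template alignments: template rank r has quality q * 0.9^(r-1)."""
    blosum = load_matrix("BLOSUM62")
    gonnet = load_matrix("GONNET160")
    alignments, labels = [], []
    for i in range(params.n):
        rng = _record_rng(params.seed, i)
        lo, hi = params.quality_range
        q = float(rng.uniform(lo, hi))
        target = rng.integers(0, 20, size=params.n_res)
        rows = []
        for r in range(params.n_templates):
            q_r = q * 0.9**r
            template = _mutate(target, q_r, rng)
            start, stop = _coverage_window(params.n_res, q_r, rng)
            rows.append(
                (
                    f"tmpl_{i:04d}_{r + 1}",
                    "".join(
                        AA_ORDER[a] if start <= j < stop else "-"
                        for j, a in enumerate(template)
                    ),
                )
            )
        maln = MultiAlignment(
            target_id=f"target_{i:04d}",
            target_row="".join(AA_ORDER[a] for a in target),
            templates=tuple(rows),
        )
        alignments.append(maln)
        labels.append(_label(q, params.noise_sigma, rng))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, maln in enumerate(alignments):
            parts = [f">{maln.target_id}\n{maln.target_row}\n"]
            parts += [f">{tid}\n{row}\n" for tid, row in maln.templates]
            (out_dir / f"multi_{i:04d}.fasta").write_text("".join(parts))
    dataset = _dataset_from(
        alignments, labels, params, "multi", lambda a: multi_features(a, blosum, gonnet)
    )
    return alignments, dataset


def _smooth_chain(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding CA chain: persistent direction walk with 3.8 A steps."""
    coords = np.zeros((n_res, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, n_res):
        for _attempt in range(200):
            proposal = direction + 0.6 * rng.normal(size=3)
            proposal /= np.linalg.norm(proposal)
            candidate = coords[i - 1] + CA_SPACING * proposal
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - candidate, axis=1)) > 3.5:
                break
        coords[i] = candidate
        direction = proposal
    return coords


def simulate_structure_pair(
    n_res: int, target_quality: float, seed: int
) -> tuple["CAStructure", "CAStructure"]:
    """Native chain plus a model whose correct fraction is ``target_quality``.

    A contiguous segment of ``round((1 - target_quality) * n_res)``
    residues is replaced by a fresh chain offset 50 A from the native;
    the remaining residues get per-coordinate thermal noise of 0.2 A.
    """
    from .structscore import CAStructure  # local import to avoid a cycle

    if n_res < 10:
        raise ValueError("n_res must be >= 10")
    if not 0 <= target_quality <= 1:
        raise ValueError("target_quality must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    native_coords = _smooth_chain(n_res, rng)
    aas = tuple(AA_ORDER[a] for a in rng.integers(0, 20, size=n_res))
    numbers = np.arange(1, n_res + 1)

    n_wrong = int(round((1.0 - target_quality) * n_res))
    model_coords = native_coords + rng.normal(0.0, THERMAL_SIGMA, size=(n_res, 3))
    if n_wrong > 0:
        start = int(rng.integers(0, n_res - n_wrong + 1))
        wrong = _smooth_chain(max(n_wrong, 10), rng)[:n_wrong]
        offset_dir = rng.normal(size=3)
        offset_dir /= np.linalg.norm(offset_dir)
        anchor = native_coords.mean(axis=0) + DISPLACEMENT * offset_dir
        model_coords[start : start + n_wrong] = wrong - wrong.mean(axis=0) + anchor

    native = CAStructure(
        structure_id=f"native_{seed}",
        residue_numbers=numbers,
        amino_acids=aas,
        coords=native_coords,
    )
    model = CAStructure(
        structure_id=f"model_{seed}",
        residue_numbers=numbers.copy(),
        amino_acids=aas,
        coords=model_coords,
    )
    return native, model


def simulate_end_to_end_dataset(
    n: int,
    seed: int,
    struct_n_res: int = 40,
    aln_n_res: int = 60,
    quality_range: tuple[float, float] = (0.2, 0.9),
    models_per_target: int = 5,
) -> LabeledDataset:
    """Pairwise corpus whose labels are *computed* GDT-TS scores.

    Each record draws one latent quality ``q`` that drives both a
    pairwise alignment (features) and a structure pair; the label is the
    GDT-TS of the model against the native as computed by
    :mod:`aliqa.structscore` — the full label-generation path a real
    corpus would take, with no closed-form label link involved.
    """
    from .structscore import gdt_ts

    blosum = load_matrix("BLOSUM62")
    lo, hi = quality_range
    vectors, labels = [], []
    for i in range(n):
        rng = _record_rng(seed, i)
        q = float(rng.uniform(lo, hi))
        aln = pairwise_alignment_at(q, aln_n_res, rng, i)
        struct_seed = (seed * 1009 + 7 * i + 1) % (2**31)
        native, model = simulate_structure_pair(struct_n_res, q, seed=struct_seed)
        labels.append(gdt_ts(model, native).gdt_ts)
        vectors.append(pairwise_features(aln, blosum))
    return LabeledDataset(
        record_ids=tuple(f"rec_{i:04d}" for i in range(n)),
        target_ids=tuple(f"T{i // models_per_target:03d}" for i in range(n)),
        X=np.vstack([v.as_array() for v in vectors]),
        y=np.asarray(labels, dtype=float),
        schema="pairwise",
        feature_names=vectors[0].feature_names,
    )
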