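"""Embedded amino-acid substitution matrices.

Two symmetric score tables over the 20 standard residues are shipped as
plain-text data files inside the package:

``BLOSUM62``
    The Henikoff & Henikoff (1992) BLOSUM62 matrix in half-bit units, the
    default of the BLAST family of alignment tools.
``GONNET160``
    The Gonnet/Cohen/Benner (1992) exhaustive-matching matrix in 1/10
    units.  The embedded file is the single source of truth for Gonnet
    scoring in this package.

Non-standard residue letters (B, Z, X, U, O, ...) are rejected rather than
scored zero, so a corrupted alignment cannot silently bias a feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = [
    "STANDARD_AA",
    "SubstitutionMatrix",
    "UnsupportedResidueError",
    "load_matrix",
    "lookup_score",
]

#: The 20 standard amino acids, one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

MATRIX_IDS = ("BLOSUM62", "GONNET160")


class UnsupportedResidueError(ValueError):
    """Raised when a residue letter outside the 20 standard amino acids is scored."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric amino-acid pair score table.

    Parameters
    ----------
    matrix_id
        ``"BLOSUM62"`` or ``"GONNET160"``.
    scores
        Mapping from ordered residue pair to score; populated for both
        orderings of every pair so lookup is symmetric by construction.
    """

    matrix_id: str
    scores: dict[tuple[str, str], float] = field(repr=False)

    @property
    def min_score(self) -> float:
        return min(self.scores.values())

    @property
    def max_score(self) -> float:
        return max(self.scores.values())

    def score(self, aa1: str, aa2: str) -> float:
        return lookup_score(self, aa1, aa2)


def _parse_matrix_file(text: str) -> dict[tuple[str, str], float]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    columns = lines[0].split()
    scores: dict[tuple[str, str], float] = {}
    for row in lines[1:]:
        fields = row.split()
        aa1, values = fields[0], fields[1:]
        for aa2, value in zip(columns, values, strict=True):
            scores[(aa1, aa2)] = float(value)
    expected = {(a, b) for a in STANDARD_AA for b in STANDARD_AA}
    if set(scores) != expected:
        raise ValueError("matrix file does not cover the 20 standard residues")
    return scores


@lru_cache(maxsize=None)
def load_matrix(matrix_id: str) -> SubstitutionMatrix:
    """Load an embedded substitution matrix by id.

    Raises
    ------
    ValueError
        If ``matrix_id`` is not one of the embedded matrices.
    """
    if matrix_id not in MATRIX_IDS:
        raise ValueError(f"unknown matrix id {matrix_id!r}; available: {MATRIX_IDS}")
    text = resources.files("aliqa.data").joinpath(f"{matrix_id}.txt").read_text()
    return SubstitutionMatrix(matrix_id=matrix_id, scores=_parse_matrix_file(text))


def lookup_score(matrix: SubstitutionMatrix, aa1: str, aa2: str) -> float:
    """Return the substitution score for a residue pair (symmetric in its arguments)."""
    for aa in (aa1, aa2):
        if aa not in STANDARD_AA:
            raise UnsupportedResidueError(
                f"unsupported residue {aa!r}: only the 20 standard amino acids are scored"
            )
    return matrix.scores[(aa1, aa2)]
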