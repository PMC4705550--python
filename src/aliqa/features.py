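"""Alignment-derived input features for model quality prediction.

Two feature schemes, one per alignment kind:

pairwise (query vs. one template)
    ``f_evalue``    normalized alignment e-value in [0, 1] (see
                    :func:`normalize_evalue`);
    ``f_identity``  fraction of aligned positions with identical residues;
    ``f_coverage``  fraction of query residues aligned to a template residue;
    ``f_blosum``    mean BLOSUM62 score over aligned positions.

multi (target vs. ranked templates)
    ``f_coverage``  fraction of target residues aligned to a residue in at
                    least one template;
    ``f_identity``  fraction of those aligned target residues matched
                    identically by *any one* template;
    ``f_blosum``    mean BLOSUM62 score over aligned target residues, the
                    partner being the residue of the highest-ranked
                    template with a residue in that column;
    ``f_gonnet``    as ``f_blosum`` with the Gonnet table.

Note the two multi rules differ deliberately: identity may be satisfied by
any template, while the substitution scores always take the rank-precedence
residue.  Features are emitted raw; min-max scaling for the SVR lives with
the trained model so that a stored model is self-contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment_io import GAP, MultiAlignment, PairwiseAlignment
from .matrices import SubstitutionMatrix, lookup_score

__all__ = [
    "EmptyAlignmentError",
    "PairwiseFeatureVector",
    "MultiFeatureVector",
    "normalize_evalue",
    "pairwise_features",
    "multi_features",
]

#: Floor applied to e-values before taking the logarithm; PSI-BLAST
#: underflow (an e-value printed as exactly 0) is treated as this floor.
EVALUE_FLOOR = 1e-100


class EmptyAlignmentError(ValueError):
    """Raised when an alignment contains no aligned residue pair to score."""


@dataclass(frozen=True)
class PairwiseFeatureVector:
    f_evalue: float
    f_identity: float
    f_coverage: float
    f_blosum: float

    schema = "pairwise"
    feature_names = ("f_evalue", "f_identity", "f_coverage", "f_blosum")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_evalue, self.f_identity, self.f_coverage, self.f_blosum])


@dataclass(frozen=True)
class MultiFeatureVector:
    f_coverage: float
    f_identity: float
    f_blosum: float
    f_gonnet: float

    schema = "multi"
    feature_names = ("f_coverage", "f_identity", "f_blosum", "f_gonnet")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_coverage, self.f_identity, self.f_blosum, self.f_gonnet])


def normalize_evalue(evalue: float | None) -> float:
    """Map an alignment e-value onto a bounded significance scale.

    The raw e-value spans hundreds of orders of magnitude, so the feature
    is ``-log10(e)`` clamped to [0, 100] and divided by 100: 1.0 at
    e <= 1e-100 (saturated significance), 0.0 at e >= 1.  An e-value of
    exactly 0 (reported by PSI-BLAST on underflow) is treated as 1e-100.
    """
    if evalue is None:
        raise ValueError("pairwise scheme requires an e-value")
    if evalue < 0:
        raise ValueError(f"e-value must be non-negative, got {evalue}")
    clamped = min(max(evalue, EVALUE_FLOOR), 1.0)
    return min(1.0, max(0.0, -math.log10(clamped) / 100.0))


def pairwise_features(
    aln: PairwiseAlignment, matrix: SubstitutionMatrix
) -> PairwiseFeatureVector:
    """Compute the four pairwise-scheme features from a query/template alignment."""
    pairs = [
        (q, t)
        for q, t in zip(aln.query_row, aln.template_row)
        if q != GAP and t != GAP
    ]
    if not pairs:
        raise EmptyAlignmentError(
            f"empty alignment: no aligned residue pairs in {aln.query_id}/{aln.template_id}"
        )
    n_aligned = len(pairs)
    n_query = len(aln.query_row.replace(GAP, ""))
    identical = sum(q == t for q, t in pairs)
    blosum_sum = sum(lookup_score(matrix, q, t) for q, t in pairs)
    return PairwiseFeatureVector(
        f_evalue=normalize_evalue(aln.evalue),
        f_identity=identical / n_aligned,
        f_coverage=n_aligned / n_query,
        f_blosum=blosum_sum / n_aligned,
    )


def multi_features(
    maln: MultiAlignment,
    blosum: SubstitutionMatrix,
    gonnet: SubstitutionMatrix,
) -> MultiFeatureVector:
    """Compute the four multi-scheme features from a target/templates alignment.

    A target residue aligned in several templates is scored against the
    highest-ranked template holding a residue in that column; identity is
    granted if any template matches.
    """
    n_target = 0
    n_aligned = 0
    n_identical = 0
    blosum_sum = 0.0
    gonnet_sum = 0.0
    for col, target_aa in enumerate(maln.target_row):
        if target_aa == GAP:
            continue
        n_target += 1
        column = [row[col] for _, row in maln.templates if row[col] != GAP]
        if not column:
            continue
        n_aligned += 1
        if target_aa in column:
            n_identical += 1
        precedence_aa = column[0]  # templates are stored in rank order
        blosum_sum += lookup_score(blosum, target_aa, precedence_aa)
        gonnet_sum += lookup_score(gonnet, target_aa, precedence_aa)
    if n_aligned == 0:
        raise EmptyAlignmentError(
            f"no aligned target residues in alignment {maln.target_id}"
        )
    return MultiFeatureVector(
        f_coverage=n_aligned / n_target,
        f_identity=n_identical / n_aligned,
        f_blosum=blosum_sum / n_aligned,
        f_gonnet=gonnet_sum / n_aligned,
    )
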