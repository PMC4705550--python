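# Methods

## Problem and model

`aliqa` estimates the accuracy of a template-based protein structure
model from the sequence alignment that produced it.  The response is
GDT-TS on the 0–1 scale; the predictor is an ε-support-vector regressor
with RBF kernel.  The assumption doing the work is that alignment-level
signals — statistical significance, residue identity, coverage,
substitution-score conservation — carry most of the information about
how good the resulting model can be, so a low-dimensional feature vector
(four features per scheme) suffices.

## Feature definitions and their edge cases

Pairwise scheme (query + one template + e-value):

* `f_evalue = min(1, max(0, −log₁₀(clamp(e, 1e−100, 1)) / 100))`.
  E-values span hundreds of orders of magnitude, so the feature is the
  negative decimal log, saturated at 10⁻¹⁰⁰ and rescaled to [0, 1].  An
  e-value of exactly 0 (search-tool underflow) is treated as 10⁻¹⁰⁰ and
  maps to 1.0; e-values above 1 map to 0.0 rather than going negative.
  A missing e-value is an error in this scheme, not a default.
* `f_identity` = identical pairs / aligned positions.  The denominator
  is the number of *aligned* positions, not the query length — coverage
  already carries the length normalization, keeping the two features
  non-redundant.
* `f_coverage` = aligned positions / query residues (gaps excluded).
* `f_blosum` = mean BLOSUM62 score over aligned pairs.

Multi-template scheme (target + templates in significance rank order):

* `f_coverage` = target residues aligned in ≥1 template / target
  residues;
* `f_identity` = aligned target residues matched identically by *any*
  template / aligned target residues;
* `f_blosum`, `f_gonnet` = mean substitution score taking, per column,
  the residue of the *highest-ranked* template present there.

The identity rule (any template) and the scoring rule (rank precedence)
deliberately differ; the test-suite fixture target `AC` vs `AD`/`AC`
pins the distinction.  An alignment with zero aligned positions raises
an error rather than emitting NaNs, and non-standard residue letters
(B, Z, X, U, O) are rejected rather than scored 0, so degraded inputs
cannot silently bias features.

Substitution tables: BLOSUM62 (half-bit units) and the Gonnet/Cohen/
Benner 1992 matrix (1/10 units) are embedded as plain-text files in
`src/aliqa/data/`; the embedded files are the single source of truth,
and data-integrity tests assert symmetry, completeness over the 210
residue pairs, and BLOSUM62 diagonal dominance.

## GDT-TS scorer

Labels come from GDT-TS between model and native CA traces.  Residues
are paired by residue number (a mismatch in amino-acid type warns but
does not fail, since models occasionally renumber); the denominator is
the *native* length, so incomplete models are penalized.  For each
cutoff (1, 2, 4, 8 Å) the scorer runs a seeded search: seed windows of
length 3, 5 and 7 slide along the chain (plus the full common set and,
on chains of ≤ 20 common residues, every residue triple); each seed is
superposed by least-squares (Kabsch, SVD with a proper-rotation
correction), the residues within the cutoff are selected, and selection
and superposition iterate to a fixed point (≤ 10 rounds).  At every
superposition, distance-sorted prefixes of the residue list are also
tried as candidates — all prefixes on small chains, prefixes reaching at
most 2× the cutoff on larger ones.  Every candidate selection is
*verified* (superposing on the selection must keep all its members
within the cutoff) before it can be counted, so the reported fraction is
always attained by an actual superposition and can never exceed the
exact subset maximum.  Cutoffs are searched in ascending order with the
best selection carried forward as a seed, which makes
p1 ≤ p2 ≤ p4 ≤ p8 hold by construction.  On instances small enough for
exhaustive subset enumeration the search recovers the exact maximum
(asserted in the tests against a brute-force oracle); on larger chains
it is a heuristic in the LGA tradition and may in principle undershoot.

## Regressor

Features are min-max scaled to [0, 1] using training-data extremes
(stored in the model artifact) because the mean-substitution features
have a different dynamic range than the [0, 1] features and RBF kernels
are scale-sensitive.  Fitting is delegated to libsvm via scikit-learn;
prediction is computed from the stored support vectors and dual
coefficients by the package's own kernel code, so a saved model
(versioned single-file JSON, `aliqa-model/1`) predicts bit-identically
after reload.  Predictions are clipped to [0, 1].

Hyperparameter search: k-fold cross-validation over the default grids —
pairwise: w ∈ {0.5, 0.2, 0.1, 0.05, 0.02, 0.01}, c ∈ {2.0, 1.0, 0.5,
0.1, 0.05, 0.01}, g ∈ {0.5, 0.3, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001}
with k = 5; multi: w ∈ {0.1, 0.08, 0.06, 0.05, 0.02, 0.01}, same c
grid, g ∈ {0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001} with
k = 10.  Scaling is refit inside each training fold (no leakage).  The
winner is the lowest mean held-out RMSE; ties break by lower mean
absolute error, then smaller g, smaller c, larger w — preferring the
smoother, less regularized, wider-tube model among equals.  Fold
assignment is a seeded random permutation of records; because
alignments of one target are correlated, an optional group-by-target
mode keeps each target's records in a single fold.  Neither mode is
claimed to be more than a design choice.  A `repeats` option averages
the CV score over several fold assignments (seeds seed, seed+1, …).

## Evaluation statistics

RMSE and "ABS" (mean absolute error) between predicted and real scores;
Pearson correlation is reported as undefined when either vector is
constant.  Top-1 ranking selects, per target, the record with the
highest predicted score (ties broken by lexicographically smallest
record id for reproducibility) and sums the real scores of the picks.
Method comparison uses paired two-sided tests: Student's t on the
per-target differences, and the Wilcoxon signed-rank test with
Wilcoxon's drop-zeros rule and midranks for ties.  The exact Wilcoxon
p-value (≤ 25 non-zero pairs) is computed from the full null
distribution of the positive-rank sum via dynamic programming over
doubled midranks — equivalent to enumerating all 2^m sign assignments,
which the tests verify against a literal enumeration oracle — and a
normal approximation with continuity and tie correction is used above
that.  Two-sided p-values are the conservative default.

## Synthetic corpora

The generator stands in for a real structure-prediction corpus.  Each
record draws a latent quality q ~ U(0.2, 0.9) (defaults); the template
is the query with per-residue substitution probability 1 − q,
substitutions sampled ∝ exp(BLOSUM62 row score) so identity and mean
substitution score co-vary with q; coverage tracks q by trimming
template coverage at the alignment ends; the header e-value is
10^(−100·q·u), u ~ U(0.8, 1.0).  The label is logistic(6(q − ½)) plus
Gaussian noise (σ = 0.05 default), clipped to [0, 1] — an invented link
whose only purpose is to give parameter-recovery tests a known noise
floor.  Multi-template records decay template quality by rank
(q_r = q·0.9^(r−1)).  Defaults (500 records, 60 residues, 3 templates,
5 models per pseudo-target) echo the scale of a single-experiment
corpus of a few hundred alignments.

Structure pairs are smooth self-avoiding CA chains with 3.8 Å spacing;
the model copies the native with 0.2 Å thermal noise except for a
contiguous segment covering a fraction 1 − q of residues, which is
*replaced by a freshly generated chain* displaced 50 Å away.  Replacing
(rather than rigidly moving) the segment matters: a rigidly displaced
block keeps its internal geometry and would superpose onto its native
counterpart by itself, driving GDT-TS towards max(q, 1 − q) instead of
q.  With replacement, computed GDT-TS tracks the dialled quality with
Pearson r ≥ 0.95 across q ∈ [0.2, 0.9] (asserted in tests).

One global seed drives everything; each record uses a deterministic
substream (`SeedSequence(seed, spawn_key=(i,))`), so growing n never
reshuffles earlier records.

What the generator does *not* emulate: real e-value statistics of any
search tool, realistic amino-acid composition or indel structure,
correlated errors between alignments of one target, or CASP-like score
distributions.  Passing tests therefore demonstrate the machinery —
feature definitions, search correctness, tuning, statistics — not
field performance on real corpora.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale chosen to
exercise every code path: corpora of 100–500 alignments, chains of
10–60 residues, 200 structure pairs for the end-to-end check, the full
288-point pairwise grid with 5-fold CV.  Exhaustive GDT verification is
limited to ≤ 15-residue instances where subset enumeration is exact.
SVR solver tolerance is 1e-4; Kabsch uses double-precision SVD with the
determinant sign correction; GDT feasibility uses a hard ≤ cutoff
comparison in Å.  File formats are deliberately minimal: gapped
multi-FASTA with `-` as the only gap character ('.' is rejected), an
`EVALUE=` token in the template header as the one e-value channel, TSV
feature tables with `repr`-precision floats so round-trips are lossless,
and PDB fixed-width ATOM records for structures.

## Known limitations

* The GDT search is exact only where exhaustively verified; for long
  chains it remains a heuristic and its fractions are lower bounds of
  the exact subset maximum.
* The Gonnet table is shipped at its published 1992 scaling; no
  PAM160-specific rescaling is applied, and all Gonnet-dependent numbers
  are keyed to the embedded file.
* Grouped cross-validation reduces, but does not remove, optimism when
  many alignments share a target.
* The alignment dialect deliberately refuses files with columns gapped
  in every row and alignments without any aligned position, so some
  tool outputs need trivial cleanup before ingestion.
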