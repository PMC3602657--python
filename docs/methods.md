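# Methods

## Overview

`dbpred` frames DNA-binding protein prediction as binary classification of
fixed-length descriptor vectors derived from the amino-acid sequence and
three optional per-residue profile sources. The design premise is that
protein properties informative for DNA binding live at different sequence
scales: global composition patterns, nonlocal residue–residue coupling, and
local (terminal/regional) signals. Every profile source is therefore
encoded three ways — OCTD (global), autocovariance (nonlocal), and
region averaging (local) — rather than committing to one representation.

## Descriptor blocks and dimensions

| block | dimension | input |
|---|---|---|
| OAAC | 20 | sequence |
| DPC (raw → selected) | 1200 → 400 | sequence |
| SAAC | 120 | sequence |
| AAIndex-OCTD / -AC / -SAA | 364 / 252 / 168 | 28 property tracks |
| PSSM-OCTD / -AC / -SAA | 260 / 220 / 120 | 20 log-odds tracks |
| S&F-OCTD / -AC / -SAA | 52 / 40 / 24 | 4 structure/disorder tracks |

Total with DPC at 400: **2040**. The raw feature matrix keeps DPC at 1200
and the 400-of-1200 reduction is refit inside each training fold, because
selecting the subset once on the full data would leak test information into
the schema. The selected name list is persisted with the model and applied
verbatim at prediction time.

## Key formulas and conventions

- **OAAC / SAAC**: *f_i* = √(*n_i*/*L*). The square root flattens the
  frequency distribution and makes Σ *f_i*² = 1 a per-block identity that
  the tests assert.
- **DPC**: *f_s*(*i*,*j*) = *D_s*(*i*,*j*)/(*L*−1) for all skip levels
  *s* ∈ {0, 1, 2}. The denominator is deliberately *L*−1 for every *s*,
  although only *L*−1−*s* pairs exist for *s* > 0; consequently
  Σ *f_s* = (*L*−1−*s*)/(*L*−1), which the suite uses as a counting oracle.
- **OCTD**: per protein and per track, values are min-max normalized and
  positions assigned to group A if ≤ 0.5, else B. Ties at exactly 0.5 go
  to A; a constant track (zero range) puts all positions in A — a
  deterministic, testable degenerate rule. The distribution slots report
  the chain position (as a fraction of *L*) of the 1st and the
  ⌈*r·n_g*⌉-th group member for *r* = 0.25/0.5/0.75/1; an empty group
  yields five zeros. Because of the internal normalization, OCTD is
  invariant to positive affine rescaling of any track, which is why a
  surrogate AAIndex calibration does not change its behaviour.
- **AC**: mean-centered lag products normalized by *L*−*lg*. Maximum lags
  are per-source: 9 (AAIndex), 11 (PSSM), 10 (S&F). A sequence must satisfy
  *L* ≥ *LG*+1 or the descriptor is undefined (reported as an error naming
  the protein, never silently padded).
- **SAA regions** (d_N = 25, d_M ≥ 20, d_C = 10): for *L* ≥ 130, four
  N-terminal windows of 25, middle to *L*−10, C-tail of 10. For
  110 < *L* < 130 the middle is the 20 residues immediately before the
  C-tail and may overlap the fourth N window — the geometry forces the
  overlap, and accepting it keeps every block dimension fixed. For
  *L* ≤ 110 the N part is a single window of ⌊(*L*−10)/2⌋ residues
  duplicated into all four N slots; duplication is our convention for
  keeping the 6-region schema and fixed dimensionality on short sequences.
- **Minimum length 31**: guarantees every descriptor is defined (AC needs
  *L* ≥ 12; the short-sequence region split needs non-empty N/M/C parts).
  This floor is a package choice, configurable per call.

## Feature selection

mRMR discretizes each feature into three states at mean ± *t*·std
(*t* = 1, population standard deviation — matching the reference mRMR
convention; both *t* and the ddof are parameters). Mutual information is
the plug-in estimator in bits. The ranking is greedy MID ("difference"):
step *m*+1 maximizes I(*f*; class) − (1/*m*) Σ I(*f*; *f_s*) over selected
*s*, with ties broken toward the smaller column index so rankings are
reproducible. Because discretization is per-feature standardized, the
ranking is invariant to affine feature rescaling.

One consequence worth knowing: a balanced two-valued feature (e.g. a
literal copy of the labels) has both values strictly inside the mean ± std
band and discretizes to a constant, i.e. zero measured relevance. The
discretization is designed for continuous descriptors; the test suite uses
strongly class-shifted continuous features for its maximal-relevance
checks.

IFS evaluates growing prefixes of the ranking (step configurable). Each
prefix is scored by stratified 5-fold CV: the (C, γ) pair with highest mean
accuracy over the grid is chosen and its mean per-fold MCC becomes the
curve value — the same CV both tunes and scores, as in the standard
LIBSVM-style workflow, so the curve is mildly optimistic; the unbiased
estimate is the outer-CV report. The optimal prefix is the smallest one
attaining the curve maximum (parsimony tie-break).

## Modeling

Features are scaled to [0, 1] by (value−min)/(max−min) with the training
split's extrema; test-time values are clipped into [0, 1] and zero-range
features map to 0. The classifier is an RBF SVM (scikit-learn's libsvm
binding). The default grid is C = 2⁻⁵..2¹⁵, γ = 2⁻¹⁵..2³ in steps of 2²;
`fast_grid()` is a coarse 2×2 sub-grid used by the simulations and tests.
Folds are stratified with a fixed, recorded seed. CV metrics are the
average of per-fold values (pooled confusion counts available via
`pool_reports`). MCC with a zero denominator factor is reported as 0 with a
logged warning; AUC is computed from decision values.

## Ensemble

Twelve per-block SVMs are combined by majority voting — binding iff
strictly more than 6 of 12 votes, so a 6–6 tie resolves to non-binding
(ties were observed to be predominantly non-binding; the threshold is
configurable for the other reading) — or by stacking, where a meta RBF-SVM
consumes the twelve base decision values. Meta-training uses out-of-fold
decision values from an internal stratified 5-fold so the meta-learner
never sees a decision value produced by a model trained on the same
sample; the base models are then refit on the full training data. The
voting combiner's "decision value" is the vote-count margin, which gives
it a (coarse) AUC.

## Synthetic data

The generator emulates the pipeline's inputs, not protein biophysics:

- sequences of length uniform on [50, 350] with i.i.d. residues; the
  positive class adds δ (default 0.15) of probability mass split over
  K/R/F — the residue types enriched at DNA-contacting positions — with
  the remaining letters renormalized; δ = 0 makes the classes exchangeable;
- PSSMs as one-hot(emitting residue)·7 plus integer noise on [−2, 2],
  written in the PSI-BLAST ASCII dialect, preserving the
  profile/sequence-consistency property the readers enforce;
- secondary structure as per-residue coil/helix/strand states (base
  probabilities 0.5/0.3/0.2; the positive class moves 0.10 from coil to
  helix), with Dirichlet-concentrated confidence rows;
- disorder scores i.i.d. Beta with mean 0.35 (+0.10 for positives) and
  concentration 8 — a unimodal [0, 1] family chosen for simplicity.

All draws come from one seeded generator, so equal configs produce
byte-identical files. What passing tests show: the pipeline recovers
planted class differences of the kinds it encodes (composition, helix
fraction, disorder level) and stays at chance on exchangeable classes.
What they do not show: performance on real proteomes — real sequences have
autocorrelated composition, domain structure and evolutionary profile
correlations that i.i.d. emission does not emulate, and the published
benchmark accuracies depend on curated PDB/Swiss-Prot sets and real
PSI-BLAST/PSIPRED/IUPred runs that are outside this package's scope.

## Problem sizes used by the checks

The statistical checks run the full protocol at simulation sizes chosen to
make their assertions well-powered while staying cheap: null and
planted-signal runs use 100 proteins per class with mRMR depth 30, IFS
step 5 and the coarse grid; the δ-monotonicity check uses 50 proteins per
class on the sequence-derived blocks (median over 3 seeds across
δ ∈ {0, 0.05, 0.15, 0.30}); the ensemble comparison uses 20–30 per class.
The full-scale settings (mRMR depth 1000, IFS step 1, full grid) remain
the library defaults.

## Known limitations

- The bundled AAIndex table is a synthetic surrogate (see
  `dbpred.aaindex_synthetic`); supply a genuine table for interpretable
  AAIndex feature names.
- PSSM log-odds are used raw as AC/SAA inputs (OCTD normalizes
  internally); the original workflow may have rescaled them — exposed by
  supplying transformed profiles if desired.
- Whether OCTD should normalize AAIndex values once over the 20 residue
  types (globally) instead of per protein is ambiguous; per-protein was
  chosen for determinism and testability.
- IFS curve values are tuning-coupled (see above); trust the outer-CV
  report for generalization estimates.
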