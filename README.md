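# dbpred — sequence-based prediction of DNA-binding proteins

DNA-binding proteins (transcription factors, polymerases, histones,
nucleases, ...) are central to replication and transcription, but
experimental identification is slow and structure-based predictors cannot
run proteome-wide. `dbpred` implements a purely sequence-based protocol for
classifying a protein as DNA-binding or non-binding, aimed at
bioinformaticians who have FASTA sequences and, optionally, standard
per-residue profiles (PSI-BLAST PSSMs, PSIPRED secondary structure, IUPred
disorder).

## The method

Each protein of length *L* is described by four feature families encoded at
three sequence scales, giving twelve descriptor blocks:

**Composition (from the sequence itself)**

- *OAAC* (20): square-root residue frequencies, *f_i* = √(*n_i*/*L*), so
  Σ *f_i*² = 1.
- *DPC* (1200 → 400): dipeptide counts at skip distances *s* = 0, 1, 2,
  *f_s*(*i*,*j*) = *D_s*(*i*,*j*)/(*L*−1); the 1200 raw features are reduced
  to the 400 top-ranked by mRMR on training data.
- *SAAC* (120): square-root composition computed separately in six regions —
  four 25-residue N-terminal windows, a middle part, and a 10-residue
  C-terminal tail (with short-sequence fallbacks).

**Property tracks** — 28 AAIndex physicochemical scales, the 20×*L* PSSM
log-odds, and 4 structural/functional tracks (coil/helix/strand confidence
+ disorder score) — each transformed three ways:

- *OCTD* (global, 13 values/track): min-max normalize the track within the
  protein, split positions into two groups at 0.5, and report group
  composition, transition frequency along the chain, and the chain positions
  of the first and 25/50/75/100% occurrences of each group.
- *AC* (nonlocal, *LG* values/track): autocovariance
  AC(*i*, *lg*) = Σ_j (*S_{i,j}* − *S̄_i*)(*S_{i,j+lg}* − *S̄_i*)/(*L*−*lg*)
  at lags 1..*LG*, with *LG* = 9 / 11 / 10 for AAIndex / PSSM / S&F tracks.
- *SAA* (local, 6 values/track): the track mean over the six regions above.

With DPC at its selected 400, the twelve blocks total **2040 features**.
Two final models are built on [0, 1]-scaled features:

1. **mRMR-IFS + SVM** — features are ranked by minimum-redundancy
   maximum-relevance (mutual information on a 3-state mean±std
   discretization, MID criterion), growing prefixes of the ranking are
   scored by 5-fold cross-validated MCC, and the peak prefix trains one
   RBF-SVM tuned by (C, γ) grid search;
2. **ensemble** — one RBF-SVM per block, combined by majority voting
   (binding iff > 6 of 12 votes) or by stacking (a meta-SVM on the twelve
   out-of-fold decision values).

Note on AAIndex: the genuine AAIndex numeric tables are not redistributed;
the package ships a clearly labelled synthetic surrogate
(`dbpred.aaindex_synthetic`) keyed by the real accession IDs, and
`encode_aaindex` accepts a user-supplied real table. All transforms are
invariant to each scale's calibration, so only the biological reading of
individual AAIndex features depends on the genuine values.

## Worked example

No external tools are needed: the built-in simulator writes sequences plus
surrogate profile files in the exact dialects the readers consume.

```bash
dbp simulate --n-per-class 15 --delta 0.3 --seed 4 --out data
dbp train --fasta data/sequences.fasta --labels data/labels.tsv \
    --profiles data/profiles --strategy mrmr-ifs \
    --top-k 15 --step 5 --max-features 15 --seed 4 --out model
dbp predict --fasta data/sequences.fasta --profiles data/profiles \
    --model model/model.joblib --out pred.tsv
dbp evaluate --predictions pred.tsv --labels data/labels.tsv
```

The last command prints the six evaluation indices:

```
Acc     1.000
AUC     1.000
F-score 1.000
Sen     1.000
Sp      1.000
MCC     1.000
```

Here `--delta 0.3` plants a large compositional difference (extra K/R/F
mass in the positive class), so the model separates the classes perfectly —
predictions are on the training proteins, and the CV report written to
`model/cv_report.tsv` is the honest generalization estimate. `model/`
also contains the IFS curve (TSV + PNG) and the persisted model archive.

Feature names follow `block:track:slot`, e.g. `OAAC:K`, `DPC:s1:AC`
(skip-1 dipeptide A→C), `SAAC:r3:K`, `PSSM-AC:R:lg3`,
`AAIndex-OCTD:CIDH920103:D_B_75`.

As a library:

```python
from dbpred import SyntheticConfig, generate_dataset, featurize, pipeline
ds = generate_dataset(SyntheticConfig(n_per_class=50, delta=0.3, seed=7))
X, schema = featurize(ds.records, ds.track_sets())
y = pipeline.labels_vector(ds.records)
result = pipeline.run_feature_selection_protocol(X, y, schema, top_k=30, step=5)
print(result.cv_report)   # averaged 5-fold Acc/AUC/F-score/Sen/Sp/MCC
```

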