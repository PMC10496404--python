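# Methods

## Problem and model

`gutshield` classifies small molecules as **anti-commensal** (label 1: the
compound inhibits growth of at least one representative human gut bacterial
strain) or **commensal** (label 0: it inhibits none). The classifier is a
QSAR consensus model built in four stages:

1. **Data preparation.** Input structures are cleaned by two rules: of a
   disconnected structure, only the largest organic fragment (most heavy
   atoms among carbon-containing fragments; ties broken by molecular weight,
   then canonical SMILES) is retained, and compounds containing elements
   outside a whitelist (H, C, N, O, P, S, F, Cl, Br, I by default,
   configurable) are rejected. Charges and stereo flags are kept as given.
   Labels may be derived from a strain-inhibition count: label 1 iff the
   compound inhibits ≥ 1 strain.
2. **Characterization sets.** Six fingerprints (MACCS 166 keys; an 881-bit
   PubChem-width keyed fingerprint; circular ECFP4/ECFP6 folded to 1024 and
   2048 bits) crossed with descriptor panels {none, 13MD, RDMD} give 18
   characterization sets; a third panel slot (a pretrained-embedding panel,
   CCMD) is exposed as a plugin interface and reported unavailable otherwise,
   which is what completes the 24-set grid. Descriptor columns are min–max
   scaled, x* = (x − x_min)/(x_max − x_min), with extrema always fitted on
   training rows only; external values clip to [0, 1]; constant columns map
   to 0; missing values are imputed with training medians (never by dropping
   rows, so split sizes stay fixed).
3. **Model selection by voting.** The labeled set is split 18 times into
   stratified random 8:2 train/validation partitions (split *i* seeded
   `base_seed + i`). Every (split × characterization set × algorithm) cell is
   tuned by stratified 5-fold cross-validation repeated 10 times over a small
   hyperparameter grid; the grid point with the highest mean F1 wins the
   cell (AUC is recorded alongside; undefined metrics never win). Per split,
   each characterization set credits its best algorithm — exact F1 ties split
   the credit — and the algorithm with the largest total credit wins. With
   the algorithm fixed, each split names its best characterization set and
   the modal set wins (modal ties break toward higher mean F1).
4. **Consensus.** One member model per split is trained on that split's
   training portion with its tuned hyperparameters. The consensus score of a
   molecule is the arithmetic mean of the member probabilities, thresholded
   at 0.5. A label-vote mode is available behind a flag; probability
   averaging was chosen as the default because it subsumes majority vote at
   threshold 0.5 for odd ensembles and produces smoother score distributions.

**Evaluation metrics.** SE = TP/(TP+FN), SP = TN/(TN+FP), ACC, MCC, F1 =
2TP/(2TP+FP+FN), and tie-aware rank AUC (the normalized Mann–Whitney U).
Zero-denominator cases return NaN ("undefined"), which always loses model
comparisons. F1 is the selection criterion throughout; AUC is reported
alongside.

**Internal vs external validation of the consensus.** Internal metrics
aggregate each member's own tuned cross-validation metrics across the 18
splits (mean ± sd). External metrics are computed by letting member *i*
predict only its own held-out 20% — the one evaluation in which no
evaluated compound ever entered the evaluating model's training set — again
aggregated across splits. Averaging *all* members' probabilities on split
*i*'s hold-out would leak, because the other 17 members saw most of those
compounds in training; the full probability-averaging consensus is therefore
reserved for genuinely new molecules at deployment. An explicit leakage
guard raises if any validation id appears in its member's training ids.

## Applicability domain

A compound is in-domain when its Euclidean distance to the training-set
centroid, in the scaled feature space of the winning characterization set,
does not exceed the empirical 99th percentile (linear interpolation) of the
training compounds' own distances. By construction, training-set coverage is
99% up to ties and interpolation, which the acceptance script verifies at
n = 1,000. A k-nearest-neighbour variant (mean distance to the k nearest
training compounds, leave-self-out for the cutoff) is available via
`fit_ad(..., method="knn")` for users who prefer a local density criterion.

## Structural alerts

Candidate fragments come from a bundled dictionary of 4,860 SMARTS patterns
with the cardinality and bit semantics of the Klekota–Roth fragment set.
The published pattern list is not redistributable here, so the bundled
dictionary is a **synthetic stand-in**, generated deterministically from
curated functional-group/heterocycle patterns plus combinatorial
substituted-ring and heteroatom-chain families (`gutshield.smartskeys`);
pattern identity with the published set is not claimed. The 881-bit
PubChem-width fingerprint is likewise a keyed stand-in (element/ring-count
threshold bits plus SMARTS keys). All patterns use concrete atoms only,
which admits an exact count-based prescreen: a NumPy comparison of
per-element/aromatic/ring-atom requirements eliminates most patterns before
the subgraph matcher runs (~3 ms per molecule for the full dictionary).

Fragment presence is binary per compound. Fragments seen more than 10 times
in the dataset (strict inequality) are scored by

* **information gain** IG = H(label) − H(label | fragment), base-2 entropies
  with 0·log 0 := 0 — the mutual information between presence and label
  (a natural-log variant is a one-line config change in `_entropy2`); and
* **class frequency** freq_c = (m_c/n_c)/(m/N), within-class prevalence over
  overall prevalence, so values > 1 mean enrichment.

Alerts are fragments with freq_p > freq_n, ranked by IG descending (ties by
dictionary index), reported top-k (default 7) with up to three positive
representative compounds each.

## Synthetic data generator

The generator emulates the study conditions of the screening dataset the
pipeline targets: ~1,181 compounds with ~33% positives (391/1181). Molecules
are drawn from a scaffold/decoration grammar — aromatic and aliphatic cores
with one or two substitution sites, a substituent vocabulary including
alkyl chains of graded length (C1–C10) for a near-continuous spread of
size/lipophilicity — rather than random molecular graphs, which frequently
fail valence sanitization. Labels follow a logistic model: planted alert
fragments each multiply the odds of activity by a configured factor
(default: one sulfonamide fragment, odds × 8, inserted with probability
0.5), optional descriptor effects add coefficient × population-z-scored
descriptor terms, the intercept is calibrated by bisection to the target
positive fraction, and labels are flipped with probability `label_noise`
(default 0.05). Everything is bit-reproducible from the seed.

What the generator does **not** emulate: the chemical diversity of a real
screening library (its support is a few thousand grammar products),
stereochemistry-dependent activity, assay noise structure, and any
correlation between activity and scaffold class beyond the planted effects.
Passing tests therefore demonstrate that the machinery recovers planted
signal under controlled conditions, not that the reported headline numbers
of any particular screening dataset are reproduced.

## Test problem sizes and numerical choices

* Planted-alert recovery runs 100 seeded simulations at n = 1,000 with the
  default odds-8 sulfonamide and 5% label noise, requiring the planted
  SMARTS in the top-3 alerts in ≥ 95 runs.
* The feature-set-vote concentration check contrasts a descriptor-only
  panel (13MD) against MACCS on data whose signal is a tert-butyl fragment
  at odds 40 with 2% noise: tert-butyl has an n-butyl decoy in the
  decoration vocabulary, so the physchem panel can barely separate carriers
  while the fingerprint sees the branching directly. n = 600, 18 splits,
  XGBoost at a single grid point, 5-fold CV — the vote concentrates at ≥
  16/18. The null-data control (n = 400) checks that consensus hold-out AUC
  stays within three Mann–Whitney null standard deviations of 0.5.
* Default hyperparameter grids are small, desk-scale spans of each
  algorithm's customary tunables (see `gutshield.modeling.DEFAULT_GRIDS`),
  all config-overridable.
* SVM members expose scores via a sigmoid of the decision function
  (probability fitting is not enabled by default); all other learners use
  `predict_proba`.
* The 13MD panel uses open surrogates throughout: Crippen logP for AlogP, an
  ESOL-style linear model for solubility, Labute ASA for molecular surface
  area, TPSA for polar surface area, MFPSA = PSA/MSA. logD is not computable
  without pKa; a user-supplied logD column is accepted and AlogP is
  substituted (with a logged warning) otherwise. The 13th panel member is
  taken to be the rotatable-bond count. Numerical agreement with
  commercially computed descriptor values is not claimed.
* Degenerate inputs: constant descriptor columns scale to 0 and are flagged
  and ranked last in importance studies; folds that would lack a class raise
  with advice rather than producing undefined metrics silently; empty alert
  lists are valid results.

## Known limitations

* The fragment dictionary and PubChem-width key set are stand-ins (above);
  alert *indices* are therefore not comparable to tools using the published
  dictionaries, although IG/enrichment statistics computed over any
  dictionary of matched cardinality behave identically.
* Descriptor surrogates shift absolute descriptor values; models trained
  here should not be mixed with feature matrices from other toolkits.
* The grammar's chemical space is narrow by design; generalization claims
  about real pharmaceutical space require real training data.
* Stereochemistry is preserved in SMILES but not encoded by any of the
  2-D fingerprints or descriptors, so enantiomer-specific activity is
  invisible to the model — a structural limitation of 2-D QSAR.
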