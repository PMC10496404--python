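# gutshield

Consensus machine-learning screening of small molecules for **anti-commensal
effects on the human gut microbiome**.

Many drugs — not only antibiotics — inhibit the growth of commensal gut
bacteria, and this off-target toxicity is rarely assayed during early drug
discovery. `gutshield` is a cheminformatics toolkit for building and
auditing a structure-based classifier of that risk: given a table of
compounds (SMILES plus a binary label, or a count of inhibited strains), it
labels each molecule **anti-commensal** (inhibits growth of ≥ 1
representative gut bacterial strain) or **commensal** (inhibits none). It
is aimed at computational chemists and drug-safety researchers who want a
reproducible, fully open reimplementation of the consensus-QSAR protocol —
including its model-selection voting, applicability domain and
structural-alert mining — plus a synthetic-data generator that makes every
stage testable without proprietary data or software.

## The method

* **Characterization sets.** Six fingerprints (MACCS 166 keys, an 881-bit
  PubChem-width keyed fingerprint, ECFP4/ECFP6 folded to 1024 and 2048
  bits) crossed with descriptor panels {none, 13MD, RDMD}. Descriptor
  columns are min–max scaled, x\* = (x − x_min)/(x_max − x_min), with
  extrema fitted on training data only.
* **Voting protocol.** 18 stratified random 8:2 splits; on each split every
  (characterization set × algorithm) cell — algorithms: SVM, k-NN, RF,
  naive Bayes, GBM, XGBoost — is tuned by 5-fold cross-validation repeated
  10×, selecting hyperparameters by mean F1 = 2TP/(2TP+FP+FN). Per split
  each characterization set credits its best algorithm; the algorithm with
  the largest total credit wins, then each split names its best
  characterization set for that algorithm and the modal set wins.
* **Consensus model.** One member per split; the consensus probability of a
  new molecule is the arithmetic mean of the 18 member probabilities,
  thresholded at 0.5. Performance is reported as SE (sensitivity on
  anti-commensals), SP (specificity on commensals), ACC, MCC, F1 and
  tie-aware rank AUC, mean ± sd over splits.
* **Applicability domain.** A compound is in-domain when its Euclidean
  distance to the training centroid (scaled feature space) is at most the
  99th percentile of the training compounds' own distances.
* **Structural alerts.** Fragments from a bundled 4,860-pattern SMARTS
  dictionary, scored by information gain IG = H(label) − H(label | fragment)
  (bits) and class-frequency enrichment freq_c = (m_c/n_c)/(m/N); alerts are
  fragments with freq_p > freq_n, ranked by IG.

Design details, surrogate choices and limitations are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Everything below runs in about a minute on one CPU, at reduced grid sizes
(3 characterization sets, 2 algorithms, 18 splits of a 300-molecule
synthetic dataset with a planted sulfonamide activity signal).

```sh
gutshield synth --n 300 --seed 7 --out data.csv --truth truth.json
# wrote 300 molecules (103 positive) to data.csv
gutshield split --data data.csv --n-splits 18 --seed 7 --out splits.json
printf 'folds: 5\nrepeats: 1\nn_splits: 18\nseed: 7\ngrids:\n  XGB: {max_depth: [3, 5]}\n' > cfg.yaml
gutshield screen --data data.csv --splits splits.json --config cfg.yaml \
    --specs "MACCS,13MD+MACCS,13MD" --algorithms "NB,XGB" --out cv.json
gutshield vote --cv cv.json --splits splits.json --out-dir tables
# winning algorithm: NB; winning feature set: 13MD
```

The vote table (`tables/algorithm_vote.csv`) mirrors the protocol's ratio
layout — per split, how many of the 3 contested characterization sets each
algorithm won (naive Bayes wins 45 of 54 credits here; on this small planted
dataset the descriptor panel alone carries most of the signal):

```
,NB,XGB
1,0/3,3/3
2,3/3,0/3
3,2/3,1/3
...
```

Train the consensus with the voted winners and inspect its validation
performance (mean ± sd over the 18 splits; external = each member on its own
held-out 20%):

```sh
gutshield consensus-train --data data.csv --splits splits.json --cv cv.json \
    --spec 13MD --algorithm NB --config cfg.yaml --out model.pkl --report consensus.json
# "external": { "SE": 0.765, "SP": 0.521, "ACC": 0.606, "MCC": 0.278,
#               "F1": 0.576, "AUC": 0.698, ... }
gutshield predict --model model.pkl --data data.csv --ad-check --out preds.csv
# id,smiles,score,label,in_domain,ad_distance
# SYN00000,NCCC1CCCCC1,0.104,0,1,0.654
```

SE 0.765 means the ensemble recovers ~77% of the anti-commensal compounds
on held-out data; `in_domain=1` marks predictions inside the
applicability domain, where they should be trusted.

Structural-alert mining recovers the planted sulfonamide as the top alert:

```python
from gutshield import read_dataset, identify_alerts
ds, _ = read_dataset("data.csv")
for a in identify_alerts(ds, top_k=3):
    s = a.stats
    print(a.rank, s.smarts, round(s.IG, 4), round(s.freq_p, 2), round(s.freq_n, 2))
# 1 S(=O)(=O)N 0.1459 1.55 0.71
# 2 S          0.1459 1.55 0.71
# 3 NS         0.1459 1.55 0.71
```

(The sub-fragments `S` and `NS` tie exactly because in this grammar they
co-occur perfectly with the planted sulfonamide.)

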