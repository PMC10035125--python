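# subloc

Sequence-feature encoders and one-vs-rest classifiers for predicting the
subcellular localization of mRNA transcripts from sequence alone.

## The problem

Where an mRNA resides — cytoplasm, nucleus, endoplasmic reticulum (ER),
extracellular region (ExR), mitochondria, and further compartments such as
cytosol, exosome or ribosome — constrains its regulatory role, and wet-lab
localization assays (RNA-FISH and successors) are slow and expensive.
`subloc` implements an in-silico predictor: transcripts (DNA alphabet; RNA
input with U is accepted and mapped to T) are encoded into four families of
numeric features, one binary classifier is trained per location, and an
unknown transcript is assigned to the location whose classifier scores it
highest.

## Features and model

Four feature groups, seven blocks (6122 features in total):

- **k-mer** — frequencies `Kmer_i = C_i / L` for k = 2..5 over the
  transcript of length L (16 + 64 + 256 + 1024 = 1360 features).
- **PseKNC** — type-I pseudo k-tuple nucleotide composition: the same
  k-tuple blocks, normalized per window count, plus λ = 10 sequence-order
  correlation factors θ₁..θ_λ computed from standardized dinucleotide
  helical parameters, weighted by w = 0.1 (1370 features).
- **physicochemical** — PseEIIP: trinucleotide frequencies weighted by
  summed electron-ion interaction pseudopotentials (EIIP: A 0.1260,
  C 0.1340, G 0.0806, T 0.1335; 64 features); DPCP/TPCP: products of di-/
  trinucleotide property values and normalized frequencies (148×16 = 2368
  and 12×64 = 768 features).
- **Z-curve** — the 3-D transform of trinucleotide frequencies along
  purine/pyrimidine (x), amino/keto (y) and strong/weak-bonding (z) axes,
  phase-independent (48) and per codon phase (144).

Per location, a binary one-vs-rest model (decision tree, Gaussian naive
Bayes, RBF SVC, random forest, XGBoost or LightGBM) is trained on
location-specific feature groups: compositional features (k-mer + PseKNC)
for cytoplasm, nucleus and ER; physicochemical + Z-curve features for ExR
and mitochondria. Negative sets are sampled from the other locations at 1:1
(1:2 for ExR, 1:3 for mitochondria). Evaluation uses a 20% stratified
holdout plus stratified five-fold CV and reports Sn, Sp, Acc, Pre, F1 and
MCC.

The bundled di-/trinucleotide property tables are synthetic stand-ins with
the canonical layout and naming (see their file headers); pass your own TSV
to `load_dinucleotide_properties` / `load_trinucleotide_properties` to use a
published compendium.

## Worked example

```python
import subloc as sl

corpus = sl.generate_synthetic_corpus(
    sl.five_location_config(seed=5, n_per_location=80))
result = sl.train_bundle(corpus, sl.default_specs(corpus.locations),
                         sl.SplitPlan(0.2, 5, seed=5), seed=5)
print(result.report[result.report["split"] == "test"]
      [["location", "sensitivity", "specificity", "accuracy", "mcc"]]
      .round(3).to_string(index=False))
```

prints

```
    location  sensitivity  specificity  accuracy   mcc
   cytoplasm        1.000        1.000     1.000 1.000
     nucleus        1.000        1.000     1.000 1.000
          ER        1.000        0.938     0.969 0.939
         ExR        1.000        1.000     1.000 1.000
mitochondria        0.938        1.000     0.984 0.958
```

— each row is one location's binary one-vs-rest model evaluated on its
untouched 20% holdout. On the same run, scoring every held-out positive
with all five models and assigning by argmax recovers the true location for
80/80 transcripts (`sl.assignment_accuracy`). The synthetic corpus plants
strong compositional signal, so near-perfect separation is the expected
outcome; see `docs/methods.md` for what this does and does not demonstrate.

The `examples/` directory holds one short script per capability (encoding,
corpus simulation, training/prediction, feature ranking, metrics). A thin
CLI mirrors the pipeline stages:

```sh
subloc simulate --locations cytoplasm,nucleus,ER --n-per-location 50 \
    --seed 1 --out-fasta corpus.fa --out-labels corpus.tsv
subloc encode corpus.fa --groups kmer,pseknc --out features.csv
subloc train --fasta corpus.fa --labels corpus.tsv \
    --locations cytoplasm,nucleus,ER --out-dir bundle/
subloc predict --bundle bundle/ --fasta corpus.fa --out pred.tsv
subloc evaluate --predictions pred.tsv --labels corpus.tsv \
    --locations cytoplasm,nucleus,ER
```

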