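# frscreen

Fuzzy-rough descriptor selection, 1-D convolutional IC50 regression, local
surrogate explanations and candidate ranking for ligand-based drug
repurposing.

## The problem

Virtual screening for drug repurposing starts from a reference panel of
compounds with measured potency — IC50 in µg/mL against one cancer cell
line — described by a few dozen molecular descriptors, and asks which
compounds from an unlabeled candidate pool are likely to be potent. With
panels of only 40–120 compounds and ~44 correlated, noisy descriptors,
two questions dominate: *which descriptors actually govern potency*, and
*how confident can a per-compound prediction be*. `frscreen` answers the
first with fuzzy-rough-set dependency analysis and the second with an
explainable convolutional regressor.

## The machinery

**Feature selection.** A feature subset `S` induces a graded similarity
between compounds, `R_S(x,y) = min_{a∈S} (1 − |a(x) − a(y)| / range(a))`.
Potency bands (quantile bins of IC50) are approximated from below with
the Łukasiewicz implicator, `lower_S(A)(x) = inf_y min(1, 1 − R_S(x,y) +
A(y))`, and the dependency degree `γ(S) = (1/n) Σ_x max_A lower_S(A)(x)`
scores how decisively `S` assigns compounds to bands. QuickReduct greedily
grows a reduct — a small subset whose γ matches the full descriptor
set's — with an exhaustive enumeration oracle for small tables.

**Regression.** The selected-descriptor vector, read as a single-channel
sequence, passes through `Conv1D(32,k=3) → MaxPool(2) → Conv1D(64,k=3) →
MaxPool(2) → Flatten → Dense(64) → Dense(1)` (ReLU throughout, valid
convolutions), trained with Adam on MSE against min-max-scaled targets.
The network is pure NumPy and bit-reproducible from one seed. Quality is
reported as `MSE = Σ(y_k−ŷ_k)²/m` and `MAE = Σ|y_k−ŷ_k|/m`.

**Ranking and explanation.** Candidates are ranked by ascending predicted
IC50 (most potent first). Each top hit is explained LIME-style: quartile
binning, seeded bin-toggle perturbations, distance-weighted ridge
regression — signed per-feature weights with range-condition labels like
`0.24 < PEOE_VSA3 <= 0.61`.

**Synthetic libraries.** `generate_library` draws seeded compound panels
in which a small planted descriptor subset determines a positive
IC50-like response plus noise, with a truth record for scoring selection
recall and ranking quality offline.

## Worked example

```
$ frs-screen simulate --seed 7 --out demo
wrote reference.csv (90 rows), candidates.csv (60 rows), truth.json under demo

$ frs-screen select --input demo/reference.csv --target IC50 \
    --tolerance 0.01 --out demo/reduct.json
selected 35/44 descriptors (gamma 0.7000 / full 0.7096)

$ frs-screen train --input demo/reference.csv --reduct demo/reduct.json \
    --seed 7 --out demo/model.json
final train MSE (scaled) 1.46e-18, val MSE 0.039
```

`selected 35/44` says the greedy search stopped once the dependency
degree γ of the subset came within the configured tolerance of the full
set's γ (0.7000 vs 0.7096): nine descriptors added nothing about the
potency bands. The train/validation MSE pair is on the [0,1]-scaled
target; a ~35k-parameter network interpolates 72 training compounds
exactly, and the validation error is the honest number to watch.
Predicting and ranking the candidate pool, then explaining the top hit:

```
$ frs-screen predict --checkpoint demo/model.json --input demo/candidates.csv \
    --top-k 3 --out demo/ranked.csv
top hit: CAND0031 (predicted IC50 10.4271 µg/mL)

$ frs-screen explain --checkpoint demo/model.json --input demo/candidates.csv \
    --row 31 --seed 7 --top-k 3 --out demo/expl.json
explanation for CAND0031 (surrogate R2=0.395, n=5000, seed=7)
  oppose  -13.1136  JGI10 <= 0.17
  oppose  -11.1992  SssO <= 0.15
  oppose  -8.2145  ZMIC3 <= 0.23
```

The weights are in predicted-IC50 units: this candidate's low `JGI10`
value pulls its predicted IC50 down by ~13 µg/mL relative to compounds
outside that bin — evidence *for* potency (lower IC50), rendered as
"oppose" because it pushes the prediction down. A full end-to-end run
(`frs-screen run --config cfg.yaml --seed 7 --out out/`) writes the
reduct JSONs, a with/without-lead descriptor comparison CSV, the model
checkpoint, metrics CSV, ranked-candidates CSV, explanation JSONs and a
`manifest.json` of content hashes; identical configs yield identical
manifests.

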