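# Methods

`frscreen` implements a ligand-based virtual-screening workflow for drug
repurposing: given a reference panel of compounds with measured IC50
against one assay context (one cancer cell line), it (i) selects the
molecular descriptors that govern potency with fuzzy-rough-set dependency
analysis, (ii) fits a one-dimensional convolutional regressor on the
selected descriptors, (iii) predicts IC50 for an unlabeled candidate pool
and ranks it ascending (most potent first), and (iv) explains individual
predictions with a local linear surrogate. This note records the models,
the defaults and why, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Decision tables

The working object is a decision table: `n` compounds × `m` continuous
molecular descriptors, an optional name column and an optional IC50 column
(µg/mL, finite, > 0). Descriptors are min-max normalized to [0, 1] per
column before any similarity or model fitting; the training table's
per-feature (min, max) are stored and re-applied to candidate tables, with
out-of-range candidate values clipped into [0, 1]. Constant columns map to
0 and are flagged. Rows containing non-finite cells are dropped (not
imputed) and counted in the log: with tables this small, imputation would
manufacture chemistry that was never computed.

Descriptor arithmetic is delegated to a pluggable provider. The default
provider binds to RDKit's 2-D descriptor registry; the shipped 44-name
default vocabulary mixes autocorrelation, E-state, VSA and path-count
names with common constitutional descriptors, and a provider is free to
support any subset of it — unsupported names are reported, not silently
skipped. All statistical machinery downstream is agnostic to where the
numbers came from, which is what makes the pipeline testable on synthetic
tables.

## Fuzzy-rough feature selection

For a feature subset `S`, compound similarity is

    R_S(x, y) = min_{a in S} ( 1 − |a(x) − a(y)| / range(a) )

— per-feature similarity aggregated by the minimum t-norm. The empty
subset induces the all-ones relation. A decision class `A` (a fuzzy set
over compounds) is approximated from below with the Łukasiewicz implicator
and from above with the min t-norm:

    lower_S(A)(x) = inf_y min(1, 1 − R_S(x,y) + A(y))
    upper_S(A)(x) = sup_y min(R_S(x,y), A(y))

With 0/1 similarities and crisp classes these reduce exactly to the
classical rough approximations ("the whole class lies inside A" / "the
class meets A"), which is the oracle the tests enforce by explicit
partition enumeration. This implicator/t-norm pair was chosen precisely
for that degeneration property; it also guarantees lower ≤ upper
pointwise.

Continuous IC50 becomes a decision structure in one of two ways:

* **crisp** (default): quantile cuts into `bins` ordered potency bands
  (3 bands: potent / moderate / weak), returned as 0/1 sets partitioning
  the panel. A value equal to a cut falls in the lower band. Fewer
  distinct IC50 values than bands is an error that points at the fuzzy
  method.
* **fuzzy**: one similarity class per compound on the normalized target,
  membership `1 − |y_x − y| / range(y)`. No binning, tolerates ties.

The dependency degree of a subset is the mean fuzzy-positive-region
membership,

    γ(S) = (1/n) Σ_x max_A lower_S(A)(x),

which is monotone non-decreasing under feature addition (adding a feature
can only shrink similarities, and the Łukasiewicz lower approximation is
antitone in the relation). QuickReduct greedily adds the feature with the
largest γ gain, breaking ties by lexicographically smallest name, and
stops when γ reaches γ(full set) − tolerance or no gain is positive. An
exhaustive enumerator (`brute_force_reduct`, ≤ 12 features) returns every
minimal subset matching γ(full) to 1e−12 and serves as the test oracle.

**Stopping tolerance.** The library default is 1e−6 — essentially "match
γ(full) exactly". On continuous descriptors this is a demanding target:
every feature strictly sharpens the min-t-norm relation, so γ creeps
toward γ(full) only as nearly all features are added, and the reduct is
close to the full set. The pipeline therefore runs QuickReduct at a
screening-scale tolerance of 0.01 by default, which on the synthetic
libraries yields a proper-subset reduct (roughly 30–40 of 44 columns)
while recovering the potency-driving descriptors in every seeded
replicate. Both values are plain config fields.

## The 1-D convolutional regressor

The selected-descriptor vector enters as a length-`m` single-channel
sequence and passes through

    Conv1D(32 filters, k=3, ReLU) → MaxPool1D(2)
    → Conv1D(64 filters, k=3, ReLU) → MaxPool1D(2)
    → Flatten → Dense(64, ReLU) → Dense(1)

Convolutions are valid (no padding); pooling truncates odd remainders;
the smallest admissible input length for the default stack is 10, and
building with fewer features fails with that minimum in the message. The
network, Adam optimizer and backpropagation are implemented directly in
NumPy; weights initialize Glorot-uniform from the config seed, so two
builds with one seed are bit-identical.

Training minimizes MSE on min-max-scaled targets (scaling inverted at
prediction, so predictions are in µg/mL) with Adam at 1e−3, 200 epochs,
batch 16. A seeded 80/20 train/validation split is held fixed for the
whole run and the per-epoch train/validation MSE history is recorded; the
split, the shuffling and the initialization all derive from one seed, so
the entire history is reproducible to the bit. Evaluation reports

    MSE = Σ (y_k − ŷ_k)² / m        MAE = Σ |y_k − ŷ_k| / m

in a CSV with one row per assay context.

Capacity, not calibration, is what the synthetic benchmark checks: on a
noise-free planted library of 300 compounds × 20 descriptors the default
configuration reaches held-out scaled-target MSE ≈ 0.02–0.04. At
screening-panel sizes (~90 compounds) the network is heavily
over-parameterized and its candidate-set predictions carry substantial
variance; see "Known limitations".

## Local surrogate explanations

One prediction is explained by a distance-weighted ridge regression in an
interpretable binary space. Descriptors are discretized at their training
quartiles (a value on an edge falls in the lower bin; constant features
collapse to one flagged bin). Each of `n` perturbed samples keeps every
feature in the instance's bin with probability 0.5 or moves it to a
uniformly chosen other bin, drawing the concrete value uniformly inside
the chosen bin; row 0 is the unperturbed instance. Samples are weighted by
`exp(−d²/w²)` with `d` the normalized Hamming distance to the all-ones
row and kernel width `w = 0.75·√m` by default. Ridge (α = 1) coefficients
on the same-bin indicators are the feature weights: positive = the
instance's bin for that feature pushes the predicted IC50 up, negative =
down. Entries sort by |weight| descending, ties by name; condition labels
render the instance's bin as `lo < name <= hi` with two decimals.

The surrogate's hypothesis space is linear in the *binned* indicators,
not in the raw descriptors. Consequently its weighted R² is near 1 for
black boxes that are constant within bins (exactly linear in the
interpretable representation), while for black boxes linear in the raw
features a portion of the variance — the within-bin and across-other-bin
spread — is structurally unexplainable and R² settles around 0.6–0.8.
Sign recovery is the meaningful faithfulness check in that case, and it
is assessed at instances whose features sit in extreme bins: there
"same bin as the instance" has an unambiguous direction, so the
surrogate weight sign must match the true coefficient sign. For an
instance in a middle bin the same-bin indicator is nearly uninformative
about the feature's direction and the sign comparison is not meaningful.

## Synthetic libraries

`generate_library` emulates the statistical shape of a screening decision
table, not chemistry: descriptors are i.i.d. uniform(0, 1); a small
planted subset (default 5 of 44, weights (3, −2.5, 2, −1.5, 2.5)) drives
a latent potency `logistic(Σ w_i (x_i − 0.5))` mapped affinely onto the
IC50 range (default 0.01–100 µg/mL, matching the µg/mL scale of reported
screening tables); observed targets add Gaussian noise (default 5% of the
range) and are clipped positive. The default panel is 90 compounds — the
middle of the 40–120 range typical of per-cell-line reference panels —
and the truth record (planted subset, weights, noiseless targets) lets
tests score selection recall and ranking quality without re-deriving
anything. Real descriptor tables are correlated, heavy-tailed and
partially discrete; none of that is simulated, so passing benchmarks
demonstrate the machinery's correctness and its behaviour under the
stated signal/noise geometry, not performance on real chemistry.

`generate_crisp_table` builds ≤ 12-object 0/1 tables realizing an exact
indiscernibility partition (distinct random bit-codes per block), the
fixture for the classical-rough-set oracle tests. `plant_redundancy`
appends a bit-exact duplicate column for reduct-minimality fixtures.

## Pipeline and reproducibility

One run = one assay context. Stages: load reference CSV → optional lead
handling (a named lead compound can be held in or out of the training
panel; descriptor selection is always reported both with and without the
lead, mirroring the two-column selected-descriptor comparison) → quantile
decision fuzzification → QuickReduct → train the CNN on the selected
columns (candidate tables are scaled with the training parameters; an
id-overlap check guarantees no candidate row is trained on) → predict,
rank ascending with ties by name, truncate to `top_k` → explain the top
hits. Every artifact (reduct JSONs, comparison CSV, checkpoint, metrics
CSV, ranked CSV, explanation JSONs) is hashed into `manifest.json`;
identical configs produce identical manifests, which is the end-to-end
determinism contract. A stage failure aborts with the stage name.

Problem sizes used by the shipped benchmarks (`scripts/acceptance.py`):
crisp oracles on ≤ 8-object tables; 200 random tables for monotonicity;
50 tables ≤ 8 features for greedy-vs-exhaustive reduct agreement; 20
seeded 90×44 libraries for recovery; one 300×20 noise-free library for
regressor capacity; 20 seeded reference/candidate pairs (90 reference, 60
candidates) for the ranking benchmark, with lightweight explainer
sampling (n = 200) inside pipeline runs.

## Known limitations

* The fuzzy-rough construction is the standard similarity-based one; no
  noise-tolerant (VQRS/OWA) or discernibility-matrix variants.
* With min-t-norm aggregation, γ saturates slowly on continuous data, so
  reduct size is governed by the stopping tolerance; at 1e−6 the reduct
  approaches the full feature set.
* The convolutional architecture reads an arbitrary descriptor ordering
  as a sequence; its inductive bias is weak for tabular QSAR, and at
  ~90-compound panel sizes its candidate-set ranking is noticeably noisier
  than tree ensembles fitted to the same table. The ranking benchmark in
  `scripts/acceptance.py` measures exactly this and reports the observed
  hit rate.
* Explanations are quartile-binned; black boxes linear in raw features
  are faithfully signed but not fully captured (see above).
* The synthetic generator does not model descriptor covariance, assay
  censoring (">100 µg/mL"-style values) or inter-replicate variability.
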