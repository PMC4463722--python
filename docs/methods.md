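# Methods

## Model and procedure

`toxknn` couples a two-class nearest-neighbour classifier with a category
read-across for chronic-endpoint data gap filling.

**Endpoints and classing.** Each chemical carries a rat oral LD50 and a rat
oral LOEL, both in mg/kg/day. Curation keeps only records with LOEL ≤ LD50 —
a chronic lowest-effect dose above the acutely lethal dose indicates corrupt
underlying data; the boundary LOEL = LD50 is kept because only strictly larger
values are implausible. Classes follow the collapsed GHS scheme: class 1
(toxic) for LD50 ≤ 2000 mg/kg/day, class 2 (non-harmful) above; the boundary
dose belongs to class 1.

**Distance.** Fingerprints are binary vectors of named bits. The
Jaccard-Tanimoto distance d(a,b) = 1 − |a∧b|/|a∨b| (set-bit counts) is a
metric on {0,1}^m. Conventions for degenerate inputs: d(0,0) = 0 (two
featureless vectors are identical) and d(0, x≠0) = 1; an all-zero fingerprint
triggers a logged warning at ingestion because it usually signals an upstream
featurisation failure. Distances are computed in double precision; reports
round to 4 decimals at most.

**Classification.** A query's class is the majority class of its k nearest
references. Deterministic tie rules, chosen for reproducibility and documented
rather than inherited from any toolbox: neighbour ranks are resolved by a
stable ascending sort on (distance, reference input order); vote ties
(possible for even k) go to the class with the smaller summed neighbour
distance and, failing that, to class 1 — the conservative call, since
over-predicting toxicity is the safer error in hazard screening. When a query
id occurs among the references, the query is excluded from its own neighbour
list by default; self-inclusion is available to measure resubstitution
("fitting") performance, where k = 1 necessarily reproduces every label.

**Choice of k.** Stratified "venetian blinds" cross-validation: within each
class, records are dealt round-robin into folds after a seeded shuffle; each
fold is predicted from the remaining folds and the pooled predictions are
scored per candidate k (default grid 1…10, five folds). The selected k
minimises the mean class error 1 − NER, ties going to the smallest k (the
simpler model). NER is the *balanced* accuracy — the mean of per-class
sensitivities — not raw accuracy; it is the only definition under which a
single mean class error describes both classes simultaneously, and it makes
the two-class mirror identity (specificity of one class = sensitivity of the
other) hold exactly, which the validation module asserts on every report it
produces. A fold that loses one class entirely yields an undefined
sensitivity; it is reported as missing, excluded from the NER mean, and
logged.

**Read-across.** Every query, together with its k analogs, forms a category;
its LOEL prediction is the arithmetic mean of the analog LOELs (so the
prediction always lies inside the analog LOEL range). Prediction error is the
orientation-free fold difference max/min of experimental and predicted LOEL,
binned < 10, 10–100 (inclusive at both edges), > 100; bin assignment uses
full-precision values. A category is qualified iff the classifier predicted
the query's class correctly. Read-across is computed for all queries —
qualification filters summaries but never suppresses predictions. A category
is flagged as an extrapolation when the query's experimental LOEL falls
strictly outside the analog LOEL range (equality with an extreme analog is not
flagged); extrapolated categories are where the mean is structurally biased.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| GHS class-1 boundary | 2000 mg/kg/day | acute class threshold, boundary in class 1 |
| train fraction | 0.8 | per-class train size = floor(0.8·n + 0.5); 70/48 chemicals split 56/14 and 38/10 |
| k grid | 1…10 | candidate neighbour counts |
| CV folds | 5 | venetian-blind stratified folds |
| fold-difference bins | 10, 100 | order-of-magnitude bands, edges in the middle bin |
| report rounding | 2 decimals, half-up | tables only; all internal arithmetic in full precision |

## The synthetic generator

`SimulationConfig` defaults emulate the intended application scale: 118
chemicals, 79 binary bits, class-1 fraction 70/118. Eight bits are
class-informative by default (class-1 template all-ones, class-2 all-zeros on
those bits, each flipped independently with probability 0.1); the remaining
bits are fair coins. LD50 is log10-uniform within the class range — class 1 on
(0.1, 2000], class 2 on (2000, 10000] mg/kg/day — and LOEL is coupled to LD50
through a latent log10 acute/chronic ratio drawn from Normal(1.0, 0.5) plus
Normal(0, 0.3) log10 noise, truncated so that LOEL ≤ LD50. The ratio
distribution is an arbitrary but configurable choice: a one-decade mean
acute-to-chronic gap with half-a-decade spread is a reasonable desk
approximation of published acute/chronic ratio variability, and nothing in
the pipeline depends on its exact shape.

The coupling is deliberately *only* through LD50: fingerprints influence class
membership, class membership constrains the LD50 range, and LOEL follows LD50.
There is no direct fingerprint→LOEL effect, so synthetic experiments probe
exactly the hypothesis the method exploits (structural similarity → same acute
class → transferable chronic endpoint) and nothing else.

What the generator does **not** emulate: real Estate bit semantics or
bit-to-bit correlation structure, multimodal chemical families, assay-duration
heterogeneity in LOEL, censoring, or measurement error in LD50. Passing tests
on synthetic data therefore demonstrate the machinery's correctness and the
method's behaviour under its own assumptions — not predictive performance on
real chemical inventories.

## Numerical and design choices

- Reported doses and folds are rounded half-up (not banker's) to 2 decimals,
  matching toxicology report conventions; comparisons in tests use ±0.01.
- Duplicate chemical ids are a hard error everywhere — read-across identity
  resolution depends on ids, and silent deduplication could swap endpoints.
- Dense uint8 storage for fingerprints; at the intended scale (≲10³ chemicals,
  ≲5·10³ bits) sparse formats would only add overhead.
- Fold assignment, the split and the generator all consume explicit integer
  seeds through `numpy.random.default_rng`; identical seeds give bit-identical
  outputs, and the CLI embeds the effective configuration in its outputs.
- The split's per-class rounding (floor(f·n + 0.5)) reproduces the canonical
  94/24 partition of 70+48 chemicals at f = 0.8.

## The packaged worked-example tables

Two category tables (94 training and 24 test queries: experimental LOEL, three
analog LOELs, printed predicted LOEL and printed fold difference) are packaged
verbatim as CSV. Recomputation reproduces all 118 predicted LOELs and all 24
test-set fold differences to ±0.01. Seven *training* rows (entries 14, 35, 38,
39, 65, 68, 91) print a fold difference that instead equals the ratio of the
query LOEL to the **sum** of the analog LOELs — an internal inconsistency of
the source table (each mismatch matches the sum-based value to ±0.01). The
fixture stores the printed values untouched; tests assert the exact
characterization above rather than blanket equality. One of the seven (entry
68) changes order-of-magnitude bin under correct arithmetic (20.56 vs printed
6.85), so recomputed training bin totals are (70, 17, 7) against the published
(71, 16, 7); the test-set totals (17, 5, 2) are unaffected. `toxknn
verify-fixtures` re-derives all of this from the packaged data.

## Validation strategy

Where a reference fingerprint set is unavailable, per-fingerprint performance
numbers are not reproducible, so validation is property-based:

- neighbour search and distances agree with an independent brute-force oracle
  (scipy's Jaccard metric plus exhaustive sorting) on random instances;
- k = 1 with self-inclusion attains fitting accuracy 1.0;
- with zero informative bits the cross-validated NER is statistically
  indistinguishable from chance (within 3 Monte-Carlo standard errors of 0.5
  over 50 replicates), and the median CV NER is non-decreasing in the number
  of informative bits (0 → 16, 20 replicates per setting);
- with strong informative bits and a tight acute/chronic ratio (sd 0.25), the
  fraction of qualified categories predicted within 10-fold exceeds the same
  fraction under a permuted-LOEL null on identical data.

These replicate counts keep the whole suite to a few seconds while leaving
wide Monte-Carlo margins (the observed effects exceed their standard errors
many-fold).

## Known limitations

- The two-class scheme discards dose-range information within class 1, which
  spans more than four decades of LD50; read-across error concentrates there.
- The mean is a biased LOEL predictor whenever the query sits at the edge of
  its category (extrapolation); the flag marks, but does not correct, this.
- Metrics are defined for the two-class pipeline only; no multi-class
  generalisation, ROC analysis, or inter-model significance testing.
- Fingerprint computation, SMILES standardisation, salt stripping and CAS
  authentication are upstream responsibilities.
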