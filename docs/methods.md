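# Methods

## The decision-theoretic model

The pipeline treats diagnosis as a sequence of three-way decisions. For a
target class `X` (one nominal class, taken one-vs-rest), each sample's
neighborhood granule `[x]_B^δ` summarises the local evidence, and the
decision problem has three actions — accept (`a_P`), defer (`a_B`),
reject (`a_N`) — against the two states `X` and `X^C`. Classical
decision-theoretic rough sets need six hand-set losses; here the losses
are *generated* from granule statistics and one compensation coefficient
ξ:

```
λ_PP = 0                    λ_PN = S^C(X|[x])
λ_BP = S(X|[x]) (P − ξ)     λ_BN = S^C(X|[x]) (1 − P − ξ)
λ_NP = S(X|[x])             λ_NN = 0
```

with `P = P(X|[x])` the granule's conditional class probability. ξ
encodes the decision-maker's tolerance of uncertainty; its working range
is (0, 0.4], and values outside it trigger a warning rather than an
error. The significances are implemented by counting:
`S(X|[x]) = |[x] ∩ X| / |X|` and `S^C(X|[x]) = |[x] ∩ X^C| / |X^C|` — a
granule's share of each class's global mass. This counting definition is
a design choice of this package: it is computable from the raw
distribution of the data, lies in [0, 1], vanishes exactly when the
granule contains no mass of the class, and makes a granule that covers
the whole universe maximally significant for both classes. Other
normalisations are conceivable; none is canonical.

The bracketed factors in `λ_BP`/`λ_BN` go negative when `P < ξ` or
`1 − P < ξ`. Negative losses invert the Bayes ordering of actions (a
deferral could be *rewarded*), so both are clamped at 0. Consequences:
every loss is non-negative, hence every risk term and the overall risk
are non-negative, and a granule pure in either class contributes exactly
zero risk.

### Regions and thresholds

Expected-loss comparison of the three actions yields the standard
threshold pair

```
α = (λ_PN − λ_BN) / ((λ_PN − λ_BN) + (λ_BP − λ_PP))
β = (λ_BN − λ_NN) / ((λ_BN − λ_NN) + (λ_NP − λ_BP))
```

and the rule: accept when `P ≥ α` (ties accept — acceptance is the less
risky action at the threshold), reject when `P ≤ β`, defer otherwise.
With granule-generated losses the formulas can degenerate (a denominator
≤ 0, or β > α — e.g. a clamped `λ_BP = 0` together with `S^C = 0`). Such
granules fall back to a two-way decision: accept iff
`(1 − P)·λ_PN ≤ P·λ_NP`, boundary empty. The overall risk `ℜ_B` sums the
expected conditional loss of each sample's assigned action, one-vs-rest
over both nominal classes (a single-class variant is available via the
`classes` argument; one-vs-rest is the default because it treats benign
and malignant boundaries symmetrically).

### Granulation choices

Distance is Euclidean on min-max-scaled coordinates restricted to `B`;
granules are closed balls (boundary ties included). Default radius
δ = 0.15 in scaled units — small enough that granules stay local on
tables of a few hundred samples, large enough that they are not
singletons in low dimension. Granules shrink as attributes are added
(anti-monotone in `B`) and grow with δ. Two non-obvious consequences of
this metric, documented because they contradict first intuition:

* a *duplicated* attribute is not neutral — it scales distances by √2 and
  tightens granules, so duplicate columns can change the risk unless the
  granulation is already pure;
* adding *any* attribute, informative or not, tends to shrink granules
  toward purity, so on weakly separated small tables the risk criterion
  alone can favour noise attributes. The synthetic recovery tests
  therefore operate at the strong-separation regime the generator
  defaults to, where informative attributes reach pure granulations
  first.

### Reduction

Condition (1) for a reduct is implemented as *non-increase*:
`ℜ_B ≤ ℜ_C` within a float tolerance (relative 1e-9). A strict decrease
requirement would make every fully consistent table irreducible — all
pure granulations have risk exactly 0 — although exactly there reduction
is most natural. Strictness lives in condition (2): every proper subset
of `B` must have strictly greater risk.

The greedy search runs forward from the best single attribute, adding the
attribute with the largest strict risk decrease; if it stalls while still
above `ℜ_C` it keeps adding the least-risk attribute (plateau escape —
in the worst case `B` grows to `C`). A backward pass then repeatedly
deletes the attribute whose removal does not increase the risk. All ties
break toward the lowest attribute label, making the procedure
deterministic. The greedy path enforces condition (2) only for single
deletions; the exhaustive oracle (≤ 10 attributes) checks all proper
subsets and is the reference the greedy result is tested against.
Reduction is computed on the training split only, scaled by
training-split statistics, so the held-out data never informs attribute
selection.

## The classifier

The PNN stores all training vectors and evaluates, for a query `x`,
Gaussian kernels `ψ_ij(x) = (2π)^{−b/2} σ^{−b} exp(−‖x−x_ij‖²/2σ²)`,
class averages `g_i`, and prior-weighted scores `p_i g_i` with
`p_i = c_i / n`; the predicted label is the argmax, ties to the lowest
class index. Internally scores are accumulated in the log domain
(log-sum-exp), so predictions remain correct where the naive product of
the `σ^{−b}` normalisation and a vanishing exponential under- or
overflows (large `b`, tiny σ); where the naive evaluation is
representable the two agree to rounding.

The classifier consumes features in their **native units**, not the
[0,1]-scaled coordinates of the granulation stage. The SPREAD protocol —
grid (0.5, 1.55], operating point σ = 0.75 — is calibrated to raw feature
scales: on [0,1]-normalised inputs a 0.75 bandwidth is several times the
data diameter per dimension, the kernel becomes nearly constant, and the
argmax collapses to the majority class. Keeping the classifier on raw
units (the synthetic generator emits unit-SD features) makes the grid
meaningful end to end. Users who normalise their tables should shrink σ
accordingly; the nearest-neighbour limit (small σ) is scale-free.

## Evaluation

Confusion counts are exact; accuracy, precision and recall follow the
usual definitions with undefined ratios reported as absent (`None`),
never as 0. The positive class defaults to benign: with benign positive,
a malignant sample misread as benign costs precision — the clinically
dangerous error is thus visible in the precision column. The accuracy
confidence interval is the Wilson score interval (via statsmodels),
clipped to [0, 1]; Wilson was chosen over Wald (poor coverage at extreme
proportions) and Clopper–Pearson (conservative) as the standard default
for proportions at these sample sizes. Wall-clock times are recorded in
sweep records and reports but are hardware-dependent and never asserted.

The ξ sweep re-runs reduction per grid value (default 0.05–0.40, step
0.05 → 8 records) on one fixed seeded split; the SPREAD sweep fixes the
attribute subset and re-fits the classifier (default 0.50–1.55, step
0.05 → 22 records; the upper end extends one step past 1.5 so the
documented 1.55 operating point of the timing comparison is on the
grid).

## Synthetic data

The generator emulates the structural features that make reduction
meaningful: class-conditional Gaussian *informative* attributes (unit SD,
class means shifted by `class_separation` SD in every informative
dimension), *redundant* attributes that are linear combinations of
informative ones plus jitter (SD 0.3 by default), and class-independent
Gaussian *noise*. The `triplet` redundancy pattern assigns each redundant
attribute a single informative parent cyclically, reproducing the
mean / SE / worst triplet redundancy of cytology feature sets. The
wbcd-like preset: 569 samples (357 benign / 212 malignant), 10
informative + 20 redundant attributes, separation 2 SD per informative
dimension — about what the strongest real cytology features show.
Default small-table spec: 3 informative + 2 redundant + 5 noise,
separation 6 SD (strong).

What the generator does *not* emulate: the skewed, heavy-tailed marginals
of real morphometric features, correlations between different base
measurements (radius and area are functionally related in real data),
label noise, and measurement truncation. Passing tests therefore
demonstrate that the machinery recovers planted structure under clean
Gaussian conditions, not that a particular attribute count or accuracy
will be reproduced on any real dataset. The UCI file reader exists
precisely so that the pipeline can be pointed at the real table; that run
depends on a download and on granulation choices (δ, the significance
definition) that published results leave open, so its outcome is reported
by users, not asserted by the test suite.

## Problem sizes and numerical notes

The test suite and acceptance script use tables of 100–569 samples and up
to 30 attributes, the exhaustive reduction oracle up to 8 attributes and
40 samples, and 20-replicate Monte-Carlo for the recovery rate; these
sizes exercise every code path while keeping a full run to a few seconds.
Distances use a 1e-12 absolute slack when testing membership at the ball
boundary so that exact-tie membership is stable across BLAS
implementations. Risk comparisons use a relative 1e-9 tolerance, below
which two subsets are considered tied and the lowest-label tie-break
applies. Seeds enter through `numpy.random.default_rng` exclusively; the
same seed reproduces tables, splits and sweep records bit-for-bit
(elapsed-time fields excepted).

## Known limitations

* Greedy reduction is a heuristic: it satisfies the reduct conditions in
  the single-deletion sense but may return a larger or higher-risk subset
  than the exhaustive optimum, and the plateau-escape phase can
  temporarily raise the traced risk.
* The fixed-δ Euclidean granulation is dimension-sensitive: risks at
  different subset sizes are comparable only through the induced regions,
  and very high-dimensional subsets drive all granules to singletons
  (zero risk), which is why reduction quality degrades gracefully rather
  than monotonically with table dimensionality.
* One-vs-rest risk doubles the work for two classes and exactly mirrors
  the complement for balanced definitions; the `classes` argument exists
  for the single-class reading.
* The PNN stores the full training set and evaluates all kernels per
  query; cost is O(n·b) per prediction, fine at these sizes, unsuitable
  for very large tables.
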