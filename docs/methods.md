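# Methods

## The model

`sibbn` fits discrete Bayesian belief networks that link sanitary-inspection
(SI) observations to E. coli detection in household drinking water.  A
network is a directed acyclic graph over categorical nodes; each node's
conditional probability table (CPT) gives one distribution over its states
per combination of parent states, and the joint factorizes by the chain
rule.  The outcome node is E. coli detection in the stored drinking water
(point of use, POU), dichotomized as detected / not detected from the CFU/1 ml
plate count (`discretize_ecoli`); its parents are detection at the source
(point of collection, POC), household water treatment (HWT), two
cluster-summary nodes, and — in the "B" variants — the fullness level of the
storage container.

### Cluster indices and intermediate nodes

Rather than wiring every SI observation into the outcome (which would blow
up the outcome CPT), related observations are summarized by *intermediate*
nodes with deterministic, hand-specified CPTs:

* **water storage** — storage covered, storage not cracked, safe place of
  storage.  Each variable scores 1 in its best state; totals 3 / 2 / 0–1 map
  to a **low / moderate / high** chance of (re)contamination.
* **surrounding environment & hygiene** — no open defecation, no livestock
  near the house, clean floor, no faeces, no garbage, no flies.  Totals
  5–6 / 3–4 / 0–2 map to low / moderate / high.

The written cut-off rule and the reported category frequencies imply
opposite label directions; the package defaults to the direction that makes
the reported frequencies coherent (full compliance ⇒ *low* chance of
contamination) and exposes `direction="methods"` for the literal reading of
the cut-off text.  The deterministic CPTs are flagged `locked`: parameter
learning never alters them (a flag allows unlocking for sensitivity
studies).

### The four variants

* **Model 1** (1A/1B): POC water quality is conditioned on the *type* of
  source — piped, well, spring, river, other.
* **Model 2** (2A/2B): wells only; POC water quality is conditioned on six
  well-SI observations (cracked structure, livestock nearby, fencing,
  excreta/garbage nearby, erosion, latrine within 10 m).
* **A vs B**: B variants add storage fullness (five levels, almost empty …
  full) as an extra parent of the outcome.

## Inference

Posteriors are exact, computed by variable elimination with a min-degree
heuristic and node-name tie-breaks (the networks have ≤ 21 nodes, so
determinism matters and optimality does not).  Factors are kept in linear
space with per-step renormalization and an explicitly tracked scale, which
keeps results directly comparable with the brute-force enumeration oracle
used throughout the test-suite (agreement required to 1e-10).  Evidence
whose probability is exactly zero raises `ImpossibleEvidenceError` rather
than returning a zero vector — a silent zero would corrupt EM's expected
counts.

## Learning

Unlocked CPTs are estimated by EM.  The E-step enumerates the joint
configurations of each record's missing fields (the survey's missingness is
a *block*: households without a source sample lack every POC-side field at
once, so at most a few hundred configurations arise) and distributes the
record's unit weight over them in posterior proportion; fractional counts
are accumulated exactly, never hard-assigned.  The M-step is smoothed
relative frequency, `(count + prior) / (total + prior·k)`.  Records are
aggregated by distinct observation pattern, in sorted order, making the fit
invariant to record order.

Defaults, all surfaced as configuration:

| parameter | default | why |
|---|---|---|
| `prior_count` | 1 (Laplace) | keeps the 64–180-row CPTs away from zero cells at survey-scale n |
| `tol` | 1e-6 relative log-likelihood gain | standard EM stopping rule |
| `max_iter` | 200 | never reached in practice (fits converge in < 40) |
| `init` | uniform | reproducible; `random` + seed for restarts |

The observed-data log-likelihood is non-decreasing across iterations; the
suite asserts this on every fit it runs (tolerance 1e-8).

## Validation

Ten-fold cross-validation with per-fold EM refitting: seeded shuffle,
contiguous folds differing by at most one record, held-out records scored
by the posterior probability of "detected" given their non-missing fields
(outcome excluded), scores pooled, one AUC.  The AUC is the Mann–Whitney
probability that a random positive outscores a random negative with ties
counted half; it is checked against an O(n²) pairwise oracle and the
trapezoid ROC computation to 1e-12.  Folds are not class-stratified by
default (stratification is a flag).  Qualitative bands: poor (≤ 0.5), less
accurate (0.5–0.7], moderately accurate (0.7–0.9], highly accurate
(0.9–1), perfect (1).

## Sensitivity

*Predictive inference*: for every node and state, the posterior of the
outcome's designated state under hard evidence on that single node, in
percent; ΔP per node is the max−min spread.  Setting a state means hard
evidence (posterior mass 1), not an intervention — no do-calculus semantics
are implied.  States with zero prior probability have no defined update;
they are skipped with a warning and excluded from ΔP.  Values are exact
internally and rounded only for display.

*Best scenario*: joint hard evidence asserting each scored outer variable's
best state, HWT performed, no detection at the POC, and (B variants) a full
container.  Intermediates are never asserted; their deterministic tables
imply them.  On any truth network whose outcome CPT is monotone in the risk
factors this can only raise the probability of clean stored water.

## The synthetic generator

The field data behind this kind of survey are rarely deposited, so the
package ships a generator whose defaults encode the study conditions it
emulates: 328 households, 49 records missing the whole POC block, root
marginals at the published survey frequencies (56% treating water, 77%
covered storage, 96% uncrazed containers, 66.7% livestock near the house,
89% garbage, 70% flies, source mix piped 31.8% / well 27.2% / spring
17.4%), and POC detection by source type (piped and spring 10%, well 42%,
river 83% detected).  Quantities the survey reports do not pin down are free
parameters with documented defaults:

* the river share of the source mix (0.015; trucks/rain/refill are folded
  into "other" at 0.221, so the five shares sum to one);
* the "other"-source detection rate (0.30);
* well-SI prevalences for model 2 (0.30–0.50 per risk factor);
* the outcome CPT, a logistic risk score with monotone effects —
  intercept −3.65 (calibrated once so the marginal POU detection is ≈ 18%,
  the emulated survey level), +1.6 for detection at the POC, +0.9 for no
  treatment, 0/+0.4/+0.8 across environment risk, 0/+0.3/+0.6 across
  storage risk, +0.7 … 0 from almost-empty to full storage.

Sampling is ancestral in topological order; the missingness is MCAR by
default, with an optional POC-type-weighted mechanism for robustness
experiments (households far from their source are plausibly likelier to
lack a sample).

**What the generator does not emulate.**  Roots are sampled independently,
so cluster-category marginals implied by correlated real-world behaviour
are not reproduced (independence puts ~1.5% of households in the low
environment-risk category where the survey reports 15%); there is no
village/spatial structure, and CFU magnitudes are not modelled, only the
detection dichotomy.  Consequently, passing tests demonstrate the
*machinery* — estimation, validation and inference behave correctly on data
with this structure — not that the published field results would be
reproduced on re-collection.

## Parameter recovery and its metric

The recovery experiments sample variant-1B tables (15% missing POC blocks)
at n ∈ {250, 1000, 5000} and compare EM's unlocked CPT entries with the
generating values.  The reported metric weights each CPT row by the
probability of its parent configuration under the truth: the 1B outcome
table has 180 rows and many carry ~1 expected observation even at n=5000,
so their parameters are unidentifiable at any realistic scale and an
unweighted average would measure the smoothing prior, not recovery.  Both
weighted and unweighted values are computed (`recovery_error`), and the
acceptance script reports both; at n=5000 the weighted error is below 0.01
and falls strictly with n.

The same data-starvation explains a visible behaviour of fitted models: the
best-scenario CPT row (all risk factors simultaneously absent) has ~6·10⁻⁴
mass under the study marginals, so at survey scale its fitted entry sits
near the Laplace prior and the fitted best-scenario update can fall below
the baseline.  Directional claims about the best scenario are therefore
properties of monotone truth networks, where they hold by construction; the
fitted-network scenario is verified against the enumeration oracle for
numerical agreement instead.

## Problem sizes used by the default suite

Stochastic tests use the scales above: study-scale tables (n=328, 49
missing blocks) for cross-validation against a label-permutation null (10
seeds), n up to 5000 for recovery (5 seeds per scale), 50 random networks
(≤ 10 nodes) for the inference oracle, and exhaustive enumeration (8 and 64
rows) for the cluster-index contract.

## Known limitations

* Discrete nodes only; no structure learning; no continuous evidence.
* Evidence-setting semantics for scenarios, not causal interventions.
* The E-step enumerates missing-field configurations, which is exact and
  fast for block missingness over ≤ ~10 fields but unsuitable for records
  missing most of a large network.
* No confidence intervals on AUC or ΔP (point estimates only).
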