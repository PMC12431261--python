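# Methods

This note documents the models, parameters and design choices behind the
package; the README covers installation and usage.

## Data model

A patient record is a sequence of visits, each split into two modalities:

* **static event data** `m = (c, y, E)`: covariates `c` (demographics),
  outcome labels `y`, and a timestamp-ordered list of discrete clinical
  events `E` (diagnoses, procedures);
* **temporal data** `t`: timestamped `(variable, value)` measurements such as
  vital signs and laboratory values.

Event and measurement times are integer hours since visit admission
(evaluation windows such as "first 48 h" make finer granularity
unnecessary); visit timestamps are ISO-8601 strings.  Each modality carries a
`qa_status` flag: `raw` for freshly generated output, `constrained` once it
has passed its quality gate.  The canonical file format is JSON-lines with a
schema header; a long-format CSV dialect (`patient_id, visit_idx, kind, time,
name, value`) serves tabular tooling.  Both round-trip losslessly; the JSON
dialect is byte-stable under read-write.

## Health knowledge graph

The graph mixes curated **concept** nodes (diseases `Dis`, symptoms `Sym`,
medications `Med`, treatments `Tre`, clinical indicators `CI`, clinical
constraints `CC` with a numeric `lower/upper/units` payload), record-derived
**entity** nodes (age, ethnicity, location, time, event type) and **event**
nodes.  Edges come from a closed relation schema (`has_symptom`,
`progresses_to`, `constraints`, `diagnoses`, `after`, ...), and loading
validates every edge against the allowed endpoint kinds.  The concept-only
view (CKG) answers value-range queries; the instance view (IKG) is built
from records by a lightweight extractor that adds one event node per event
occurrence, entity nodes per demographic value, ordering (`after`) edges and
similarity-linked `diagnoses` edges.

Node matching is similarity-based with a pluggable encoder.  The default is
a deterministic lowercase token-set representation scored by Jaccard
similarity, with threshold `tau = 0.5` and ties broken by highest score then
smallest node id.  This keeps every pipeline stage hermetic and exactly
reproducible; a dense sentence-embedding encoder can be supplied through the
same contract when reproducibility across machines is not required.

## Model roles and the mock backend

Six text-model roles drive generation and quality assurance: a demographics
`judge`, a zero-shot entity `extractor`, a few-shot `generator`, a
path-grounded `cot_reasoner`, an event predictor (`ev_predict`) and a
same-patient consistency judge (`ts_assure`).  A backend is any object with
`complete(PromptRequest) -> Completion`; per-role backend assignment is a
configuration concern, so different hosted models can serve different
stages.  The shipped mock backend implements all six roles as pure functions
of (prompt, structured context, seed) grounded in the knowledge graph:
rule-table judging, longest-match dictionary extraction, KG-successor-aware
few-shot sampling, terminal-label path reading, inversion of a declared
variable-to-diagnosis profile table, and a Jaccard-overlap consistency
verdict (cutoff 0.5).  Every call is appended to the audit trail; a typed
backend failure is retried once and then fails the record.

## Graph chain-of-thought reasoning and the CC1 gate

Reasoning state is a vector over the graph's nodes.  `e_0` marks the
question entities; each step multiplies by a transition matrix `W_t` whose
`(u, v)` entry accumulates the relation score of every edge `(u, r, v)`,
with rows L1-normalized when their mass exceeds one so the state stays in
`[0, 1]`.  The default relation scorer is untrained and deterministic:
one plus the Jaccard overlap between question tokens and relation-name
tokens; the per-step question transform `f_t` defaults to the identity.
Both are contracts that a trained scorer or attention transform can replace.

Path generation is beam search over simple paths: at each of `T` steps the
`k` best extensions (score = product of per-hop relation scores; ties broken
by lexicographic node-id sequence) are kept and added to a candidate pool,
so shorter completed paths compete with longer ones; the final answer
prompt serializes the top-`k` candidates, one `A relation B relation C`
line each.  Defaults `T = 2`, `k = 5` are config-exposed.  With beam width
at least the number of partial paths at every step the result provably
equals exhaustive enumeration, which the tests assert.

The CC1 gate walks a generated event sequence pairwise: event `i` passes
when the reasoner's answer about event `i` contains the linked label of
event `i+1`; the last event passes vacuously (single-event sequences cost
zero model calls).  An event that cannot be linked above `tau` fails as
`unlinked`.  On the first failure of a first-pass record, the upstream
generator is notified once and retries with the retrieval width expanded
from 5 to 10; a record that fails again is discarded.

## Retrieval-augmented static-event generation

Demographics are sampled independently per field from the source cohort's
empirical marginals — never as complete rows, to honour the privacy
motivation — then screened by the judge.  The generation prompt also names
an *index condition* drawn from the marginal of first events in the source
cohort; without a clinical anchor in the prompt, entity linking would have
nothing to retrieve from.  Extracted mentions are linked to nodes above
`tau`, the top-`K` most frequent objects over the linked nodes' outgoing
triples are kept (ties: lexicographic object id), subjects sharing
`(predicate, object)` are grouped into one n-ary tuple, and the rendered
sentences serve as few-shot context.  Generated events receive synthetic
timestamps spaced 24 h apart.  `K` starts at 5 and expands to 10 in the
single feedback round.

## Conditional adversarial temporal model

The condition vector summarizes constrained static event data: one-hot
categorical demographics, binned age, a multi-hot outcome-label block and a
scaled event count.  Series are regularized to a fixed grid (8 steps of 6 h
by default) by last-observation-carried-forward with per-cell observed
masks, and min-max scaled per variable using training-set ranges.

The generator feeds per-time-step latent noise (8 coordinates per step)
concatenated with the condition through a hidden projection, adds learned
positional encodings, applies a residual self-attention block, and emits
per-step values through a sigmoid head plus a direct condition skip
connection.  A single shared latent vector cannot span the full per-step
measurement noise (it confines a length-8, 8-variable series to an
8-dimensional manifold), which is why noise is injected per step.  The
discriminator mirrors this, pools over time, and scores from the pooled
features joined with raw per-variable time-means and the condition.

Training alternates Adam updates on the minimax objective

    min_G max_D  E_t[log D(t | c)] + E_z[log(1 - D(G(z, c)))]

with the standard non-saturating generator loss available behind a flag.
Three stabilizers are always active: linear decay of both learning rates to
10%, decaying instance noise on the discriminator inputs, and an
exponential moving average of generator weights used for generation.  In
addition, the generator loss carries a conditional moment-matching term
(weight 100, `0` disables): for every distinct condition vector in a batch
it matches the fake-vs-real group means, group second moments, and
within-series temporal variances (relative error, internal weight 0.2).
Pure adversarial pressure left conditional means roughly 0.1–0.2 of the
scaled range away from their targets and allowed the within-series variance
to collapse; the moment term pins both while the adversarial game shapes
the rest of the distribution.  Missingness is not adversarial: generated
masks are seeded Bernoulli draws from the empirical per-cell observation
rates of the training data (a constant fully-observed mask channel would
otherwise hand the discriminator a degenerate separating direction).

Models serialize to a single `.npz` checkpoint (parameters, config, scaler,
mask rates, loss history) and reload to bit-identical generations.

## Quality gates and assembly

* **CC2** looks up each variable's range via indicator matching in the CKG
  and fails the series iff any observed value falls outside; variables with
  no matched constraint are skipped with a logged notice, since failure is
  defined only as a range violation.
* **VD** formats the series into `(variable: values)` tuples, asks the event
  predictor for the implied diagnoses, and passes the prediction together
  with the record's event tuple to the consistency judge; an unparseable
  prediction forces `vd = 0`.
* A record is assembled into one visit and emitted iff `cc1·cc2·vd = 1`.

The pipeline samples, judges, generates (with one CC1 feedback round),
conditions the temporal model on the constrained record, generates the
series, applies CC2 and VD, and assembles — auditing every model call with
stage tags (`c` generation, `d` static QA, `g` prediction, `h` assurance;
CC2, which uses no model, logs under `f`).  Discarded records are never
regenerated past the budget of 10 attempts per requested record, and the
discard accounting is exactly conservative.  Generated records carry one
visit each; multi-visit assembly is out of scope and exercised only on real
data through sequential bigrams.

## Evaluation suite

* **Static fidelity**: patient-level n-gram probabilities (unigram, bigram,
  trigram within a visit; sequential bigram joining the last event of one
  visit to the first of the next), probability = patients exhibiting the
  n-gram / total patients; Pearson correlation over the top-1000 real-data
  n-grams with absent generated entries aligned to zero.  A comparison with
  fewer than two distinct values is reported as undefined with a reason
  rather than silently coerced.
* **Temporal fidelity**: per-patient embeddings of per-variable (min, max,
  mean, std) over the first 48 h (population std everywhere; unobserved
  variables column-median imputed with a log entry), PRDC with k = 5
  nearest-neighbor radii on Euclidean distances after standardizing both
  sides by the real columns (flag-controlled), and the mean squared
  difference of pairwise-complete inter-variable correlation matrices over
  the upper triangle.
* **Privacy**: nearest-neighbor membership inference.  The first half of the
  real cohort plays the member role.  Distances to the generated set use
  null-padded normalized Hamming over event sequences (static side) or
  Euclidean over first-48-h embeddings (temporal side).  Gaussians fitted to
  the member and holdout distance samples are compared by closed-form
  2-Wasserstein distance and grid-evaluated Jensen–Shannon divergence, and
  AUROC scores the distance-threshold attack.
* **Utility**: a generic train-on-synthetic/test-on-real harness with a
  pluggable label and featurizer around an L2-regularized logistic
  classifier, reporting both transfer directions and their difference.
* **Noise robustness**: zero-mean Gaussian noise with std = level × the
  per-variable std is injected at each requested level and the temporal
  fidelity metrics are recomputed against the unperturbed data.

## Synthetic study conditions

The fixture generator defines the study conditions: 200 patients by default
(500 for model training and privacy calibration), 8 continuous variables
with clinically plausible constraint ranges (heart rate 40–180 bpm, SpO2
60–100%, ...), 7 phenotype labels arranged in three weighted progression
chains (weights 0.4/0.3/0.3 so n-gram probabilities are non-degenerate),
noise std 1, and a planted dependency signal: each diagnosis shifts the mean
of one designated variable by +3.  Event sequences are random chain walks
(never starting at a terminal label), so CC1 holds by construction; values
are clipped inside their ranges, so CC2 holds by construction; 25% of
patients receive a second visit continuing their chain, so sequential
bigrams are populated.  Demographics are internally consistent (minors are
never partnered), which the judge rule-table verifies.

`plant_violations` corrupts a seeded 20% of records per kind — values pushed
below their lower bound (range), successors replaced by labels unreachable
within the reasoning depth (logic), or relabeled diagnoses contradicting the
unchanged temporal signature (dependency) — and returns the ground truth, so
the three gates can be scored as exact confusion matrices.

What the fixtures do not emulate: real marginal distributions of any
clinical dataset, irregular sampling patterns, missingness structure,
coding-system noise, or inter-variable correlation beyond the planted mean
shifts.  Passing tests therefore demonstrate the mechanics and calibration
of the framework, not clinical realism of its output.

## Numerical choices and limitations

* Population (ddof 0) standard deviations throughout.
* PRDC radii use the k-th within-set neighbor with self excluded; identical
  duplicate rows give zero radii but `<=` comparisons keep fixed points
  exact.
* The Jensen–Shannon grid spans ±6 fitted sigmas at 2001 points; a
  degenerate (zero-variance) Gaussian is widened to one grid cell so the
  density stays representable.
* Reasoning restricts to simple paths; cyclic graphs therefore terminate.
* The moment-matching auxiliary makes the temporal model's training
  objective a regularized variant of the printed minimax game; setting
  `moment_weight = 0` recovers the pure game at the cost of conditional
  accuracy.
* Problem sizes used by the shipped tests and acceptance script (500-patient
  training cohort, 600 epochs, 20-record pipeline runs, 1000-patient privacy
  cohorts) were chosen as the smallest scales at which the planted effects
  are estimated with comfortable statistical margin.
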