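# Methods

## The model

Each prescription is a pair of short token lists: diagnoses (view A, 1–3
terms typical) and medications (view B, at most about 5). The model is a
two-view latent Dirichlet allocation: K topics, each a pair of multinomials
(φ^A_k over the diagnosis vocabulary, φ^B_k over the medication
vocabulary), and one topic distribution θ_m per prescription shared by both
views. The shared θ is the substantive assumption: the clinical conditions
that explain the diagnoses are the same ones that explain the medications.
It is what makes a medication that no diagnosis-compatible topic explains
detectable at all.

Terms are matched exactly after whitespace normalization; no coding-system
(ICD/ATC) mapping is attempted, and usage, dosage, route and cost are
outside the model. Duplicate tokens count as repeated observations.
Diagnosis order is preserved in the data model but unused.

## Training

Collapsed Gibbs sampling. With θ and φ integrated out, a token of view A
with term v in prescription m is resampled from

p(z = k | rest) ∝ (n_kv + β^A) / (n_k + V^A β^A) · (n_mk + α) / (n_m − 1 + K α)

and symmetrically for view B. The first factor is per-view; the
document–topic counts n_mk pool both views, which couples them. The −1 in
the document denominator excludes the token being resampled; the
denominator is constant in k, so it affects nothing numerically, but it is
kept for correctness of the conditional. Sweeps iterate tokens in document
order, both views per document. The inner loops are compiled with numba;
the pure-Python conditional (`gibbs.gibbs_conditional`) is the readable
reference implementation, and the test suite checks both against exhaustive
enumeration of the collapsed joint on tiny corpora (tolerance 1e-12).

φ is estimated from the final state as (n_kv + β)/(n_k + Vβ); averaging
over post-burn-in sweeps is available (`average_phi=True`) and reduces
estimation noise at identical cost. Initialization assigns each token a
uniform-random topic. There is no automatic convergence detection: training
runs a fixed number of sweeps (default 1,000) and logs the collapsed joint
log-likelihood each sweep so the user can inspect the trace. A fixed seed
makes training bit-reproducible.

### Hyperparameters

- `K` — number of topics. A sweep helper covers {15, 20, 25, 30, 35, 40,
  45, 50}, the range in which diagnosis–medication topic models of
  outpatient data are typically run.
- `alpha` (default **0.1**) — symmetric prior on θ. The classic long-text
  heuristic α = 50/K is deliberately not used: with at most ~8 tokens per
  prescription it would add Kα = 50 pseudo-counts, drowning the document
  and preventing topic specialization (measured as a ~8× worse
  total-variation distance to the true topics on synthetic corpora). A
  sparse prior encodes that a prescription concerns one or two conditions.
- `beta_A`, `beta_B` (default **0.01**) — symmetric priors on φ; small
  values favor concentrated topic–term distributions, appropriate for
  vocabularies in which each condition uses a small set of drugs.

## Fold-in inference

New prescriptions are inferred one view at a time with φ frozen ("each view
treated as an independent topic model"), so θ̂^A and θ̂^B can disagree —
which is itself an anomaly signal, exposed as
`theta_disagreement_score` (total-variation distance between the views'
estimates; non-default). The chain samples
p(z_n = k) ∝ φ[k, x_n]·(n_k^(−n) + α), and θ̂_k = (mean post-burn-in
n_k + α)/(N + Kα), averaged over sweeps 100–200 by default. Out-of-vocabulary
tokens are skipped and counted, never smoothed — absence of evidence is not
fabricated into evidence. A view with no usable tokens returns the uniform
vector with a flag. Note the α-smoothing bounds θ̂_k at (N + α)/(N + Kα),
so a one-topic document of N=3 tokens cannot exceed ≈0.78 at α = 0.5; the
estimator is checked against exactly enumerated posterior means.

## Topic-mapping score

For each in-vocabulary diagnosis, its topic posterior is the φ^A column
renormalized (uniform topic prior), and its high-probability topics are
tagged. Default rule: top-1, ties to the lower topic index; a cumulative
mass rule (smallest prefix reaching q) is available. The union of the
diagnosis tags is the prescription's reference set D. Each medication tags
its own topics the same way from φ^B and contributes 1 iff its tags miss D
entirely. Conventions, chosen where the method description leaves room:

- Top-1 tagging keeps the score an integer 0..5 for ≤5 medications, which
  is what makes thresholds 1..5 meaningful.
- Diagnoses define the reference set and medications are tested against it
  (a symmetric mode also testing diagnoses against medication tags exists
  behind a flag).
- Out-of-vocabulary medications contribute 1 — an unseen drug–diagnosis
  pairing is precisely what a screen should surface. Out-of-vocabulary
  diagnoses are ignored when forming D, and a prescription with no usable
  diagnosis scores every medication.
- Per-diagnosis tag sets are unioned rather than matched per-diagnosis.

The score is invariant to token order in both views. Flags are
score ≥ threshold, threshold an integer ≥ 1 (default 1); flagged sets are
nested as the threshold grows, so sensitivity is non-increasing and
specificity non-decreasing — a structural property, tested as such. The
per-medication contributions are emitted for inspection but are diagnostic
output only: the validated signal is the prescription-level score, not
which medication tripped it.

## Synthetic data

Real prescription corpora with expert review labels are not public, so the
generator samples the model's own generative process with known ground
truth: φ from Dirichlet priors, θ_m ~ Dirichlet(α_true), token counts
uniform on 1–3 (diagnoses) and 1–5 (medications, reflecting the usual
regulatory cap of five medications per prescription).

Defaults define an idealized coherent clinic: `alpha_true = 0.02` (a
prescription treats essentially one condition) and `topic_separation =
0.98`. The separation parameter gives each topic a Dirichlet prior
concentrated on its own block of ~V/K terms, so that block carries 98% of
the topic's mass in expectation — mirroring how real conditions own largely
disjoint drug sets (antihypertensives vs. macrolides). This matters: an
exchangeable symmetric Dirichlet over a shared vocabulary leaves, at
K=10 and V=100, roughly 15–25% of every topic's mass on terms dominated by
other topics, so even perfectly generated prescriptions look partly
mismatched and no scorer — not even one using the true φ — can separate
planted anomalies well (AUROC ≈ 0.5–0.69 in our measurements). Set
`topic_separation=None` to study that harder regime.

Anomalies are planted by selecting round(anomaly_rate·M) prescriptions
(default rate 9.8%, a realistic review-failure prevalence) and replacing
exactly one medication: `cross_topic_swap` draws the replacement from the
topic with minimal weight under the prescription's true θ (a drug its
diagnoses cannot explain); `random_replace` draws any other medication
uniformly. Planting is a synthetic construction — real inappropriate
prescriptions also involve dosage, duplication and route errors that this
model cannot represent — so passing the detection experiments shows the
pipeline recovers planted topical mismatches, not that it would achieve the
same rates on audited hospital data.

## Evaluation

Confusion counts use label 1 = inappropriate, flag 1 = screened positive.
Rates are percentages; zero-denominator rates are reported as missing, not
NaN. Youden's index is SEN + SPE − 100. Rounding to one decimal happens
only at presentation. AUROC uses the integer TM score as the ranking
variable (finer than the binary flag) and is computed by the rank/
concordance formulation with ties counted ½; tests verify it against a
brute-force O(n²) pairwise count. Subsampling analysis draws one uniform
subsample per proportion and marks a subsample degenerate if it loses a
class.

The sample-size calculator implements the standard diagnostic-accuracy
(Buderer-type) formula: cases needed = ⌈Z²·Se(1−Se)/d²⌉, divided by
prevalence and rounded up (controls analogously with 1−prevalence), the
maximum of the two arms returned. Ceiling the case requirement *before*
dividing by prevalence is deliberate — it is the convention under which the
standard planning example (Se=Sp=0.80, α=.05, d=0.05, prevalence 1.7%)
yields exactly 14,471. Prevalence 1 is allowed (the specificity arm is then
vacuous); prevalence 0 is an error.

## Problem sizes used in the shipped experiments

Topic recovery: M=2,000, K=5, V=50 per view, 500 sweeps — mean matched
total-variation ≈ 0.04–0.06. Detection: M=5,000, K_true=10, V=100 per view,
10% anomalies, 300 sweeps — AUROC ≈ 0.81–0.87 across seeds. Both run in
seconds; larger corpora only improve the estimates (tested: TV shrinks from
M=200 to M=2,000).

## Known limitations

- The model ignores dosage, usage, route and cost; a prescription with the
  right drug at a toxic dose scores 0.
- The score says *which prescriptions* look inconsistent, not *which
  medication* is wrong; per-medication contributions are unvalidated.
- Fold-in θ̂ is a Monte-Carlo point estimate without uncertainty.
- Tagging with top-1 is brittle for genuinely multi-condition terms; the
  mass rule trades that against looser matching.
- The synthetic world is far cleaner than hospital data: vocabularies are
  closed, topics nearly disjoint, and anomalies purely topical.
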