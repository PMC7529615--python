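# Methods

## Problem and data model

`sbce_bayes` analyses small-bowel capsule endoscopy (SBCE) readings in
patients with villous atrophy.  A *reading* is one expert reviewer's
annotation of one capsule study, coded as nine categorical features
(`f1`–`f9`): total area affected, distribution pattern
(normal/patchy/continuous), mosaic pattern, fissuring, scalloping, villous
atrophy, nodularity, ulcers, and the proportion of abnormal small-bowel
mucosa (</> 50%).  Level code 1 always means normal/absent; only the
distribution pattern has three levels, so the feature space has
2⁸ × 3 = 768 cells.  Readings optionally carry a modified-Marsh histology
grade (0, 1, 2, 3a, 3b, 3c), a disease label (celiac disease, CD, vs
seronegative villous atrophy, SNVA), and patient/reader identifiers.
When the two reviewers disagree, both readings enter the cohort as separate
rows sharing a patient id — readings, not patients, are the exchangeable
unit throughout.

Two binary tasks are defined: **severity** (class 1 = mild, Marsh 0/1/2;
class 2 = severe, Marsh 3a/3b/3c) and **disease** (class 1 = SNVA,
class 2 = CD).

## Model

Within class *c* each feature *fᵢ* is categorical with parameter vector
λᵢ = (λᵢ₁ … λᵢ_K); features are conditionally independent given the class
(the naive-Bayes assumption), so

  p(SBCE | c) = ∏ᵢ₌₁⁹ p(fᵢ = k | c).

A symmetric Dirichlet prior with pseudo-count α (default α = 1, add-one /
Laplace smoothing) is placed on each λᵢ and integrated out, giving the
posterior-predictive probability

  p(fᵢ = k | c) = (N_k + α) / (N + Kα),

where N_k is the tally of level k among the class-c readings and N the
class-c reading count.  Smoothing keeps every probability strictly
positive, so the model stays defined even when a leave-one-out fold loses a
class entirely.  (Some descriptions of this estimator read N as the whole
cohort size; only the per-class count is consistent with N_k ≤ N inside a
class, and that is what is implemented.)

Two prediction rules are exposed:

* **max_likelihood** — ĉ = argmax_c p(SBCE | c);
* **naive_bayes** — ĉ = argmax_c p(SBCE | c) p(c), with posterior
  p(c | SBCE) normalised over the two classes.  The class marginal is
  estimated with the same smoothing, p(c) = (N_c + 1)/(N + 2); the raw
  proportion N_c/N is also available (`smoothed=False`) because cohort
  summaries conventionally quote it (e.g. 63/81 = 77.8% CD).  Smoothed is
  the default estimator.

All likelihood accumulation is done in log space and exponentiated only for
display.  With nine bounded factors underflow cannot occur; the log form is
numeric hygiene that keeps the pipeline safe for wider schemas.  Exact score
ties (within 1e-12 relative) predict class 1 — the milder / rarer-
intervention group in both tasks — and set a visible `tie` flag; this
tie-break is a package design choice, made deterministic rather than silent.

## Validation

Leave-one-out cross-validation holds each reading out in turn, refits the
tables (and, for the naive-Bayes rule, the class prior) on the remaining
readings only, and scores the held-out prediction 1/0; accuracy is
100 × mean score, displayed to one decimal, rounding half away from zero.
Fitting is pure counting, so each fold's model is produced by subtracting
the held-out reading's tallies from the full-data tallies; this downdating
is algebraically identical to refitting and is verified against a literal
refit in the test suite.  The held-out unit is one reading by default,
matching the cohort's construction in which discordant double reads are
separate rows; `fold_unit="patient"` holds out all of a patient's readings
together as a sensitivity analysis (the suite contains a cohort where the
two fold units provably differ).

## Synthetic cohort generator

No per-reading feature matrix is publicly deposited for the motivating
cohort, so every stage is exercised on synthetic data generated under
exactly the model's assumed law: class from a two-class marginal, features
independently categorical given the class, and a configurable fraction of
patients double-read, with the second reading re-drawn independently from
the same class-conditional law (reader disagreement modelled as independent
annotation noise).  The packaged default λ values
(`src/sbce_bayes/data/synthetic_lambda.yaml`) are invented, clearly
labelled synthetic numbers chosen once to realise the qualitative contrasts
the analysis expects — more abnormal-level mass in the severe/CD class for
every feature except ulcers (where the two classes differ by < 0.02), the
SNVA class favouring patchy distribution — with class marginals equal to
the reference cohort's reading proportions (31/81 mild, 18/81 SNVA) and a
double-read fraction of 9/72 = 12.5%.  Overall abnormality rates were kept
broadly comparable to a cohort in which roughly a quarter of studies are
normal and scalloping/fissuring/mosaicism are the commonest findings.

`build_reference_fixture` constructs an 81-reading stand-in for the study
cohort with the label structure exact: 72 patients with Marsh grades
distributed (9, 15, 3, 8, 19, 18) across 0…3c; reading-level class counts
exactly 31 mild / 50 severe and 18 SNVA / 63 CD; nine CD patients carry a
second reading.  SNVA patients are assigned severe grades (villous atrophy
entails Marsh ≥ 3a), and all mild-grade patients are CD — the joint
disease × histology cross-table is not published, so this is the package's
own consistent completion.  Feature values are drawn from the severity-task
default λ given each patient's severity class; the fixture is therefore a
structural fixture, not a reconstruction of the real feature matrix, and
validation accuracies computed on it are synthetic-cohort results.

What passing tests on this generator do and do not show: they verify the
estimator, the classification algebra and the cross-validation machinery
under the model's own assumptions (conditional independence, independent
double reads, no missing data).  They cannot certify performance on real
capsule data, where features are correlated (mosaicism and scalloping
co-occur), reader disagreement is not independent noise, and annotation
error is systematic.

## Numerical and design choices

* α is a single scalar applied to every level (symmetric Dirichlet); the
  `CategoricalPosterior` type stores a per-level vector internally but the
  public fitting surface exposes the scalar only.
* Level codes are stored as 1-based integers exactly as the schema assigns
  them; text level labels are an I/O convenience.
* Missing feature values are rejected, not imputed — the model has no
  missing-data mechanism.
* A reading with all features at level 1 *is* the representation of a
  normal study; there is no separate flag.
* Floating comparisons in tests use absolute tolerance 1e-12; all fitted
  quantities are ratios of small integers.
* One integer seed drives each stochastic entry point
  (generator config, fixture builder, acceptance script); all stochastic
  tests state their seed.
* Problem sizes in the statistical checks — 200 random small cohorts for
  the counting oracle, n = 20,000 for parameter recovery (binomial standard
  error < 0.005, so the ±0.02 tolerance is a 4× margin), n = 1,000 for the
  classifier identities, n = 2,000 for the Bayes-rate comparison against
  exhaustive enumeration of the 768-cell space (±3 points ≈ 3 binomial
  standard deviations, with double-reads slightly inflating variance) —
  were chosen so each check is decisive yet runs in seconds.

## Known limitations

* Conditional independence is assumed, not tested; no tree-augmented or
  correlated extension is provided.
* Two classes only; no multi-class Marsh prediction, calibration curves or
  ROC analysis.
* The generator does not emulate correlated features, systematic reader
  bias, or any association between disease type and feature distribution
  beyond what the per-task λ tables encode; in the reference fixture the
  disease task inherits only the signal that leaks through the
  severity–disease label association.
* No inter-reader agreement statistics are computed.
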