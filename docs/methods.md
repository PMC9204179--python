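# Methods

This note documents the models and procedures implemented in `forumvigil`,
the assumptions behind the synthetic-data generator, the numerical choices,
and the limitations a user should know before applying any of it to real
forum data.

## 1. Intake chain

Raw posts (forum, post id, thread id, author id, UTC timestamp, free text)
pass through four stages, in order: duplicate removal, spam removal,
relevance filtering, name masking. Conservation holds by construction:
input count = kept + duplicates removed + spam removed + irrelevant removed,
and each stage logs its removal count.

* **Duplicates** are exact: identical (text, poster, timestamp), with text
  compared after Unicode NFC normalization (removes encoding noise only).
  The survivor is the copy with the lexicographically smallest post id — the
  duplicate key itself does not determine which copy to keep, so a
  deterministic tie-break was chosen. Near-duplicate detection is out of
  scope.
* **Spam** is a lexicon of phrases (e.g. "online store") matched
  case-insensitively on word boundaries; word boundaries are transitions
  between alphanumeric and non-alphanumeric characters throughout the
  package, so "store" never fires inside "restored". An empty lexicon is a
  configuration error rather than a silent no-op.
* **Relevance** keeps posts with at least one generic-name, brand-name, or
  drug-class keyword and records every matched drug id on the post.
* **Masking** replaces dictionary person names with the fixed token
  `[NAME]`, which contains no maskable word and therefore makes the
  operation idempotent; the token also preserves token boundaries for the
  dictionary matcher downstream. Masking is the only stage that ever edits
  text.

Spam and relevance are pure per-post predicates, so they commute; the
dedup→spam→relevance→mask order is fixed for reproducibility of the stage
counts.

## 2. Term mapping

A terminology fixture maps surface synonyms to PT codes and each PT up a
4-level hierarchy (PT→HLT→HLGT→SOC, one parent per code). The shipped
fixture is synthetic: it reproduces the *structure* of regulatory medical
terminologies without any licensed content. Loading is atomic — orphan
codes, double-parent codes, or a synonym mapped to two PTs abort the load
naming the offender.

Matching scans the masked text case-insensitively on word boundaries,
longest match first; shorter candidate matches overlapping an accepted
longer match are suppressed, and each PT counts at most once per post. The
candidate order (position, then length descending, then surface
lexicographically) makes matching independent of synonym file order. No
negation, hypothetical, or third-party-speaker filtering is applied — a
known limitation: "no rash at all" still maps the rash PT.

## 3. Frequency trends

For one drug, quarter q contributes N_q (posts mentioning the drug), n_q
(posts also carrying the PT — or any PT, for the `ANY_AE` series), and
f_q = 100·n_q/N_q. Quarters are calendar quarters labelled `YYYYQk`.
Storage is full precision; presentation rounds half away from zero, one
decimal for `ANY_AE` percentages and three for per-PT frequencies. A
quarter with N_q = 0 has an undefined frequency and is reported missing,
not zero. Relative change 100·(f_end − f_start)/f_start requires a positive
start value. Quarterly series are per-quarter by default; a cumulative
variant exists for symmetry with the cumulative EBGM series. Trend
interpretation is gated on a cumulative count of ≥50 by default
(configurable); the package deliberately performs no statistical trend
tests or changepoint detection.

One presentation convention worth stating: the posts-per-author summary
presents its mean truncated to whole posts (1,672 posts over 16 authors is
presented as 104), with the full-precision mean retained alongside.

## 4. Gamma-Poisson shrinkage (EBGM)

Counts N_ij in a drug×event table are modelled against the independence
baseline E_ij = N_i·N_·j/N_·· (Σ E = Σ N; rows/columns with zero margin
carry no information and are dropped). No stratification is applied when
computing E; stratified baselines are a documented extension point. The
relative reporting rate λ of a cell has the two-component gamma mixture
prior λ ~ π·Gamma(α₁,β₁) + (1−π)·Gamma(α₂,β₂) — shape/rate
parameterization throughout, the most common source of implementation
ambiguity — so the marginal of N is a two-component negative binomial
mixture with success probability β/(β+E), evaluated in log space.

**Fitting.** θ = (α₁,β₁,α₂,β₂,π) maximizes the summed marginal
log-likelihood by L-BFGS-B in log/logit-transformed space with box bounds
[1e-4, 1e4] on shapes and rates. The canonical start (0.2, 0.1, 2, 4, 1/3)
is tried first, followed by 4 restarts jittered by N(0, 0.5) in the
transformed space from a fixed-seed stream; the best restart wins, so the
fitted log-likelihood is never below the canonical start's and refits are
bit-reproducible. Component labels are not identified (swapping components
leaves the model invariant); all reported quantities are label-invariant.

**Posterior.** The conjugate posterior is Q_n·Gamma(α₁+N, β₁+E) +
(1−Q_n)·Gamma(α₂+N, β₂+E) with Q_n ∝ π·NB₁(N). The score is
EBGM = 2^E[log₂ λ | N] with E[log₂ λ|N] = [Q_n(ψ(α₁+N) − ln(β₁+E)) +
(1−Q_n)(ψ(α₂+N) − ln(β₂+E))]/ln 2 (ψ the digamma function). EB05/EB95 are
found by bracketed root-finding (Brent) on the mixture CDF between the two
component quantiles, which always bracket the mixture quantile; the CDF at
the returned point is within 1e-6 of the target. EBGM is not asserted to
lie between EB05 and EB95 — a geometric mean may sit anywhere within the
quantiles — but EB05 ≤ EB95, EBGM > 0, and 0 ≤ Q_n ≤ 1 always hold.

**Cumulative series.** For each quarter the table is rebuilt from all
reports dated up to the end of that quarter and the prior refit from the
canonical start (no warm start), so any single point of the series is
reproducible in isolation. Quarters where the cell has no reports are
missing.

**Validation behaviour.** The marginal likelihood agrees with direct
quadrature of Poisson×mixture-density to 1e-6; with π = 1 the EBGM closed
form exp(ψ(α+N) − ln(β+E)) is matched to 1e-10; EBGM is strictly increasing
in N at fixed E; with a diffuse prior and N = 500, E = 100 the posterior
mean collapses to N/E within 2% (shrinkage vanishes at large counts); and a
simulate→fit→score round trip on 5,000 cells with E ∈ [1,100] reproduces
the true-prior EBGM within ±10% for well over 95% of cells.

A note on trend testing of the *cumulative* series: a cumulative estimate
path is a converging, strongly autocorrelated sequence, so the i.i.d. null
band of the Mann–Kendall statistic does not apply to a single series — a
no-signal series frequently shows locally monotone stretches. The test
suite therefore checks the null across 20 independent simulations (the MK
statistics are centred on zero and the final EBGM averages to the true
λ = 1) and checks the planted-ramp case by a one-sided sign test on
last-versus-first values (≥15 of 20 at the 5% level).

Other disproportionality statistics (PRR, ROR, IC) are not implemented;
they target the same signal with different shrinkage behaviour and were out
of scope.

## 5. Longitudinal linking and complexity scoring

Posts sharing an author id form a dossier, ordered by timestamp (ties by
post id). The complexity score is S = Σ u_k·I_k over a configurable
registry of indicators, each a pure function of the dossier into [0,1]. The
published indicator sets behind such scores are not public, so the default
registry is an openly documented profile of 28 binary presence/threshold
indicators with unit weights:

* 11 structural: drug mention; ≥2 and ≥5 distinct PTs; temporal expression;
  dosage pattern; lab-value pattern; negation marker; question form;
  ≥10 posts; ≥90-day span; ≥3 threads;
* 7 insight-category lexicons (medical history, disease burden, non-medical
  treatments, laboratory results, treatment history, concomitant
  medications, AE mention);
* 6 AE sub-element lexicons (time to onset, outcome, treatment of the AE,
  causality statement, dose, rechallenge/dechallenge);
* 4 voice/context: first-person narration, HCP-visit mention,
  treatment-switch vocabulary, family/caregiver voice.

Severity vocabulary is folded into the disease-burden lexicon and
co-suspect-drug mention into the concomitant-medications lexicon, keeping
the default profile at exactly 28 (enforced for the default only; custom
registries may be any size). Because every default indicator is a presence
or threshold test, the score is non-decreasing as posts are appended, and
invariant to input order. Ranking is total and stable: score descending,
ties by earlier first post, then author id.

Insight coverage is computed from annotation files (expert annotation is
out of scope); sub-element flags are only valid where an AE is mentioned,
and — following the printed convention of the source analyses — sub-element
percentages keep the full group count as denominator even though only
AE-mentioning groups can contribute. Percentages round half away from zero
to integers. The bundled lexicon-based auto-annotator exists to exercise
the coverage arithmetic on synthetic dossiers and is explicitly
non-clinical.

## 6. Follow-up

The AE classifier is a multinomial naive Bayes over lowercased alphanumeric
tokens with Laplace smoothing a = 1; per-class likelihoods normalize over
the vocabulary plus one out-of-vocabulary pseudo-token, so unseen words
carry finite likelihood and an empty document scores at the class prior.
Candidates on/after the date floor (2020-01-01 by default in the CLI) are
ranked by P(AE | text), ties by post id.

Completeness compares the elements required for a causality assessment
(per AE class, supplied as configuration) with those the post provides;
questions cover only the missing elements, clamped to 4–11: short lists pad
with the generic elements (outcome, action taken) and then by reverse
priority; long lists truncate lowest-priority first under the order
diagnosis confirmation > time to onset > duration > risk factors > history
of similar events > concomitant medication > relevant medical history >
outcome > dose > action taken. A case with nothing missing needs no
follow-up and is excluded from selection.

Selection filters non-serious and complete cases, then scans a fixed-seed
permutation of the remainder accepting cases while caps permit (≤2 per
similar-AE class, ≤1 per author) up to a pool of 30, sent in batches of 15
with declines and 30-day timeouts replaced from the remainder. Seriousness
and similarity classes are annotation inputs, not inferred — expert
judgement is not modelled. If fewer than one batch survives, everything
available is returned with a warning; widening criteria is the caller's
decision. The dual independent reviewer step is modelled as two annotation
sets plus a percent-agreement report per element, not as an adjudicator.

The engagement simulation draws consent at 0.205 and receipt at 0.75 by
default (observed rates, configurable), with uniform short delays for
consent (0–3 days), question dispatch (0–1 day) and response (0–4 days).
Metrics: rates are rounded half away from zero; day summaries use the
midpoint convention for even-length medians; completeness is
100·answered/asked over received cases. Monotone timelines are enforced at
validation.

## 7. Synthetic-data generator

The generator emulates the study conditions the pipeline is meant for: four
fora, authors posting in threads across a quarter range (default 2010Q3 to
2021Q1), drug mentions by generic/brand/class keyword, AE verbatims drawn
from the synonym lexicon with quarter-varying injection probabilities
(constant, linear ramp, or step), exact-duplicate posts, spam posts
carrying lexicon phrases, and inserted person names. Defaults: 85% of
non-spam posts mention a drug, 2% duplicates, 3% spam, 5% name insertion;
the study-scale fixtures in the tests use 10,000 posts with 8% duplicates,
5% spam, and 10% names so that every planted artifact appears in bulk.
Traffic shape per author is log-normal with a configurable skew parameter
(default σ = 1) — the real distribution of posts per author is not
specified beyond summary statistics, so skew is exposed rather than
asserted.

Text is template-based: slot-filled drug keywords, AE synonyms, names, and
filler vocabulary. The filler, spam, name, drug, and synonym vocabularies
are validated pairwise disjoint at generation time, which is what makes
ground truth exactly recoverable (extraction precision = recall = 1.0 is a
*calibration* property of the generator, not a claim about real text).
Consequently, passing pipeline tests demonstrate correctness of the
matching and accounting logic — not robustness to misspellings, negation,
hedging, slang, or adversarial overlap, none of which the generator
produces.

Randomness: a single config seed; each generator stage (structure,
duplication, spam, relevance, injection, PII, text) draws from its own
sub-stream keyed by a fixed per-stage offset, so adding or removing one
stage never perturbs the draws of another. Duplicates copy content, poster,
and timestamp exactly and receive a later post id, so the dedup tie-break
provably keeps the original. Timestamps are uniform within calendar
quarters.

Report-table simulation draws each cell's λ from the mixture prior and
N ~ Poisson(λ·E), with E either fixed or log-uniform over a range; the true
λ of every cell and the per-cell E are recorded for recovery harnesses. The
dated variant holds background λ fixed across quarters and scales one
designated signal cell's λ (pinned to 1 at baseline) linearly across the
period — a flat multiplier is the no-signal null.

## 8. Problem sizes used in the test suite

Chosen as the package's own validation scale: the pipeline fixtures use
10,000 posts across 8 quarters (≈2,000 drug posts per quarter in the
dedicated ramp-recovery corpus, where 3 binomial standard errors is a tight
band); the prior-recovery harness uses 5,000 cells; the cumulative-series
study uses 20 seeds × 12 quarters on 15×15 tables with one optimizer
restart per refit. The full suite runs in about two minutes on one CPU;
`scripts/acceptance.py` takes a few seconds.

## 9. Known limitations

* Dictionary matching only: no negation/context handling, no fuzzy or
  misspelling matching, no lowest-level-term layer.
* The terminology fixture is synthetic; real deployments must supply a
  licensed terminology in the same CSV structure.
* The EBGM baseline is unstratified; real spontaneous-report analyses
  usually stratify E by age/sex/period, and report deduplication across
  database versions is not modelled.
* Indicator lexicons are small English word lists tuned to the synthetic
  templates; they are placeholders for validated clinical NLP.
* Engagement is a simulation harness around annotation inputs; no real
  patient contact, consent management, or IRB workflow is modelled.
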