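# Methods

## Scope and data model

The package validates a short observation-based classifier (OBC) against the
two published ADOS Module 1 scoring algorithms, the 1–10 comparison severity
score, and an external clinical label. A score sheet is 29 ordinal item
codes in {0, 1, 2, 3, 7, 8} plus age, gender and an optional clinical
diagnosis. Every algorithm consumes *recoded* codes: 3 → 2 (the algorithms
cap item severity at 2), and the special codes 7 ("other abnormality") and
8 ("not applicable") → 0. The 7/8 → 0 convention follows standard practice
for algorithm totals and is configurable, as is the 3 → 2 map. Recoding is
idempotent on its output range {0, 1, 2}. Missing item codes are a hard
error; an opt-in `missing_as_zero` policy imputes 0 and logs one warning per
cell, because the validation design assumes complete score sheets.

### Item identities are configuration

The cutoff rules below are public, but *which* of the 29 items feed which
algorithm domain is licensed instrument content. The defaults satisfy the
structural constraints — 16 algorithm items shared across the two
instruments (the union of the two ADOS-2 verbal-level lists), a 7-item
social + 4-item communication ADOS-G subset, 10 SA + 4 RRB items per ADOS-2
verbal level, and 8 OBC behaviors (vocalization frequency, eye contact,
social smile, shared enjoyment, showing, joint-attention initiation,
functional play, imagination) mapped to plausible ids — and must be
overridden for real data. All results shipped with the package are computed
on synthetic cohorts, where the placeholder identities are immaterial: only
the counts and the latent-severity link matter.

## Instrument algorithms

**ADOS-G.** Domain scores are sums of recoded codes. Classification:
autism iff social ≥ 7 ∧ communication ≥ 4 ∧ total ≥ 12; else autism spectrum
iff social ≥ 4 ∧ communication ≥ 2 ∧ total ≥ 7; else non-spectrum. The
implementation is verified against a brute-force three-rule table over all
(social, communication) pairs ≤ 20, and is monotone: raising any item's
recoded code never moves the label toward non-spectrum.

**ADOS-2.** The verbal level comes from item A1 (overall level of non-echoed
language): raw code ≥ 3 → "few to no words", else "some words". The
published rule names the item but not the code threshold; ≥ 3 mirrors common
practice and is configurable. Cutoffs on the SA+RRB total: some words —
12 autism / 8 spectrum; few to no words — 16 autism / 11 spectrum (all
inclusive). At equal totals the few-to-no-words branch is never the more
severe call. Item revisions that branched former code-2 behaviors into a new
code 3 are absorbed by the shared 3 → 2 recode, so no per-edition item switch
exists.

**Comparison score.** A table of age-band × verbal-level cells, each mapping
totals to 1–10, monotone within a cell; lookups outside any cell or mapped
domain are explicit errors. The shipped table is **synthetic** — linear
decile binning of totals 0–28 into 1–10, duplicated across two age bands
([0, 5) and [5, 21) years) per verbal level — built only so the pipeline and
tests run without licensed content. It preserves the contract (range,
monotonicity, cell structure), not any published calibration.

## The classifier: alternating decision tree

The OBC is an ADTree over the 8 behaviors. A model is a root prediction
value plus an ordered list of rules; each rule has a precondition (root, or
the true/false branch of an earlier rule), a stump condition
`recoded(item) ≥ t` with t ∈ {1, 2, 3}, and two prediction values. A sheet's
score is the root value plus the values of every rule branch it reaches —
a signed real. Sign gives the class; the default orientation is negative =
spectrum, chosen so the score *decreases* with severity and its rank
correlations with instrument totals are negative. |score| below 2 (the
default) flags low confidence; an exact zero is classified non-spectrum and
flagged.

Training is canonical boosting of an alternating tree:

* instance weights start at 1 (unnormalized, so the ε-smoothing below stays
  mild at any n);
* every prediction value is ½·ln((W₊ + ε)/(W₋ + ε)) with ε = 1, where W± are
  weight sums of the two classes in the relevant region;
* each round scans every (precondition, condition) pair and adds the one
  minimizing Z = 2·[√(W₊(p∧c)·W₋(p∧c)) + √(W₊(p∧¬c)·W₋(p∧¬c))] + W(¬p);
* weights of instances reaching the new rule are multiplied by
  exp(−y·value) for the branch value they receive.

Ties in the stump search break toward the lowest (precondition index,
feature order, threshold) tuple, making training deterministic given the
input order. Default rounds = 8 — one stump per behavior, which saturates
the signal on default synthetic cohorts. Recoded codes never reach 3, so the
t = 3 candidate is vacuous; its presence guarantees that the minimal Z never
exceeds the current total weight, hence the recorded per-round *exponential
loss bound* (total weight / n) is non-increasing. That bound — not the raw
0/1 training error, which greedy boosting does not control per-round — is
the monotone "weighted training error" the tests assert. The original
published classifier's weights were never printed; the shipped demo model is
trained on a synthetic cohort and labeled as such, and all numeric behavior
beyond the sign convention and the |2| confidence threshold is design, not
reproduction.

## Evaluation

Spectrum is the positive class throughout. From each 2×2 confusion matrix
(rows = test classifier, columns = reference): sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), accuracy = (tp+tn)/n, PPV = tp/(tp+fp),
NPV = tn/(tn+fn). Zero-denominator metrics are reported missing, never 0.
Display values round half-up to 3 decimals — the convention that reproduces
published report tables exactly — with full precision kept internally.
Spearman rank correlation (average ranks for ties) is delegated to scipy and
cross-checked in the tests against a hand-computed tied-rank oracle;
zero-variance inputs return missing.

The misclassification audit lists every OBC-vs-reference disagreement with:
(a) a *borderline* flag — the reference scores lie within
`borderline_margin` (default 1 point) of a governing spectrum cutoff (all
three cutoffs for ADOS-G, the verbal-level total cutoff for ADOS-2);
"borderline" has no published operational definition, so the margin is
explicit configuration; (b) the count of reference spectrum criteria met
(0–3 for ADOS-G, 0–1 for ADOS-2); (c) the OBC low-confidence flag, plus the
pooled low-confidence fraction.

## Synthetic cohorts

Per subject: class ~ Bernoulli(p_spectrum = 0.892); latent severity
θ ~ N(+1.5, 1) for spectrum, N(−1.5, 1) for controls (a separation of 3 SD —
deliberately strong, matching a design where most spectrum cases are classic
autism); each item code from a graded-response-style model,
P(code ≥ k) = logistic(a·(θ − b_k)) with a = 1 and cutpoints
(−0.5, 0.5, 1.5), emitted as raw {0, 1, 2, 3}; item A1 from the same model,
so severely affected children land in the few-to-no-words branch; age
truncated-normal 6.21 ± 4.25 years on [1, 20]; gender 76.8/18.5/4.7%
male/female/unknown; clinical_dx equals the true class (label-noise and
availability knobs default off; special codes 7/8 are not generated by
default since they recode to 0). One seeded generator drives all draws in a
fixed stream order (class, θ, items in id order, demographics, corruption
streams), so cohorts are byte-identical per seed.

What the generator does *not* emulate: real ADOS item marginals,
item-specific discriminations, repository-specific composition, IQ, or any
dependence between items beyond the single latent factor. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
validation design behaves as expected under its own assumptions — not that
the classifier would achieve these operating characteristics on real
children. A negative control makes the dependence explicit: with zero
severity separation, held-out accuracy collapses to the base rate.

## Pipeline and numerical choices

`run_validation` either evaluates a supplied pre-trained model on the whole
cohort (the mode analogous to validating an externally trained classifier)
or splits 50/50 by a seeded shuffle, trains on one half against
ADOS-G-derived binary labels, and evaluates on the other; train and
evaluation subjects never overlap. Reports carry provenance (seed, config
hash, package version) and serialize with sorted keys and fixed formatting,
so regeneration from the same seed and configuration is byte-identical.
Default problem sizes — n = 2616 cohorts, 2000/616 recovery splits, five
seeds for stochastic properties — run the whole suite in seconds while
keeping binomial noise on the class mix within ±2%.

Known limitations: placeholder item assignments (above); a synthetic
comparison table; no ROC/AUC or bootstrap intervals (the validation design
reports point metrics); Modules 2–4/T and the Toddler algorithm are out of
scope; and the ADTree search is exhaustive over 8 × 3 stump candidates per
precondition, which is exact but would need indexing work for feature sets
orders of magnitude larger.
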