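# Methods

`tweetage` detects the exact age of Twitter users from self-reports in
individual tweets. The pipeline has four stages, each usable on its own:

1. **Retrieval** — retweets and reported speech are excluded, then a table of
   high-recall query patterns flags tweets that potentially mention a user
   age in the closed range 10–99.
2. **Classification** — a binary classifier separates tweets from which the
   poster's exact age at posting time can be determined ("age") from
   candidates that are temporally ambiguous, about another person, or not
   about an age at all ("no age").
3. **Extraction** — an ordered table of linguistic patterns with per-pattern
   arithmetic converts the matched digit groups into an exact age in years.
4. **Cohort aggregation** — tweet-level ages are reduced to one age per user,
   with a timeline-consistency flag and age-group histograms.

## Retrieval

`is_retweet` accepts either an explicit retweet flag on the record or a
leading `RT @` marker (case-insensitive). Reported-speech detection is a
deliberately simple, fully documented heuristic, not a learned model: a tweet
is dropped when a two-digit age-like number falls inside paired double quotes
(typographic quotes are normalized first), or when one of the attribution /
headline patterns in `retrieval.HEADLINE_PATTERNS` fires ("— via Outlet",
"via @outlet", the "Name, 34, arrested …" construction, a leading
"Outlet says:"). False negatives here cost precision later, not recall.

The query patterns live in `src/tweetage/data/patterns.tsv` (versioned,
editable). Every numeric capture is written as `[1-9]\d` bounded on both
sides, so a longer digit run such as `210` can never contribute an age of 21.
Retrieval matches digits only; spelled-out numbers are rewritten later, in
the extraction stage. This is a known recall trade-off: a tweet whose only
age mention is fully spelled out ("I am twenty-one") is not retrieved.

## Text normalization

Each stage sees text through its own transform (`textprep`), and all four
transforms are idempotent by construction:

- *retrieval*: lowercase, ASCII-fold typographic dashes/quotes, fuse digit
  groups split by punctuation ("the big 3–0" → "the big 30").
- *classifier_svm* (bag of words): URLs → `<url>`, @-mentions → `<user>`,
  each digit → `<d>`, other non-alphanumeric characters deleted (so "I'm" →
  "im"), lowercase, Porter-stemmed token by token. Placeholder spellings are
  arbitrary fixed constants; determinism is what matters.
- *classifier_neural*: URL/user placeholders and lowercasing only.
- *extraction*: URLs and @-mentions deleted outright (they often contain
  digits), spelled-out numbers 1–99 rewritten to digits (ordinals keep an
  ordinal suffix: "twenty-first" → "21st"), then digit-group fusion.

Two numeric normalization choices deserve emphasis. First, digit fusion only
removes a gap that contains at least one punctuation character; a
whitespace-only gap separates distinct numbers. This keeps the rewriting of
"two 21st birthdays" → "2 21st birthdays" from collapsing into "221st", and
is what makes the transform idempotent. Second, fusion can in principle merge
two genuinely separate numbers across a sentence boundary ("…21. 35 people…");
this mirrors the aggressive normalization the extraction rules assume and is
accepted as a rare failure mode.

The Porter stemmer is implemented in-repo (`_porter.py`) from the original
1980 algorithm description — classic Porter, not the later Porter2 revision —
because no installed dependency provides an English stemmer. It is validated
against step-traced examples from that description. Note the algorithm's
documented quirks apply: *runner* keeps its *-er* (the stem measure is too
small), while *running*/*runs* → *run*.

## Classification

The default backend is an n-gram SVM chosen to be faithful to a classic
bag-of-words toolchain:

- word 1–3-grams counted over the svm-transformed text (whitespace
  tokenization; the transform has already collapsed punctuation);
- per-feature scaling of counts to [0, 1], fitted on the training set only.
  Since counts are nonnegative with minimum 0 this is implemented with the
  sparse-friendly `MaxAbsScaler`, which is exactly min–max scaling here;
- RBF-kernel SVM with cost `c = 32` and class weights 2 ("age") / 1
  ("no age"). These defaults are fixed constants; `sweep_cost` provides a
  10-fold cross-validated sweep utility for re-deriving a cost on new data,
  but the test suite never runs it (determinism and runtime).

A deep neural backend (e.g. a fine-tuned transformer) is supported strictly
as a plug-in via `register_neural_backend`; nothing in the package imports or
requires one. With a strong pretrained encoder the classification stage is
where most end-to-end headroom lies; the SVM is the dependable, CPU-only
default.

`stratified_split` delegates to scikit-learn's stratified
`train_test_split`, which preserves class proportions to within one item and
yields exact 8 800 / 2 200 splits of an 11 000-tweet corpus at 80/20.

`prf` reports precision, recall and F1 at 3 decimals with explicit
`"undefined"` markers for zero denominators; the degenerate
precision = recall = 0 case reports F1 = 0 with a warning flag rather than an
error. `fleiss_kappa` wraps the standard implementation in
`statsmodels.stats.inter_rater` and returns NaN when only one category is
ever used (chance agreement is 1 and kappa is undefined); an independent
from-scratch arithmetic oracle for the statistic lives in the test suite.

## Extraction

The extractor is an ordered rule table (`src/tweetage/data/rules.tsv`): each
rule is a regular expression with named digit captures `n` (age), optional
`n2` (second age), `k` (time period) and `unit`, bound to one arithmetic
family:

| arithmetic               | age                     | example                               |
|--------------------------|-------------------------|---------------------------------------|
| `direct`                 | N                       | "recently turned 47" → 47             |
| `minus_one`              | N − 1                   | "tomorrow i'll be 20" → 19            |
| `minus_period`           | N − years(k, unit)      | "turning 18 in 3 weeks" → 17          |
| `plus_period`            | years(k, unit) + N      | "20 yrs ago at the age of 19" → 39    |
| `max_of_two`             | max(N1, N2)             | "started at 28 … at 35" → 35          |
| `plus_repeats_minus_one` | N + (k − 1)             | "turned 21 three times" → 23          |

Sub-year periods convert to whole years by ceiling division (weeks/52,
months/12, days/365), so "in 3 weeks" subtracts one year. Rules are tried
strictly in ascending `order_index` and the first match wins; specificity
ordering is the load-bearing design constraint (the repeated-birthday rule
must precede bare "turned N", the offset rules must precede the bare
possessive-birthday rule, and so on), and `validate_rule_order` checks a
probe suite against the table. If no rule matches, the fallback takes the
first standalone two-digit group verbatim.

Semantics encoded in the defaults: a possessive ordinal birthday without a
present-tense marker ("my 21st bday", "21st birthdays") refers to the *next*
birthday, so the present age is N − 1 — the same convention a human annotator
uses for "going to be N" — and likewise bare "turning N". This means the
extractor knowingly reports N − 1 on past-tense constructions like "blessed
to see my 22nd birthday", a one-year near-miss that rule-based matching
cannot resolve without tense analysis; it is the dominant error family by
design.

Arithmetic results outside 10–99 are discarded (no age reported), not
clamped: retrieval restricts candidate ages to that range, so out-of-range
arithmetic indicates the rule matched something that is not a self-report.
Normalizing an extracted *past* age to the user's present age is explicitly
out of scope, as is adjudicating contradictory ages across a user's tweets.

The rule table is a reconstruction target, not a closed vocabulary: it is a
plain TSV that deployments are expected to extend, with the conformance
suite (golden examples + order probes + generator closure) guarding edits.

## Cohort aggregation

For users with several age-predicted tweets, one tweet is selected uniformly
at random; selection is seeded and independent of input order (users and
tweets are processed in sorted order). `timeline_consistency` compares the
span between earliest and latest posting dates (fractional years, truncated
— the one-year tolerance absorbs the convention) with the span between
minimum and maximum extracted ages, and flags agreement within one year.
Histograms use the bins 10–17, 18–29, 30–49, 50–64, 65–99; the sub-adult bin
exists so no extracted age is silently dropped.

## Synthetic corpus

`synthgen` is the test bed: templated tweets with known ground truth, not a
model of real Twitter text. Age-class templates cover every arithmetic
family above, and the ground-truth age is computed from the sampled slot
values by the same arithmetic enum the extractor implements — the closure
test (extractor output = gold on 100% of in-grammar age tweets) therefore
checks pattern matching, ordering and normalization, not the arithmetic in
isolation. No-age templates realize the standard negative categories:
temporally ambiguous future/past references, another person's age, and
non-age numbers (prices, scores, counts). Filler text comes from a fixed
word list with hashtags and URLs injected at configurable rates; filler
never contains digits, number words or rule-trigger words, so it cannot
change a gold age.

Defaults are the study conditions: a 32% / 68% age / no-age mix, ages
sampled uniformly within ranges that keep every computed gold age inside
10–99, timestamps uniform over calendar year 2018. Two runs with the same
seed are byte-identical.

What passing on this corpus does *not* show: robustness to misspellings,
slang, code-switching, sarcasm, or surface forms outside the template
grammar — real-data recall and precision must be measured on annotated real
tweets. Problem sizes used by the test suite (5 000 tweets for closure,
2 000 for classifier separation, 10 000 simulated items for agreement
statistics) are chosen as the smallest sizes at which the binomial noise in
the checked quantities is negligible.

`generate_rater_matrix` simulates annotators who report a gold binary label
with fixed probability; with accuracy 1 Fleiss' kappa is 1, at accuracy 0.5
it concentrates near 0, giving the two analytic anchors for the agreement
statistic.

## Numerical and interface choices

- All randomness flows through explicit integer seeds (`random.Random` /
  scikit-learn `random_state`); there is no module-level RNG state.
- Metric rounding is standard round-half-even at 3 decimals, applied only at
  the reporting boundary; internal comparisons use full precision.
- Malformed input lines (bad JSON, missing fields, unparseable timestamps)
  are logged with line numbers, counted in a `ReadReport`, and skipped; a
  bad record never aborts a stream.
- Intermediate artifacts are always materialized as JSONL so each stage can
  be run and audited in isolation — including evaluating the extractor
  directly against gold labels, bypassing the classifier.
- Exit codes of the `tweetage` CLI: 0 success, 2 configuration error,
  3 stage failure.

## Known limitations

- The retrieval patterns and extraction rules are reconstructions of the
  surface forms evidenced in annotated examples; recall on real data depends
  on extending the tables.
- Reported-speech filtering is heuristic; quoted self-reports ("I can't
  believe I'm 30" as a caption quote) are lost.
- Tense is not modeled: possessive/turning forms are read as next-birthday
  references, a systematic one-year under-estimate on past-tense mentions.
- Ages are reported as of posting time; no normalization to the present.
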