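# tweetage

Detecting the **exact age** of Twitter users from self-reports in their own
tweets. Most demographic inference for social media works at the level of
predefined age groups; studies that need an exact age (age-specific risk
factors, cohort selection in digital epidemiology) are stuck between
high-precision profile scrapers that cover almost nobody and group-level
classifiers that never produce a number. `tweetage` implements the middle
path: an end-to-end NLP pipeline that finds tweets like
*"I was just reminded that I'm turning 18 in 3 weeks"* and turns them into
`age = 17` for that user at that time.

The pipeline has four stages:

1. **Retrieval** — exclude retweets and reported speech (quotes, headlines),
   then match high-recall query patterns for ages 10–99.
2. **Classification** — a binary "age" / "no age" classifier (word-1–3-gram
   bag of words, RBF SVM with cost c = 32 and class weights 2/1; a neural
   backend can be plugged in) rejects candidates that are temporally
   ambiguous, about someone else, or not ages at all.
3. **Extraction** — an ordered table of patterns with per-rule arithmetic
   over the captured digit groups N (and optional period k with a time
   unit): N, N−1, N − ⌈k/unit⌉, ⌈k/unit⌉ + N, max(N1, N2), N + (k−1), with
   a first-two-digit-group fallback.
4. **Cohort aggregation** — one seeded-random tweet per user, a timeline
   consistency flag (date span vs. age span within one year), and age-group
   histograms.

A fully seeded synthetic corpus generator with known ground-truth ages makes
every stage testable offline; see `docs/methods.md` for the model,
assumptions and limitations.

## Worked example

```python
>>> from tweetage.extract import extract_age
>>> p = extract_age("I was just reminded that I'm turning 18 in 3 weeks I feel old")
>>> p.age, p.rule_id
(17, 'turning_in')
```

The tweet reports a *future* age (18) at a sub-year offset (3 weeks), so the
extractor subtracts ⌈3/52⌉ = 1 year: the user is 17 now. Two more:

```python
>>> extract_age("I started having #depression 20 yrs ago at the age of 19.").age
39      # past period + past age: 20 + 19
>>> extract_age("Two more years until my 21st birthday!").age
19      # spelled "Two" -> 2, then 21 - 2
```

End to end, from the library:

```python
>>> from tweetage.synthgen import generate_corpus, as_labeled
>>> from tweetage.classify import ClassifierConfig, train
>>> from tweetage.pipeline import run_pipeline
>>> corpus = generate_corpus(1000, age_fraction=0.32, seed=1)
>>> model = train(ClassifierConfig(seed=1), [as_labeled(s) for s in corpus])
>>> records, report = run_pipeline([s.tweet for s in corpus], classifier=model)
>>> report.n_input, report.n_candidates, report.n_classified_age, report.n_predictions
(1000, 654, 318, 318)
```

Each stage can only shrink the set (the funnel property): 1000 tweets in,
654 candidate tweets survive the filters and match a query pattern, 318 are
classified as genuine self-reports of age, and an exact age is extracted for
all 318.

The same flow is available from the shell:

```bash
tweetage synth --n 1000 --seed 1 --out corpus.jsonl
tweetage retrieve --in corpus.jsonl --out candidates.jsonl
tweetage train --in corpus.jsonl --out model.joblib
tweetage classify --model model.joblib --in candidates.jsonl --out labels.jsonl
tweetage extract --in candidates.jsonl --out predictions.jsonl
tweetage cohort --in predictions.jsonl --out users.csv --histogram hist.json
tweetage evaluate --model model.joblib --in corpus.jsonl
```

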