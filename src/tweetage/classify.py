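"""Binary "age" / "no age" tweet classification and evaluation metrics.

The default backend is an n-gram bag-of-words SVM: word 1-3-grams counted
over Porter-stemmed, placeholder-normalized text, per-feature scaled to
[0, 1] on the training set, and fed to an RBF-kernel SVM with cost c = 32
and class weights 2 ("age") / 1 ("no age"). A deep neural backend can be
registered as a plug-in (see :func:`register_neural_backend`) but is never
required.

Also here: the stratified train/test split, precision/recall/F1 with the
extraction-level error subcategories, and Fleiss' kappa for inter-annotator
agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MaxAbsScaler
from sklearn.svm import SVC
from statsmodels.stats import inter_rater

from .retrieval import CandidateTweet, RawTweet
from .textprep import preprocess_for_svm

AGE = "age"
NO_AGE = "no_age"


@dataclass(frozen=True)
class LabeledTweet:
    tweet: RawTweet
    label: str  # "age" | "no_age"
    gold_age: Optional[int] = None  # present iff label == "age"

    def __post_init__(self) -> None:
        if self.label not in (AGE, NO_AGE):
            raise ValueError(f"label must be {AGE!r} or {NO_AGE!r}")
        if self.gold_age is not None and not 10 <= self.gold_age <= 99:
            raise ValueError("gold_age must be in [10, 99]")


@dataclass(frozen=True)
class ClassifierConfig:
    backend: str = "ngram_svm"  # "ngram_svm" | "neural"
    ngram_range: tuple[int, int] = (1, 3)
    kernel: str = "rbf"
    cost_c: float = 32.0
    class_weight_age: float = 2.0
    class_weight_no_age: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ngram_range[0] > self.ngram_range[1]:
            raise ValueError("ngram_range low must be <= high")
        if self.cost_c <= 0:
            raise ValueError("cost_c must be positive")


@dataclass(frozen=True)
class EvalCounts:
    """Extraction-level confusion tallies with optional error subcategories.

    When subcounts are given, fp = fp_wrong_age + fp_misclassified and
    fn = fn_no_extraction + fn_misclassified must hold.
    """

    tp: int
    fp: int
    fn: int
    tp_exact_age: Optional[int] = None
    fp_wrong_age: Optional[int] = None
    fp_misclassified: Optional[int] = None
    fn_no_extraction: Optional[int] = None
    fn_misclassified: Optional[int] = None

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn):
            if v < 0:
                raise ValueError("counts must be nonnegative")
        if self.fp_wrong_age is not None and self.fp_misclassified is not None:
            if self.fp != self.fp_wrong_age + self.fp_misclassified:
                raise ValueError("fp must equal fp_wrong_age + fp_misclassified")
        if self.fn_no_extraction is not None and self.fn_misclassified is not None:
            if self.fn != self.fn_no_extraction + self.fn_misclassified:
                raise ValueError("fn must equal fn_no_extraction + fn_misclassified")


@dataclass(frozen=True)
class Metrics:
    """Precision/recall/F1; None marks an undefined metric (zero denominator)."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    warnings: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 3) -> dict:
        """Metrics as reported: rounded to 3 decimals, 'undefined' for None."""
        def r(v):
            return "undefined" if v is None else round(v, ndigits)
        return {"precision": r(self.precision), "recall": r(self.recall), "f1": r(self.f1)}


def stratified_split(
    corpus: Sequence[LabeledTweet], train_fraction: float, seed: int
) -> tuple[list[LabeledTweet], list[LabeledTweet]]:
    """Random class-stratified partition into train/test, reproducible by seed."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = [t.label for t in corpus]
    train, test = train_test_split(
        list(corpus), train_size=train_fraction, stratify=labels, random_state=seed
    )
    return train, test


def featurize_ngrams(
    texts: Sequence[str], ngram_range: tuple[int, int] = (1, 3)
):
    """Fit a word n-gram count vectorizer on preprocessed texts.

    Texts must already carry the bag-of-words (classifier_svm) transform;
    tokenization is whitespace splitting. Returns (matrix, vocabulary,
    vectorizer); the vectorizer ignores unseen n-grams at transform time.
    """
    vectorizer = _make_vectorizer(ngram_range)
    matrix = vectorizer.fit_transform(texts)
    return matrix, vectorizer.get_feature_names_out().tolist(), vectorizer


def _identity(text: str) -> str:
    # module-level so fitted vectorizers stay picklable
    return text


def _make_vectorizer(ngram_range: tuple[int, int]) -> CountVectorizer:
    return CountVectorizer(
        analyzer="word",
        tokenizer=str.split,
        preprocessor=_identity,
        token_pattern=None,
        lowercase=False,
        ngram_range=tuple(ngram_range),
    )


@dataclass
class ClassifierModel:
    config: ClassifierConfig
    pipeline: Pipeline
    classes_: tuple[str, ...] = (AGE, NO_AGE)


# Pluggable neural backend: a callable (config, texts, labels) -> predictor,
# where predictor(texts) -> labels. Optional; nothing in the core requires it.
_NEURAL_BACKEND: Optional[Callable] = None


def register_neural_backend(factory: Callable) -> None:
    global _NEURAL_BACKEND
    _NEURAL_BACKEND = factory


def train(config: ClassifierConfig, corpus: Sequence[LabeledTweet]) -> ClassifierModel:
    """Fit a classifier on labeled tweets. Both classes must be present."""
    labels = [t.label for t in corpus]
    if len(set(labels)) < 2:
        raise ValueError("training corpus must contain both classes")
    if config.backend == "neural":
        if _NEURAL_BACKEND is None:
            raise RuntimeError(
                "no neural backend registered; install one and call "
                "register_neural_backend(), or use backend='ngram_svm'"
            )
        predictor = _NEURAL_BACKEND(config, [t.tweet.text for t in corpus], labels)
        return ClassifierModel(config=config, pipeline=predictor)
    if config.backend != "ngram_svm":
        raise ValueError(f"unknown backend {config.backend!r}")
    texts = [preprocess_for_svm(t.tweet.text).normalized for t in corpus]
    pipeline = Pipeline(
        [
            ("counts", _make_vectorizer(config.ngram_range)),
            ("scale", MaxAbsScaler()),  # min-max on nonnegative counts
            (
                "svm",
                SVC(
                    kernel=config.kernel,
                    C=config.cost_c,
                    class_weight={
                        AGE: config.class_weight_age,
                        NO_AGE: config.class_weight_no_age,
                    },
                    random_state=config.seed,
                ),
            ),
        ]
    )
    pipeline.fit(texts, labels)
    return ClassifierModel(config=config, pipeline=pipeline)


def predict(model: ClassifierModel, tweets: Sequence) -> list[str]:
    """One "age"/"no_age" label per tweet; deterministic given the model.

    Accepts CandidateTweet, LabeledTweet, RawTweet, or bare strings.
    """
    texts = []
    for t in tweets:
        if isinstance(t, str):
            raw = t
        elif isinstance(t, CandidateTweet):
            raw = t.tweet.text
        elif hasattr(t, "tweet"):
            raw = t.tweet.text
        else:
            raw = t.text
        texts.append(raw)
    if not texts:
        return []
    if model.config.backend == "neural":
        return list(model.pipeline(texts))
    processed = [preprocess_for_svm(x).normalized for x in texts]
    return list(model.pipeline.predict(processed))


def prf(counts: EvalCounts) -> Metrics:
    """Precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = harmonic mean.

    A zero denominator makes the corresponding metric undefined (None). The
    degenerate precision = recall = 0 case reports F1 = 0.0 with a warning
    flag rather than an error.
    """
    notes: list[str] = []
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if precision is None or recall is None:
        f1 = None
        notes.append("undefined metric: zero denominator")
    elif precision + recall == 0:
        f1 = 0.0
        notes.append("f1 reported as 0 with precision = recall = 0")
        warnings.warn("F1 undefined (precision = recall = 0); reporting 0", stacklevel=2)
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(precision, recall, f1, tuple(notes))


def extraction_eval_counts(
    gold: Sequence[LabeledTweet],
    predicted_labels: Sequence[str],
    predicted_ages: Sequence[Optional[int]],
) -> EvalCounts:
    """Tally extraction-level TP/FP/FN with the error subcategories.

    TP: "age" tweet classified "age" with the exact age extracted.
    FP: "age" tweet classified "age" but wrong age extracted, or "no age"
    tweet misclassified "age" with some age extracted. FN: "age" tweet
    classified "age" but nothing extracted, or "age" tweet misclassified.
    """
    tp = fp_wrong = fp_mis = fn_none = fn_mis = 0
    for item, label, age in zip(gold, predicted_labels, predicted_ages, strict=True):
        if item.label == AGE:
            if label != AGE:
                fn_mis += 1
            elif age is None:
                fn_none += 1
            elif age == item.gold_age:
                tp += 1
            else:
                fp_wrong += 1
        else:
            if label == AGE and age is not None:
                fp_mis += 1
    return EvalCounts(
        tp=tp,
        fp=fp_wrong + fp_mis,
        fn=fn_none + fn_mis,
        tp_exact_age=tp,
        fp_wrong_age=fp_wrong,
        fp_misclassified=fp_mis,
        fn_no_extraction=fn_none,
        fn_misclassified=fn_mis,
    )


def fleiss_kappa(ratings: Iterable[Sequence]) -> float:
    """Fleiss' kappa over an items x raters matrix of categorical labels.

    Returns NaN (explicitly undefined) when a single category is used
    throughout, where chance agreement is 1 and kappa divides by zero.
    """
    arr = np.asarray(list(ratings))
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >=2 items and >=2 raters")
    table, _ = inter_rater.aggregate_raters(arr)
    if table.shape[1] < 2:
        return float("nan")
    return float(inter_rater.fleiss_kappa(table, method="fleiss"))


def sweep_cost(
    corpus: Sequence[LabeledTweet],
    costs: Sequence[float] = (1, 2, 4, 8, 16, 32, 64, 128),
    n_folds: int = 10,
    seed: int = 0,
) -> dict[float, float]:
    """Cross-validated F1("age") for a range of SVM costs.

    Utility mirroring the hyperparameter sweep that fixed the default
    c = 32; not exercised by the test suite (runtime).
    """
    texts = [preprocess_for_svm(t.tweet.text).normalized for t in corpus]
    labels = [t.label for t in corpus]
    results: dict[float, float] = {}
    for c in costs:
        pipe = Pipeline(
            [
                ("counts", _make_vectorizer((1, 3))),
                ("scale", MaxAbsScaler()),
                ("svm", SVC(kernel="rbf", C=c, class_weight={AGE: 2.0, NO_AGE: 1.0})),
            ]
        )
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scores = cross_val_score(pipe, texts, labels, cv=cv, scoring="f1_macro")
        results[float(c)] = float(np.mean(scores))
    return results
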