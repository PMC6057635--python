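"""Multinomial naive-Bayes suggestion of taxonomy terms from variable text.

A deliberately transparent stand-in for an in-house model: bag of tokens
from label + name + question text (tokenizer shared with the search module),
class priors = empirical class frequencies, token likelihoods additively
smoothed as ``(count + alpha) / (class_total + alpha * |vocabulary|)``.
Out-of-vocabulary tokens get the zero-count smoothed likelihood, so no
posterior is ever exactly zero.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .model import Variable
from .search import tokenize
from .taxonomy import TermRef

__all__ = [
    "ClassifierModel",
    "TrainingError",
    "train_classifier",
    "suggest_terms",
    "evaluate_classifier",
    "model_to_json",
    "model_from_json",
    "variable_tokens",
]


class TrainingError(ValueError):
    pass


def variable_tokens(variable: Variable) -> list[str]:
    return tokenize(variable.label) + tokenize(variable.name) + tokenize(
        variable.question_text or ""
    )


@dataclass(frozen=True)
class ClassifierModel:
    alpha: float
    classes: tuple[TermRef, ...]  # sorted lexicographically
    priors: dict[TermRef, float] = field(default_factory=dict)
    token_counts: dict[TermRef, Counter] = field(default_factory=dict)
    vocabulary: frozenset[str] = frozenset()

    @property
    def class_totals(self) -> dict[TermRef, int]:
        return {c: sum(self.token_counts[c].values()) for c in self.classes}


def train_classifier(
    examples: Sequence[tuple[Variable, TermRef]], alpha: float = 1.0
) -> ClassifierModel:
    """Fit the smoothed multinomial model; requires >= 2 distinct classes."""
    if alpha <= 0:
        raise TrainingError(f"alpha must be > 0, got {alpha}")
    if not examples:
        raise TrainingError("no training examples")
    classes = sorted({TermRef(*ref) for _, ref in examples})
    if len(classes) < 2:
        raise TrainingError("training requires at least 2 distinct classes")

    priors: dict[TermRef, float] = {c: 0.0 for c in classes}
    token_counts: dict[TermRef, Counter] = {c: Counter() for c in classes}
    vocab: set[str] = set()
    n = len(examples)
    for variable, ref in examples:
        ref = TermRef(*ref)
        priors[ref] += 1.0 / n
        toks = variable_tokens(variable)
        token_counts[ref].update(toks)
        vocab.update(toks)
    return ClassifierModel(
        alpha=float(alpha),
        classes=tuple(classes),
        priors=priors,
        token_counts=token_counts,
        vocabulary=frozenset(vocab),
    )


def _log_posteriors(model: ClassifierModel, variable: Variable) -> dict[TermRef, float]:
    toks = variable_tokens(variable)
    v = len(model.vocabulary)
    totals = model.class_totals
    logp = {}
    for c in model.classes:
        lp = math.log(model.priors[c])
        denom = totals[c] + model.alpha * v
        for t in toks:
            lp += math.log((model.token_counts[c].get(t, 0) + model.alpha) / denom)
        logp[c] = lp
    return logp


def posteriors(model: ClassifierModel, variable: Variable) -> dict[TermRef, float]:
    """Normalized class posteriors (sum to 1 up to float rounding)."""
    logp = _log_posteriors(model, variable)
    m = max(logp.values())
    exp = {c: math.exp(lp - m) for c, lp in logp.items()}
    z = sum(exp.values())
    return {c: e / z for c, e in exp.items()}


def suggest_terms(
    model: ClassifierModel, variable: Variable, k: int = 3
) -> list[tuple[TermRef, float]]:
    """Top-k classes by posterior; ties broken lexicographically on the ref."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    post = posteriors(model, variable)
    ranked = sorted(post.items(), key=lambda cp: (-cp[1], cp[0]))
    return ranked[:k]


def evaluate_classifier(
    model: ClassifierModel, held_out: Sequence[tuple[Variable, TermRef]]
) -> dict:
    """Top-1 accuracy plus per-class precision/recall (0/0 defined as 0)."""
    if not held_out:
        raise ValueError("held_out must be non-empty")
    tp: Counter = Counter()
    predicted: Counter = Counter()
    actual: Counter = Counter()
    correct = 0
    for variable, gold in held_out:
        gold = TermRef(*gold)
        pred = suggest_terms(model, variable, k=1)[0][0]
        predicted[pred] += 1
        actual[gold] += 1
        if pred == gold:
            tp[gold] += 1
            correct += 1
    per_class = {}
    for c in sorted(set(model.classes) | set(actual)):
        precision = tp[c] / predicted[c] if predicted[c] else 0.0
        recall = tp[c] / actual[c] if actual[c] else 0.0
        per_class[c] = (precision, recall)
    return {"accuracy": correct / len(held_out), "per_class": per_class}


# ---------------------------------------------------------------------------
# JSON model serialization (CLI artifact)

def model_to_json(model: ClassifierModel) -> str:
    doc = {
        "alpha": model.alpha,
        "classes": [list(c) for c in model.classes],
        "priors": [[list(c), p] for c, p in sorted(model.priors.items())],
        "token_counts": [
            [list(c), sorted(model.token_counts[c].items())] for c in model.classes
        ],
        "vocabulary": sorted(model.vocabulary),
    }
    return json.dumps(doc, indent=1)


def model_from_json(text: str) -> ClassifierModel:
    doc = json.loads(text)
    return ClassifierModel(
        alpha=doc["alpha"],
        classes=tuple(TermRef(*c) for c in doc["classes"]),
        priors={TermRef(*c): p for c, p in doc["priors"]},
        token_counts={
            TermRef(*c): Counter(dict((t, n) for t, n in counts))
            for c, counts in doc["token_counts"]
        },
        vocabulary=frozenset(doc["vocabulary"]),
    )
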