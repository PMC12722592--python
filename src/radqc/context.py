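"""Contextual masked-token anomaly detection.

A masked-language-model objective at desk scale: the reference backbone is an
order-n character context model with additive smoothing. During training,
roughly ``mask_rate`` (default 15%) of the characters of each report are
masked per pass and the model learns to predict the masked character from
its bidirectional context; at inference every character is scored by masking
it and evaluating the probability the model assigns to the observed
character (a pseudo-likelihood). Characters whose surprisal (−log p) exceeds
a calibrated threshold are flagged as contextual anomalies, and corrections
from a confusion set are ranked by re-scoring them in context.

The backbone is pluggable: anything honouring the ``ContextModel`` contract
(a normalized distribution over the vocabulary given left/right context) can
stand behind the same training/scoring interface. The reference model trains
in seconds and is fully deterministic under a fixed seed, which a
transformer backbone is not.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

_BOS = "\x02"
_EOS = "\x03"
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TokenSequence:
    """Per-character tokenization; offsets are [start, end) code points."""

    tokens: tuple[str, ...]
    offsets: tuple[tuple[int, int], ...]


def tokenize(text: str) -> TokenSequence:
    return TokenSequence(
        tokens=tuple(text), offsets=tuple((i, i + 1) for i in range(len(text)))
    )


@dataclass(frozen=True)
class ContextTrainingConfig:
    mask_rate: float = 0.15
    rng_seed: int = 0
    epochs: int = 10
    order: int = 2
    alpha: float = 0.01  # additive-smoothing pseudocount
    backbone: str = "ngram-bidirectional"

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_rate < 1.0:
            raise ValueError("mask_rate must be in (0, 1)")
        if self.epochs < 1 or self.order < 1:
            raise ValueError("epochs and order must be >= 1")


@dataclass(frozen=True)
class TokenScore:
    position: int
    probability: float
    surprisal: float


@dataclass(frozen=True)
class CorrectionCandidate:
    surface: str
    context_score: float


class TrainingError(RuntimeError):
    pass


class SuggestionError(RuntimeError):
    pass


class ContextModel:
    """Bidirectional character context model with additive smoothing.

    ``predict_distribution(left, right)`` returns the renormalized product of
    the left-context and right-context predictions over the vocabulary plus
    one out-of-vocabulary slot; the result sums to 1 within 1e-9.
    """

    def __init__(self, order: int, alpha: float, vocab: Sequence[str]) -> None:
        self.order = order
        self.alpha = alpha
        self.vocab: tuple[str, ...] = tuple(vocab)
        self._index: dict[str, int] = {c: i for i, c in enumerate(self.vocab)}
        self._left: dict[str, np.ndarray] = {}
        self._right: dict[str, np.ndarray] = {}
        self._dist_cache: dict[tuple[str, str], np.ndarray] = {}

    # -- training ---------------------------------------------------------
    def _observe(self, table: dict[str, np.ndarray], ctx: str, char: str) -> None:
        vector = table.get(ctx)
        if vector is None:
            vector = np.zeros(len(self.vocab), dtype=np.int64)
            table[ctx] = vector
        vector[self._index[char]] += 1

    def observe_masked(self, text: str, position: int) -> None:
        padded = _BOS * self.order + text + _EOS * self.order
        i = position + self.order
        self._observe(self._left, padded[i - self.order : i], text[position])
        self._observe(self._right, padded[i + 1 : i + 1 + self.order], text[position])
        self._dist_cache.clear()

    # -- inference --------------------------------------------------------
    def _directional(self, table: dict[str, np.ndarray], ctx: str) -> np.ndarray:
        counts = table.get(ctx)
        v = len(self.vocab) + 1  # +1 out-of-vocabulary slot
        if counts is None:
            return np.full(v, 1.0 / v)
        extended = np.concatenate([counts.astype(float), [0.0]])
        return (extended + self.alpha) / (counts.sum() + self.alpha * v)

    def predict_distribution(self, left_context: str, right_context: str) -> np.ndarray:
        key = (left_context, right_context)
        cached = self._dist_cache.get(key)
        if cached is None:
            product = self._directional(self._left, left_context) * self._directional(
                self._right, right_context
            )
            cached = product / product.sum()
            self._dist_cache[key] = cached
        return cached

    def token_probability(self, left_context: str, right_context: str, char: str) -> float:
        dist = self.predict_distribution(left_context, right_context)
        idx = self._index.get(char, len(self.vocab))  # OOV slot if unseen
        return float(dist[idx])

    def min_floor_probability(self) -> float:
        """A lower bound on any emitted probability (used to normalize surprisal)."""
        v = len(self.vocab) + 1
        max_total = max(
            [int(c.sum()) for c in self._left.values()]
            + [int(c.sum()) for c in self._right.values()]
            + [0]
        )
        floor_dir = self.alpha / (max_total + self.alpha * v)
        return floor_dir**2 / 1.0  # product before renormalization never smaller

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format_version": _FORMAT_VERSION,
            "backbone": "ngram-bidirectional",
            "order": self.order,
            "alpha": self.alpha,
            "vocab": list(self.vocab),
            "left": {ctx: counts.tolist() for ctx, counts in sorted(self._left.items())},
            "right": {ctx: counts.tolist() for ctx, counts in sorted(self._right.items())},
        }
        return json.dumps(payload, ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ContextModel":
        payload = json.loads(text)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format {payload.get('format_version')!r}")
        model = cls(payload["order"], payload["alpha"], payload["vocab"])
        for ctx, counts in payload["left"].items():
            model._left[ctx] = np.asarray(counts, dtype=np.int64)
        for ctx, counts in payload["right"].items():
            model._right[ctx] = np.asarray(counts, dtype=np.int64)
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ContextModel":
        with open(path, encoding="utf-8") as handle:
            return cls.from_json(handle.read())


def _texts(corpus: Iterable) -> list[str]:
    return [item if isinstance(item, str) else item.text for item in corpus]


def train(clean_corpus: Sequence, config: ContextTrainingConfig | None = None) -> ContextModel:
    """Fit the masked-token predictor on clean report texts."""
    config = config or ContextTrainingConfig()
    texts = _texts(clean_corpus)
    if not texts:
        raise TrainingError("training corpus is empty")
    vocab = sorted({ch for text in texts for ch in text})
    model = ContextModel(config.order, config.alpha, vocab)
    rng = np.random.default_rng(config.rng_seed)
    for _ in range(config.epochs):
        for text in texts:
            if not text:
                continue
            masked = np.nonzero(rng.random(len(text)) < config.mask_rate)[0]
            for position in masked:
                model.observe_masked(text, int(position))
    return model


def score_tokens(model: ContextModel, text: str) -> list[TokenScore]:
    """Pseudo-likelihood score for every character of *text*."""
    padded = _BOS * model.order + text + _EOS * model.order
    scores = []
    for position, char in enumerate(text):
        i = position + model.order
        p = model.token_probability(
            padded[i - model.order : i], padded[i + 1 : i + 1 + model.order], char
        )
        scores.append(TokenScore(position=position, probability=p, surprisal=-math.log(p)))
    return scores


def detect_anomalies(scores: Sequence[TokenScore], threshold: float) -> list[tuple[int, int]]:
    """Merge maximal runs of tokens with surprisal > threshold into spans."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    spans: list[tuple[int, int]] = []
    for score in scores:
        if score.surprisal > threshold:
            if spans and spans[-1][1] == score.position:
                spans[-1] = (spans[-1][0], score.position + 1)
            else:
                spans.append((score.position, score.position + 1))
    return spans


def suggest_correction(
    model: ContextModel,
    text: str,
    span: tuple[int, int],
    candidates: Sequence[str],
) -> list[CorrectionCandidate]:
    """Rank confusion-set candidates by in-context pseudo-log-likelihood.

    Each candidate is substituted into the span and the mean log-probability
    over the affected window (span ± model order) is its context score.
    Ties break lexicographically by surface for determinism.
    """
    if not candidates:
        raise SuggestionError("no candidates to rank")
    start, end = span
    ranked = []
    for candidate in candidates:
        variant = text[:start] + candidate + text[end:]
        lo = max(0, start - model.order)
        hi = min(len(variant), start + len(candidate) + model.order)
        window = score_tokens(model, variant)[lo:hi]
        mean_logp = float(np.mean([math.log(s.probability) for s in window]))
        ranked.append(CorrectionCandidate(surface=candidate, context_score=mean_logp))
    ranked.sort(key=lambda c: (-c.context_score, c.surface))
    return ranked


def pseudo_log_likelihood(model: ContextModel, text: str) -> float:
    """Sum of per-token log probabilities (higher = more fluent)."""
    return float(sum(math.log(s.probability) for s in score_tokens(model, text)))


def calibrate_threshold(
    model: ContextModel,
    clean_texts: Sequence[str],
    target_false_flag_rate: float = 0.05,
) -> float:
    """Surprisal cutoff such that at most *target_false_flag_rate* of clean
    reports carry any flag, estimated on a held-out clean split."""
    if not clean_texts:
        raise ValueError("calibration split is empty")
    maxima = np.asarray(
        [max(s.surprisal for s in score_tokens(model, t)) for t in _texts(clean_texts)]
    )
    return float(
        np.quantile(maxima, 1.0 - target_false_flag_rate, method="higher") + 1e-9
    )
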