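"""tf-idf feature ranking, Naïve Bayes training, and relation extraction.

The classifier is a multinomial Naïve Bayes over bag-of-context-words around
co-mentioned entity pairs, with Laplace-style pseudo-count smoothing.  Two
tasks share the machinery: a binary plant-compound task (classes ``related``
/ ``unrelated``) and a three-class plant-disease task (``preventive`` /
``promoting`` / ``noise``), where only the first two classes emit edges and
their sign.

Candidate lexical features are ranked by tf-idf (raw term frequency across
all contexts times ln(N/df)), and the working feature set is grown from the
top of that ranking one feature at a time until leave-one-out accuracy on the
shuffled training set stops improving for a configurable number of steps
(a patience/tolerance plateau).
"""

from __future__ import annotations

import json
import math
import random
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .entity_tagging import TaggedAbstract, extract_candidates

__all__ = [
    "CONTENT_CLASSES",
    "DISEASE_CLASSES",
    "FeatureRanking",
    "NaiveBayesModel",
    "EvaluationResult",
    "ContentEdge",
    "SignedEdge",
    "rank_features_tfidf",
    "train_naive_bayes",
    "classify",
    "select_features_incremental",
    "evaluate",
    "extract_relations",
    "label_candidates",
]

CONTENT_CLASSES = ("related", "unrelated")
DISEASE_CLASSES = ("preventive", "promoting", "noise")

#: map an abstract-level truth relation to the task label
_CONTENT_LABEL = {"contains": "related"}
_DISEASE_LABEL = {"prevents": "preventive", "promotes": "promoting"}

LabelledContext = tuple[str, Sequence[str]]


@dataclass(frozen=True)
class FeatureRanking:
    """tf-idf ranked tokens, descending score, lexicographic tie-break."""

    items: tuple[tuple[str, float], ...]

    def __post_init__(self):
        keys = [(-s, t) for t, s in self.items]
        if keys != sorted(keys):
            raise ValueError("ranking not sorted")
        tokens = [t for t, _ in self.items]
        if len(tokens) != len(set(tokens)):
            raise ValueError("duplicate token in ranking")

    def tokens(self) -> list[str]:
        return [t for t, _ in self.items]

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class NaiveBayesModel:
    classes: tuple[str, ...]
    priors: dict[str, float]
    cond: dict[tuple[str, str], float]
    features: frozenset[str]
    smoothing: float

    def __post_init__(self):
        if abs(sum(self.priors.values()) - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        for c in self.classes:
            for f in self.features:
                p = self.cond[(c, f)]
                # 1.0 occurs only in the degenerate single-feature model,
                # where the multinomial conditional is identically one
                if not 0.0 < p <= 1.0 or (p == 1.0 and len(self.features) > 1):
                    raise ValueError("conditional out of range")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "classes": list(self.classes),
            "priors": self.priors,
            "log_cond": {f"{c}\t{f}": math.log(p)
                         for (c, f), p in sorted(self.cond.items())},
            "features": sorted(self.features),
            "smoothing": self.smoothing,
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NaiveBayesModel":
        d = json.loads(text)
        cond = {}
        for key, lp in d["log_cond"].items():
            c, f = key.split("\t")
            cond[(c, f)] = math.exp(lp)
        return cls(classes=tuple(d["classes"]), priors=d["priors"],
                   cond=cond, features=frozenset(d["features"]),
                   smoothing=d["smoothing"])


@dataclass(frozen=True)
class EvaluationResult:
    accuracy: float
    precision: float
    recall: float
    f1: float
    n: int


@dataclass(frozen=True)
class ContentEdge:
    plant_id: str
    compound_id: str
    abstract_id: str
    posterior: float


@dataclass(frozen=True)
class SignedEdge:
    plant_id: str
    disease_id: str
    sign: str  # "positive" (preventive) or "negative" (promoting)
    abstract_id: str
    year: int
    posterior: float


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def rank_features_tfidf(contexts: Iterable[LabelledContext]) -> FeatureRanking:
    """Rank tokens by tf * ln(N/df) over candidate contexts as documents."""
    docs = [toks for _, toks in contexts if toks]
    if not docs:
        raise ValueError("no non-empty contexts")
    n = len(docs)
    tf: Counter = Counter()
    df: Counter = Counter()
    for toks in docs:
        tf.update(toks)
        df.update(set(toks))
    scored = [(t, tf[t] * math.log(n / df[t])) for t in tf]
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return FeatureRanking(tuple(scored))


# ---------------------------------------------------------------------------
# training and classification
# ---------------------------------------------------------------------------

def train_naive_bayes(train: Sequence[LabelledContext],
                      features: Iterable[str],
                      smoothing: float = 1.0) -> NaiveBayesModel:
    """Multinomial NB restricted to ``features``; out-of-feature tokens are
    ignored both in totals and at classification time."""
    features = frozenset(features)
    if not features:
        raise ValueError("empty feature set")
    if smoothing <= 0:
        raise ValueError("smoothing must be > 0")
    classes = tuple(sorted({label for label, _ in train}))
    n = len(train)
    n_c: Counter = Counter(label for label, _ in train)
    if any(n_c[c] == 0 for c in classes) or not classes:
        raise ValueError("every class needs at least one example")
    counts: dict[str, Counter] = {c: Counter() for c in classes}
    for label, toks in train:
        counts[label].update(t for t in toks if t in features)
    cond = {}
    for c in classes:
        total = sum(counts[c].values())
        denom = total + smoothing * len(features)
        for f in features:
            cond[(c, f)] = (counts[c][f] + smoothing) / denom
    priors = {c: n_c[c] / n for c in classes}
    return NaiveBayesModel(classes=classes, priors=priors, cond=cond,
                           features=features, smoothing=smoothing)


def classify(model: NaiveBayesModel,
             context: Sequence[str]) -> tuple[str, float]:
    """Return (argmax label, normalized posterior); lexicographic tie-break.

    A context with no model feature falls back to the priors.
    """
    counts = Counter(t for t in context if t in model.features)
    scores = {}
    for c in model.classes:
        s = math.log(model.priors[c]) if model.priors[c] > 0 else -math.inf
        for f, k in counts.items():
            s += k * math.log(model.cond[(c, f)])
        scores[c] = s
    top = max(scores.values())
    weights = {c: math.exp(s - top) for c, s in scores.items()}
    z = sum(weights.values())
    posteriors = {c: w / z for c, w in weights.items()}
    best = min(c for c in model.classes if scores[c] == top)
    return best, posteriors[best]


def posterior_distribution(model: NaiveBayesModel,
                           context: Sequence[str]) -> dict[str, float]:
    """Full normalized posterior over classes (diagnostic helper)."""
    counts = Counter(t for t in context if t in model.features)
    scores = {}
    for c in model.classes:
        s = math.log(model.priors[c]) if model.priors[c] > 0 else -math.inf
        for f, k in counts.items():
            s += k * math.log(model.cond[(c, f)])
        scores[c] = s
    top = max(scores.values())
    weights = {c: math.exp(s - top) for c, s in scores.items()}
    z = sum(weights.values())
    return {c: w / z for c, w in weights.items()}


# ---------------------------------------------------------------------------
# LOOCV and incremental feature selection
# ---------------------------------------------------------------------------

def loocv_accuracy(train: Sequence[LabelledContext],
                   features: Iterable[str], smoothing: float = 1.0) -> float:
    """Leave-one-out accuracy; each example is scored by a model trained on
    the remaining ones (classes that vanish from the fold are excluded from
    the argmax, which scores the held-out example wrong if it was the sole
    member of its class)."""
    features = frozenset(features)
    n = len(train)
    if n < 2:
        raise ValueError("need at least two training examples")
    classes = tuple(sorted({label for label, _ in train}))
    n_c = Counter(label for label, _ in train)
    totals: dict[str, Counter] = {c: Counter() for c in classes}
    doc_counts: list[Counter] = []
    for label, toks in train:
        dc = Counter(t for t in toks if t in features)
        doc_counts.append(dc)
        totals[label].update(dc)

    s = smoothing
    nf = len(features)
    correct = 0
    for i, (label, _) in enumerate(train):
        dc = doc_counts[i]
        best_c, best_s = None, -math.inf
        for c in classes:
            m = n_c[c] - (1 if c == label else 0)
            if m == 0:
                continue
            score = math.log(m / (n - 1))
            held = dc if c == label else None
            total_c = sum(totals[c].values()) - (sum(dc.values()) if held else 0)
            denom = total_c + s * nf
            for f, k in dc.items():
                cnt = totals[c][f] - (dc[f] if held else 0)
                score += k * math.log((cnt + s) / denom)
            if score > best_s or (score == best_s and c < best_c):
                best_c, best_s = c, score
        if best_c == label:
            correct += 1
    return correct / n


def _plateau_cut(trace: Sequence[float], tolerance: float,
                 patience: int) -> int:
    """Number of features at the start of the first plateau.

    A plateau is ``patience`` consecutive steps whose accuracy improvement
    over the previous step is <= ``tolerance``; if none occurs the whole
    ranking is kept.
    """
    run = 0
    for k in range(1, len(trace)):
        if trace[k] - trace[k - 1] <= tolerance:
            run += 1
        else:
            run = 0
        if run >= patience:
            return k + 1 - patience
    return len(trace)


def select_features_incremental(train: Sequence[LabelledContext],
                                ranking: FeatureRanking,
                                patience: int = 5,
                                tolerance: float = 0.0,
                                smoothing: float = 1.0,
                                shuffle_seed: int = 42,
                                max_features: int | None = None,
                                ) -> tuple[list[str], list[float]]:
    """Grow the feature set from the top of ``ranking`` until the LOOCV
    accuracy plateaus; return the selected (ordered) features and the full
    accuracy trace."""
    if len(ranking) < 1:
        raise ValueError("ranking must contain at least one feature")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    shuffled = list(train)
    random.Random(shuffle_seed).shuffle(shuffled)
    tokens = ranking.tokens()
    if max_features is not None:
        tokens = tokens[:max_features]
    trace: list[float] = []
    for k in range(1, len(tokens) + 1):
        trace.append(loocv_accuracy(shuffled, tokens[:k], smoothing))
        run = 0
        for j in range(1, len(trace)):
            if trace[j] - trace[j - 1] <= tolerance:
                run += 1
            else:
                run = 0
        if run >= patience:
            break
    cut = _plateau_cut(trace, tolerance, patience)
    return tokens[:cut], trace


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(model: NaiveBayesModel, test: Sequence[LabelledContext],
             positive_label: str) -> EvaluationResult:
    """Accuracy over all classes; precision/recall/F1 one-vs-rest for
    ``positive_label``."""
    if not test:
        raise ValueError("empty test set")
    if positive_label not in model.classes:
        raise ValueError(f"{positive_label!r} not among model classes")
    tp = fp = fn = correct = 0
    for label, toks in test:
        pred, _ = classify(model, toks)
        if pred == label:
            correct += 1
        if pred == positive_label and label == positive_label:
            tp += 1
        elif pred == positive_label:
            fp += 1
        elif label == positive_label:
            fn += 1
    n = len(test)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return EvaluationResult(accuracy=correct / n, precision=precision,
                            recall=recall, f1=f1, n=n)


# ---------------------------------------------------------------------------
# corpus-level application
# ---------------------------------------------------------------------------

def label_candidates(tagged: TaggedAbstract, task: str,
                     window: int = 10) -> list[LabelledContext]:
    """Labelled (label, context) pairs for training, from abstract truth.

    ``task`` is ``"content"`` (binary) or ``"disease"`` (three-class).  A
    candidate whose id pair carries an informative truth relation gets that
    relation's task label; any other co-mention is ``unrelated`` / ``noise``.
    """
    if task not in ("content", "disease"):
        raise ValueError(f"unknown task {task!r}")
    partner = "compound" if task == "content" else "disease"
    fallback = "unrelated" if task == "content" else "noise"
    label_map = _CONTENT_LABEL if task == "content" else _DISEASE_LABEL
    truth = {}
    a = tagged.abstract
    entries = a["truth"] if isinstance(a, dict) else a.truth
    for (x, y, rel) in entries:
        truth[frozenset((x, y))] = rel
    out = []
    for cand in extract_candidates(tagged, partner, window):
        rel = truth.get(frozenset((cand.plant.entity_id,
                                   cand.partner.entity_id)))
        out.append((label_map.get(rel, fallback), cand.context))
    return out


def extract_relations(corpus: Sequence[TaggedAbstract],
                      model_content: NaiveBayesModel | None,
                      model_disease: NaiveBayesModel | None,
                      window: int = 10,
                      ) -> tuple[list[ContentEdge], list[SignedEdge]]:
    """Classify every candidate in the tagged corpus and emit edges.

    ``related`` candidates become plant-compound content edges;
    ``preventive`` / ``promoting`` candidates become signed plant-disease
    edges carrying the abstract's year.  ``unrelated`` / ``noise`` candidates
    emit nothing.  Edges keep abstract-level granularity.
    """
    if model_content is not None and set(model_content.classes) != set(CONTENT_CLASSES):
        raise ValueError("content model has wrong classes for the task")
    if model_disease is not None and set(model_disease.classes) != set(DISEASE_CLASSES):
        raise ValueError("disease model has wrong classes for the task")
    content_edges: list[ContentEdge] = []
    signed_edges: list[SignedEdge] = []
    for tagged in corpus:
        if model_content is not None:
            for cand in extract_candidates(tagged, "compound", window):
                label, post = classify(model_content, cand.context)
                if label == "related":
                    content_edges.append(ContentEdge(
                        cand.plant.entity_id, cand.partner.entity_id,
                        tagged.abstract_id, post))
        if model_disease is not None:
            for cand in extract_candidates(tagged, "disease", window):
                label, post = classify(model_disease, cand.context)
                if label in ("preventive", "promoting"):
                    sign = "positive" if label == "preventive" else "negative"
                    signed_edges.append(SignedEdge(
                        cand.plant.entity_id, cand.partner.entity_id, sign,
                        tagged.abstract_id, tagged.year, post))
    return content_edges, signed_edges
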