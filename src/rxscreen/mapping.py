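"""Topic-mapping (TM) anomaly scores.

Each in-vocabulary diagnosis tags its high-probability topics; the union of
those tags is the prescription's reference set. Each medication is then
tested against it: a medication whose own tagged topics miss the reference
set entirely — or which is out of vocabulary — contributes an anomaly score
of 1. The prescription's score is the sum over its medications, so it is an
integer in 0..(number of medications), and thresholds 1..5 turn it into a
screening flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus import EncodedCorpus, PrescriptionRecord
from .infer import infer_theta
from .model import MVLDAModel

__all__ = [
    "TagRule",
    "TopicTagSet",
    "AnomalyResult",
    "OutOfVocabularyError",
    "feature_topic_posterior",
    "tag_topics",
    "tm_score",
    "score_records",
    "score_corpus",
    "classify",
    "theta_disagreement_score",
]


class OutOfVocabularyError(KeyError):
    """Term not present in the model vocabulary for the requested view."""


@dataclass(frozen=True)
class TagRule:
    """How "high probability" topics are selected for a term.

    ``top_n``: the n highest-posterior topics (ties broken by ascending
    topic index). ``mass``: the smallest prefix of descending-sorted topics
    whose cumulative posterior reaches q. Exactly one must be set.
    """

    top_n: int | None = 1
    mass: float | None = None

    def __post_init__(self):
        if (self.top_n is None) == (self.mass is None):
            raise ValueError("set exactly one of top_n or mass")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.mass is not None and not (0 < self.mass <= 1):
            raise ValueError("mass must be in (0, 1]")

    @classmethod
    def parse(cls, text: str) -> "TagRule":
        """Parse 'top_n:1' or 'mass:0.8'."""
        kind, _, value = text.partition(":")
        if kind == "top_n":
            return cls(top_n=int(value))
        if kind == "mass":
            return cls(top_n=None, mass=float(value))
        raise ValueError(f"unknown tag rule {text!r}")


@dataclass
class TopicTagSet:
    term: str
    view: str
    topics: frozenset[int]
    rule: TagRule


@dataclass
class AnomalyResult:
    """TM score for one prescription and its decision at a threshold.

    ``contributions`` gives the per-medication 0/1 mismatch indicators in
    medication order; they are diagnostic output only — the validated signal
    is the prescription-level score, not which medication tripped it.
    """

    prescription_id: str
    score: int
    contributions: list[int] = field(default_factory=list)
    flagged: bool = False
    threshold: int = 1


def feature_topic_posterior(model: MVLDAModel, term: str, view: str) -> np.ndarray:
    """p(topic | term) under a uniform topic prior: the term's phi column
    renormalized. Raises OutOfVocabularyError for unknown terms."""
    if view == "A":
        vocab, phi = model.vocab_A, model.phi_A
    elif view == "B":
        vocab, phi = model.vocab_B, model.phi_B
    else:
        raise ValueError("view must be 'A' or 'B'")
    idx = vocab.get(term)
    if idx is None:
        raise OutOfVocabularyError(f"term {term!r} not in view-{view} vocabulary")
    col = phi[:, idx]
    return col / col.sum()


def tag_topics(
    posterior: np.ndarray, rule: TagRule, term: str = "", view: str = ""
) -> TopicTagSet:
    """Select a term's high-probability topics under the given rule."""
    posterior = np.asarray(posterior, dtype=float)
    K = posterior.shape[0]
    # stable sort on -p → ties resolved toward the lower topic index
    order = np.argsort(-posterior, kind="stable")
    if rule.top_n is not None:
        n = min(rule.top_n, K)
        topics = frozenset(int(k) for k in order[:n])
    else:
        cum = np.cumsum(posterior[order])
        n = int(np.searchsorted(cum, rule.mass - 1e-12) + 1)
        topics = frozenset(int(k) for k in order[:n])
    return TopicTagSet(term=term, view=view, topics=topics, rule=rule)


def _tag_term(model: MVLDAModel, term: str, view: str, rule: TagRule) -> TopicTagSet | None:
    try:
        post = feature_topic_posterior(model, term, view)
    except OutOfVocabularyError:
        return None
    return tag_topics(post, rule, term=term, view=view)


def tm_score(
    model: MVLDAModel,
    record: PrescriptionRecord,
    rule: TagRule = TagRule(top_n=1),
    threshold: int = 1,
    symmetric: bool = False,
) -> AnomalyResult:
    """TM anomaly score for one prescription.

    Diagnoses define the reference tag set (their union); each medication
    contributes 1 iff its tagged topics do not intersect it. Out-of-vocabulary
    medications contribute 1 (an unseen drug-diagnosis pairing is exactly what
    screening should surface); out-of-vocabulary diagnoses are ignored when
    forming the reference set, and a prescription with no in-vocabulary
    diagnoses scores every medication. ``symmetric`` additionally tests each
    diagnosis against the medication-tagged union and adds those mismatches.
    """
    if threshold < 1:
        raise ValueError("threshold must be a positive integer")
    diag_tags = [
        t for t in (_tag_term(model, d, "A", rule) for d in record.diagnoses) if t
    ]
    ref = frozenset().union(*(t.topics for t in diag_tags)) if diag_tags else frozenset()
    contributions: list[int] = []
    for med in record.medications:
        tag = _tag_term(model, med, "B", rule)
        if tag is None:
            contributions.append(1)
        else:
            contributions.append(0 if tag.topics & ref else 1)
    score = int(sum(contributions))
    if symmetric:
        med_tags = [
            t for t in (_tag_term(model, m, "B", rule) for m in record.medications) if t
        ]
        med_ref = (
            frozenset().union(*(t.topics for t in med_tags)) if med_tags else frozenset()
        )
        for tag in diag_tags:
            if not (tag.topics & med_ref):
                score += 1
    return AnomalyResult(
        prescription_id=record.prescription_id,
        score=score,
        contributions=contributions,
        flagged=score >= threshold,
        threshold=threshold,
    )


def score_records(
    model: MVLDAModel,
    records: Iterable[PrescriptionRecord],
    rule: TagRule = TagRule(top_n=1),
    threshold: int = 1,
    symmetric: bool = False,
) -> list[AnomalyResult]:
    return [tm_score(model, r, rule, threshold, symmetric) for r in records]


def score_corpus(
    model: MVLDAModel,
    corpus: EncodedCorpus,
    rule: TagRule = TagRule(top_n=1),
    threshold: int = 1,
) -> list[AnomalyResult]:
    """Score every prescription of an encoded corpus (decoded through its
    own vocabularies, so terms unseen by the model are handled as OOV)."""
    return score_records(model, corpus.records(), rule, threshold)


def classify(results: Sequence[AnomalyResult], threshold: int) -> np.ndarray:
    """Binary flags at an integer threshold >= 1: flagged ⇔ score >= threshold."""
    if not isinstance(threshold, (int, np.integer)) or isinstance(threshold, bool):
        raise TypeError("threshold must be an integer")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return np.asarray([int(r.score >= threshold) for r in results], dtype=np.int8)


def theta_disagreement_score(
    model: MVLDAModel,
    record: PrescriptionRecord,
    n_sweeps: int = 200,
    burn_in: int = 100,
    seed: int = 0,
) -> float:
    """Alternative (non-default) scorer: total-variation distance between the
    separately inferred diagnosis-view and medication-view topic proportions.
    Continuous in [0, 1]; large values mean the two views tell different
    stories."""
    theta_A, _, _ = infer_theta(model, record, "A", n_sweeps, burn_in, seed)
    theta_B, _, _ = infer_theta(model, record, "B", n_sweeps, burn_in, (seed + 1) % (2**31))
    return float(0.5 * np.abs(theta_A - theta_B).sum())
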