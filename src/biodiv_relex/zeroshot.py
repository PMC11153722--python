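"""Zero-shot relation classification via boolean QA and NLI templates.

For a candidate pair the sentence becomes the passage (boolean QA) or the
premise (NLI), and the query is filled from one of four fixed templates,
entity surface text inserted verbatim — deliberately without grammatical
normalization, since the underlying models tolerate slightly ungrammatical
queries:

* has_location question:   ``Is there <habitat> in <geographic location>?``
* has_time question:       ``Did <reproductive condition> event happen on <temporal expression>?``
* has_location hypothesis: ``The <habitat> was in <geographic location>.``
* has_time hypothesis:     ``The <reproductive condition> event happened on <temporal expression>.``

A *backend* answers queries: Yes/No for boolean QA, or
entailment/neutral/contradiction for NLI.  Yes and entailment map to a
positive relation label; everything else maps to negative.  Backends must
be deterministic (sampling disabled).  Three adapters wrap published
checkpoints fine-tuned for BoolQ/NLI (loaded lazily, requiring the optional
``transformers`` dependency); :class:`MockBackend` answers from an explicit
lookup table or per-pair labels and is the offline/testing backend.

When a *compound* target (a run of coordinated same-type mentions) is
queried, one query covers all member pairs and its verdict propagates
uniformly to each of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Union

from .model import EntityMention, RelationInstance, RelationType
from .rules import CompoundEntity


class QueryMode(Enum):
    BOOL_QA = "bool_qa"
    NLI = "nli"


class VerdictLabel(Enum):
    YES = "yes"
    NO = "no"
    ENTAILMENT = "entailment"
    NEUTRAL = "neutral"
    CONTRADICTION = "contradiction"


_MODE_LABELS = {
    QueryMode.BOOL_QA: {VerdictLabel.YES, VerdictLabel.NO},
    QueryMode.NLI: {
        VerdictLabel.ENTAILMENT,
        VerdictLabel.NEUTRAL,
        VerdictLabel.CONTRADICTION,
    },
}

_POSITIVE_LABELS = {VerdictLabel.YES, VerdictLabel.ENTAILMENT}


class BackendUnavailableError(RuntimeError):
    """A model backend cannot be loaded (offline, or dependency missing)."""


class VerdictContractError(ValueError):
    """A verdict's label does not belong to the query's mode."""


@dataclass(frozen=True)
class QueryItem:
    """One filled template plus the pairs its answer decides."""

    mode: QueryMode
    context_text: str
    query_text: str
    covered_pairs: tuple[tuple[EntityMention, EntityMention], ...]
    relation_type: RelationType
    sent_id: str = ""


@dataclass(frozen=True)
class BackendVerdict:
    label: VerdictLabel
    score: Optional[float] = None


def question_text(relation_type: RelationType, source_text: str, target_text: str) -> str:
    if relation_type is RelationType.HAS_LOCATION:
        return f"Is there {source_text} in {target_text}?"
    return f"Did {source_text} event happen on {target_text}?"


def hypothesis_text(relation_type: RelationType, source_text: str, target_text: str) -> str:
    if relation_type is RelationType.HAS_LOCATION:
        return f"The {source_text} was in {target_text}."
    return f"The {source_text} event happened on {target_text}."


def _build_query(
    mode: QueryMode,
    instance: RelationInstance,
    target: Optional[CompoundEntity],
) -> QueryItem:
    if target is None:
        target_text = instance.target.text
        covered = ((instance.source, instance.target),)
    else:
        target_text = target.joined_text
        covered = tuple((instance.source, member) for member in target.members)
    maker = question_text if mode is QueryMode.BOOL_QA else hypothesis_text
    if not instance.source.text or not target_text:
        raise ValueError("entity texts must be nonempty to fill a template")
    context = instance.sentence.text if instance.sentence is not None else ""
    return QueryItem(
        mode=mode,
        context_text=context,
        query_text=maker(instance.relation_type, instance.source.text, target_text),
        covered_pairs=covered,
        relation_type=instance.relation_type,
        sent_id=instance.sent_id,
    )


def make_question(
    instance: RelationInstance, target: Optional[CompoundEntity] = None
) -> QueryItem:
    """Boolean-QA query for an instance (or its compound target)."""
    return _build_query(QueryMode.BOOL_QA, instance, target)


def make_hypothesis(
    instance: RelationInstance, target: Optional[CompoundEntity] = None
) -> QueryItem:
    """NLI premise-hypothesis query for an instance (or its compound target)."""
    return _build_query(QueryMode.NLI, instance, target)


def validate_verdict(query: QueryItem, verdict: BackendVerdict) -> None:
    if verdict.label not in _MODE_LABELS[query.mode]:
        raise VerdictContractError(
            f"verdict {verdict.label.value!r} is not valid for mode {query.mode.value!r}"
        )


def verdict_to_label(verdict: BackendVerdict) -> int:
    """1 for Yes/entailment, else 0."""
    return 1 if verdict.label in _POSITIVE_LABELS else 0


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

def pair_key(
    sent_id: str, relation_type: RelationType, source: EntityMention, target: EntityMention
) -> tuple:
    return (
        sent_id,
        relation_type.value,
        source.start,
        source.end,
        target.start,
        target.end,
    )


class Backend:
    """Contract: ``classify(query) -> BackendVerdict``, deterministic per query."""

    name = "backend"

    def classify(self, query: QueryItem) -> BackendVerdict:  # pragma: no cover
        raise NotImplementedError


class MockBackend(Backend):
    """Deterministic offline backend for tests and dry runs.

    Resolution order per query: explicit ``lookup`` by query text; then
    ``pair_labels`` (positive iff any covered pair is marked 1); then a
    ``heuristic`` callable on the query; then ``default`` (negative).
    """

    name = "mock"

    def __init__(
        self,
        lookup: Optional[Mapping[str, Union[VerdictLabel, str, int, bool]]] = None,
        pair_labels: Optional[Mapping[tuple, int]] = None,
        heuristic: Optional[Callable[[QueryItem], bool]] = None,
        default: bool = False,
    ):
        self.lookup = dict(lookup or {})
        self.pair_labels = dict(pair_labels or {})
        self.heuristic = heuristic
        self.default = default

    @staticmethod
    def _positive_for(mode: QueryMode, positive: bool) -> VerdictLabel:
        if mode is QueryMode.BOOL_QA:
            return VerdictLabel.YES if positive else VerdictLabel.NO
        return VerdictLabel.ENTAILMENT if positive else VerdictLabel.NEUTRAL

    @staticmethod
    def _coerce(value: Union[VerdictLabel, str, int, bool]) -> Union[VerdictLabel, bool]:
        if isinstance(value, VerdictLabel):
            return value
        if isinstance(value, str):
            return VerdictLabel(value.lower())
        return bool(value)

    def classify(self, query: QueryItem) -> BackendVerdict:
        if query.query_text in self.lookup:
            value = self._coerce(self.lookup[query.query_text])
            if isinstance(value, VerdictLabel):
                return BackendVerdict(label=value)
            return BackendVerdict(label=self._positive_for(query.mode, value))
        if self.pair_labels:
            positive = any(
                self.pair_labels.get(
                    pair_key(query.sent_id, query.relation_type, s, t), 0
                )
                == 1
                for s, t in query.covered_pairs
            )
            return BackendVerdict(label=self._positive_for(query.mode, positive))
        if self.heuristic is not None:
            return BackendVerdict(
                label=self._positive_for(query.mode, bool(self.heuristic(query)))
            )
        return BackendVerdict(label=self._positive_for(query.mode, self.default))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "MockBackend":
        """Load a {query_text: answer} lookup table from a JSON file."""
        table = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(lookup=table)


def gold_echo_backend(gold: Iterable[RelationInstance]) -> MockBackend:
    """MockBackend that answers according to gold pair labels."""
    labels = {
        pair_key(inst.sent_id, inst.relation_type, inst.source, inst.target): inst.label
        for inst in gold
        if inst.label in (0, 1)
    }
    return MockBackend(pair_labels=labels)


class CountingBackend(Backend):
    """Wrapper counting classify() calls; used for efficiency checks."""

    def __init__(self, inner: Backend):
        self.inner = inner
        self.calls = 0
        self.name = f"counting({inner.name})"

    def classify(self, query: QueryItem) -> BackendVerdict:
        self.calls += 1
        return self.inner.classify(query)


class _TransformerBackend(Backend):
    """Shared lazy-loading machinery for the published-checkpoint adapters."""

    model_id = ""

    def __init__(self, model_id: Optional[str] = None):
        if model_id:
            self.model_id = model_id
        self._model = None
        self._tokenizer = None

    def _load(self):  # pragma: no cover - requires optional heavy deps
        if self._model is not None:
            return
        try:
            import transformers  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                f"backend {self.name!r} needs the optional 'transformers' "
                "dependency (and network access to fetch the checkpoint "
                f"{self.model_id!r}); for offline or test runs use "
                "MockBackend (backend name 'mock')"
            ) from exc
        self._load_model()

    def _load_model(self):  # pragma: no cover
        raise NotImplementedError


class RobertaBoolQBackend(_TransformerBackend):
    """Sequence-classification BoolQ adapter (argmax over Yes/No logits)."""

    name = "roberta-boolq"
    model_id = "shahrukhx01/roberta-base-boolq"

    def _load_model(self):  # pragma: no cover
        from transformers import AutoModelForSequenceClassification, AutoTokenizer

        self._tokenizer = AutoTokenizer.from_pretrained(self.model_id)
        self._model = AutoModelForSequenceClassification.from_pretrained(self.model_id)
        self._model.eval()

    def classify(self, query: QueryItem) -> BackendVerdict:  # pragma: no cover
        self._load()
        import torch

        inputs = self._tokenizer(
            query.query_text, query.context_text, return_tensors="pt", truncation=True
        )
        with torch.no_grad():
            logits = self._model(**inputs).logits[0]
        probs = torch.softmax(logits, dim=-1)
        yes_index = 1  # label 1 = yes in the published checkpoint
        positive = bool(probs[yes_index] >= 0.5)
        return BackendVerdict(
            label=VerdictLabel.YES if positive else VerdictLabel.NO,
            score=float(probs[yes_index]),
        )


class T5BoolQBackend(_TransformerBackend):
    """Text-to-text BoolQ adapter (greedy decode of 'True'/'False')."""

    name = "t5-boolq"
    model_id = "mrm8488/t5-base-finetuned-boolq"

    def _load_model(self):  # pragma: no cover
        from transformers import AutoModelForSeq2SeqLM, AutoTokenizer

        self._tokenizer = AutoTokenizer.from_pretrained(self.model_id)
        self._model = AutoModelForSeq2SeqLM.from_pretrained(self.model_id)
        self._model.eval()

    def classify(self, query: QueryItem) -> BackendVerdict:  # pragma: no cover
        self._load()
        text = f"question: {query.query_text} context: {query.context_text}"
        inputs = self._tokenizer(text, return_tensors="pt", truncation=True)
        output = self._model.generate(**inputs, do_sample=False, max_new_tokens=4)
        answer = self._tokenizer.decode(output[0], skip_special_tokens=True).strip().lower()
        positive = answer in ("yes", "true")
        return BackendVerdict(label=VerdictLabel.YES if positive else VerdictLabel.NO)


class T5NLIBackend(_TransformerBackend):
    """T5 MNLI adapter: maps the generated token to the three NLI labels."""

    name = "t5-nli"
    model_id = "t5-large"

    def _load_model(self):  # pragma: no cover
        from transformers import AutoModelForSeq2SeqLM, AutoTokenizer

        self._tokenizer = AutoTokenizer.from_pretrained(self.model_id)
        self._model = AutoModelForSeq2SeqLM.from_pretrained(self.model_id)
        self._model.eval()

    def classify(self, query: QueryItem) -> BackendVerdict:  # pragma: no cover
        self._load()
        text = f"mnli premise: {query.context_text} hypothesis: {query.query_text}"
        inputs = self._tokenizer(text, return_tensors="pt", truncation=True)
        output = self._model.generate(**inputs, do_sample=False, max_new_tokens=4)
        answer = self._tokenizer.decode(output[0], skip_special_tokens=True).strip().lower()
        mapping = {
            "entailment": VerdictLabel.ENTAILMENT,
            "neutral": VerdictLabel.NEUTRAL,
            "contradiction": VerdictLabel.CONTRADICTION,
        }
        return BackendVerdict(label=mapping.get(answer, VerdictLabel.NEUTRAL))


_BACKENDS: dict[str, Callable[..., Backend]] = {
    "mock": MockBackend,
    "roberta-boolq": RobertaBoolQBackend,
    "t5-boolq": T5BoolQBackend,
    "t5-nli": T5NLIBackend,
}


def resolve_backend(name: str, **kwargs) -> Backend:
    """Instantiate a backend by config name.

    Names: ``mock``, ``roberta-boolq``, ``t5-boolq``, ``t5-nli``. Extra
    keyword arguments are forwarded to the backend constructor.
    """
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return factory(**kwargs)


def default_query_mode(backend_name: str) -> QueryMode:
    return QueryMode.BOOL_QA if "boolq" in backend_name else QueryMode.NLI
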