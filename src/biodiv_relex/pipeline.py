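"""The two-step hybrid extractor and the method dispatcher.

Step 1 applies the high-precision token-type regex rules and labels every
matched pair positive.  Step 2 sends every remaining candidate to a
zero-shot backend — one query per pair, or, when compound grouping is on,
one query per (source, compound target run), whose verdict propagates to
every covered pair.  Rule positives are never overridden, every candidate
receives exactly one label, and the number of backend calls never exceeds
the number of candidates (compound grouping strictly reduces it whenever a
compound covers two or more still-open pairs).

``run_method`` exposes the comparison suite: the all-positive co-occurrence
baseline, the standalone regex rules (non-matches labelled 0), the
dependency-distance matcher, pure zero-shot boolean-QA/NLI, and the hybrid
with or without compound grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import dataset as _dataset
from . import dependency as _dependency
from .io import Document
from .model import RelationInstance, RelationType, Sentence
from .rules import (
    apply_regex_rules,
    detect_compound_entities,
    encode_token_types,
)
from .zeroshot import (
    Backend,
    BackendVerdict,
    QueryItem,
    QueryMode,
    make_hypothesis,
    make_question,
    resolve_backend,
    validate_verdict,
    verdict_to_label,
)

logger = logging.getLogger(__name__)

METHODS = (
    "cooccurrence",
    "regex",
    "distance",
    "boolqa",
    "nli",
    "hybrid",
    "hybrid_compound",
)


class MethodConfigError(ValueError):
    """Unknown method name or inconsistent pipeline configuration."""


class BackendRunError(RuntimeError):
    """Backend failed mid-run; ``partial`` holds the labels flushed so far."""

    def __init__(self, message: str, partial: list[RelationInstance]):
        super().__init__(message)
        self.partial = partial


@dataclass
class PipelineConfig:
    relation_type: RelationType
    use_compound: bool = False
    backend_name: str = "mock"
    query_mode: QueryMode = QueryMode.NLI
    distance_n: Optional[int] = None
    seed: int = 0
    compound_sources: bool = False  # compound grouping of source entities (off by default)

    def __post_init__(self) -> None:
        if self.distance_n is not None and self.distance_n < 1:
            raise MethodConfigError(f"distance_n must be >= 1, got {self.distance_n}")


@dataclass
class RunStats:
    """Per-run bookkeeping: candidate, rule, query and compound counts."""

    candidates: int = 0
    rule_positive: int = 0
    backend_queries: int = 0
    compound_queries: int = 0
    by_sentence: dict = field(default_factory=dict)


def _query_for(
    mode: QueryMode, instance: RelationInstance, compound=None
) -> QueryItem:
    if mode is QueryMode.BOOL_QA:
        return make_question(instance, compound)
    return make_hypothesis(instance, compound)


def _classify(
    backend: Backend,
    query: QueryItem,
    cache: dict[tuple, BackendVerdict],
    partial: list[RelationInstance],
) -> BackendVerdict:
    cache_key = (query.sent_id, query.query_text)
    if cache_key in cache:
        return cache[cache_key]
    try:
        verdict = backend.classify(query)
    except Exception as exc:  # noqa: BLE001 - re-raised with partial results
        if isinstance(exc, (KeyboardInterrupt, SystemExit)):
            raise
        raise BackendRunError(
            f"backend {backend.name!r} failed on query {query.query_text!r} "
            f"({len(partial)} instances labelled before failure): {exc}",
            partial=partial,
        ) from exc
    validate_verdict(query, verdict)
    cache[cache_key] = verdict
    return verdict


def _step2_queries(
    sentence: Sentence,
    relation_type: RelationType,
    remaining: list[RelationInstance],
    use_compound: bool,
    mode: QueryMode,
    compound_sources: bool = False,
) -> list[tuple[QueryItem, list[RelationInstance]]]:
    """Build step-2 queries and the open instances each one decides."""
    queries: list[tuple[QueryItem, list[RelationInstance]]] = []
    if not use_compound:
        return [(_query_for(mode, inst), [inst]) for inst in remaining]
    compounds = detect_compound_entities(sentence, relation_type.target_type)
    member_of = {}
    for comp in compounds:
        for m in comp.members:
            member_of[m] = comp
    singleton_queue: list[RelationInstance] = []
    by_source: dict = {}
    for inst in remaining:
        by_source.setdefault(inst.source, []).append(inst)
    for _source, insts in by_source.items():
        grouped: dict = {}
        singletons: list[RelationInstance] = []
        for inst in insts:
            comp = member_of.get(inst.target)
            if comp is None:
                singletons.append(inst)
            else:
                grouped.setdefault(id(comp), (comp, []))[1].append(inst)
        for comp, members in grouped.values():
            if len(members) >= 2:
                queries.append((_query_for(mode, members[0], comp), members))
            else:
                singletons.extend(members)
        singleton_queue.extend(singletons)
    if compound_sources:
        queries.extend(
            _group_singletons_by_source_compound(
                sentence, relation_type, singleton_queue, mode
            )
        )
    else:
        queries.extend((_query_for(mode, inst), [inst]) for inst in singleton_queue)
    return queries


def _group_singletons_by_source_compound(
    sentence: Sentence,
    relation_type: RelationType,
    singletons: list[RelationInstance],
    mode: QueryMode,
) -> list[tuple[QueryItem, list[RelationInstance]]]:
    """Optionally merge per-pair queries sharing a target whose sources form
    a compound run into one query filled with the joined source text."""
    from .zeroshot import QueryItem as _QI
    from .zeroshot import hypothesis_text, question_text

    source_comps = detect_compound_entities(sentence, relation_type.source_type)
    comp_of = {}
    for comp in source_comps:
        for m in comp.members:
            comp_of[m] = comp
    by_target: dict = {}
    leftovers: list[RelationInstance] = []
    for inst in singletons:
        comp = comp_of.get(inst.source)
        if comp is None:
            leftovers.append(inst)
        else:
            by_target.setdefault((inst.target, id(comp)), (comp, []))[1].append(inst)
    queries: list[tuple[QueryItem, list[RelationInstance]]] = []
    for (target, _cid), (comp, insts) in by_target.items():
        if len(insts) < 2:
            leftovers.extend(insts)
            continue
        maker = question_text if mode is QueryMode.BOOL_QA else hypothesis_text
        query = _QI(
            mode=mode,
            context_text=sentence.text,
            query_text=maker(relation_type, comp.joined_text, target.text),
            covered_pairs=tuple((inst.source, inst.target) for inst in insts),
            relation_type=relation_type,
            sent_id=sentence.sent_id,
        )
        queries.append((query, insts))
    queries.extend((_query_for(mode, inst), [inst]) for inst in leftovers)
    return queries


def run_hybrid(
    doc: Document,
    config: PipelineConfig,
    backend: Optional[Backend] = None,
    stats: Optional[RunStats] = None,
) -> list[RelationInstance]:
    """Run the two-step hybrid over a document; every candidate gets 0/1."""
    backend = backend if backend is not None else resolve_backend(config.backend_name)
    stats = stats if stats is not None else RunStats()
    verdict_cache: dict[tuple, BackendVerdict] = {}
    out: list[RelationInstance] = []
    for sentence in doc.sentences:
        cands = _dataset.generate_candidates(sentence, config.relation_type)
        stats.candidates += len(cands)
        if not cands:
            continue
        rule_pairs = apply_regex_rules(
            encode_token_types(sentence, config.relation_type)
        )
        labelled: dict[int, RelationInstance] = {}
        remaining: list[RelationInstance] = []
        for i, inst in enumerate(cands):
            if (inst.source, inst.target) in rule_pairs:
                labelled[i] = inst.with_label(1, predicted_by="rule")
                stats.rule_positive += 1
            else:
                remaining.append(inst)
        index_of = {inst.key: i for i, inst in enumerate(cands)}
        queries = _step2_queries(
            sentence, config.relation_type, remaining, config.use_compound,
            config.query_mode, compound_sources=config.compound_sources,
        )
        stats.backend_queries += len(queries)
        stats.compound_queries += sum(1 for _, insts in queries if len(insts) > 1)
        for query, insts in queries:
            verdict = _classify(backend, query, verdict_cache, out)
            y = verdict_to_label(verdict)
            for inst in insts:
                labelled[index_of[inst.key]] = inst.with_label(
                    y, predicted_by="backend"
                )
        out.extend(labelled[i] for i in sorted(labelled))
    logger.info(
        "hybrid run: %d candidates, %d rule positives, %d backend queries "
        "(%d compound)",
        stats.candidates, stats.rule_positive, stats.backend_queries,
        stats.compound_queries,
    )
    return out


def _run_zeroshot(
    doc: Document,
    relation_type: RelationType,
    mode: QueryMode,
    backend: Backend,
) -> list[RelationInstance]:
    out: list[RelationInstance] = []
    cache: dict[tuple, BackendVerdict] = {}
    for sentence in doc.sentences:
        for inst in _dataset.generate_candidates(sentence, relation_type):
            verdict = _classify(backend, _query_for(mode, inst), cache, out)
            out.append(
                inst.with_label(verdict_to_label(verdict), predicted_by="backend")
            )
    return out


def run_method(
    doc: Document,
    method: str,
    config: PipelineConfig,
    backend: Optional[Backend] = None,
    stats: Optional[RunStats] = None,
) -> list[RelationInstance]:
    """Dispatch to one of the comparison extractors.

    All methods return one labelled instance per candidate, in the same
    order, so their metrics are directly comparable.
    """
    if method not in METHODS:
        raise MethodConfigError(
            f"unknown method {method!r}; choose from {METHODS}"
        )
    if method == "cooccurrence":
        return _dataset.cooccurrence_baseline(
            _dataset.generate_all_candidates(doc, config.relation_type)
        )
    if method == "regex":
        out: list[RelationInstance] = []
        for sentence in doc.sentences:
            rule_pairs = apply_regex_rules(
                encode_token_types(sentence, config.relation_type)
            )
            for inst in _dataset.generate_candidates(sentence, config.relation_type):
                y = 1 if (inst.source, inst.target) in rule_pairs else 0
                out.append(inst.with_label(y, predicted_by="rule"))
        return out
    if method == "distance":
        n = config.distance_n if config.distance_n is not None else _dependency.DEFAULT_N
        return _dependency.predict_by_distance(
            _dataset.generate_all_candidates(doc, config.relation_type), n=n
        )
    if method in ("boolqa", "nli"):
        mode = QueryMode.BOOL_QA if method == "boolqa" else QueryMode.NLI
        backend = backend if backend is not None else resolve_backend(config.backend_name)
        return _run_zeroshot(doc, config.relation_type, mode, backend)
    # hybrid / hybrid_compound
    from dataclasses import replace

    cfg = replace(config, use_compound=(method == "hybrid_compound"))
    return run_hybrid(doc, cfg, backend=backend, stats=stats)
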