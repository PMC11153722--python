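"""Reading and writing of annotated corpora.

Two exchange formats are supported:

* **CoNLL-U with a ``biodiv`` FEATS extension.**  Standard 10-column
  CoNLL-U, where entity annotations ride in the FEATS (6th) column as a
  ``biodiv=<BIO-tag>`` feature, e.g. ``biodiv=B-Habitat`` on the first token
  of a habitat mention.  Keeping annotations inside FEATS keeps the files
  valid for ordinary CoNLL-U tooling.  Multiword-token ranges (``1-2``) and
  empty nodes (``1.1``) are skipped for entity and dependency purposes.

* **JSONL relation instances.**  One JSON object per line with keys
  ``sent_id, text, tokens, relation_type, source, target, label,
  predicted_by``; ``source``/``target`` are ``{type, start, end, text}``
  objects with 0-based token offsets; ``label`` is 0, 1 or null.

All files are UTF-8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

from .model import (
    ROOT,
    BioTagError,
    EntityMention,
    EntityType,
    RelationInstance,
    RelationType,
    Sentence,
    Token,
    decode_bio_tags,
    encode_bio_tags,
)

PathOrIO = Union[str, Path, IO[str]]


class ConlluParseError(ValueError):
    """Malformed CoNLL-U input; carries the 1-based line number."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class JsonlSchemaError(ValueError):
    """A JSONL record is missing a required key or has a bad value."""


@dataclass
class Document:
    """An ordered collection of sentences sharing a document id."""

    doc_id: str
    sentences: list[Sentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.sentences:
            if s.sent_id in seen:
                raise ValueError(f"duplicate sent_id {s.sent_id!r} in document")
            seen.add(s.sent_id)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def sentence_map(self) -> dict[str, Sentence]:
        return {s.sent_id: s for s in self.sentences}


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------

_N_COLUMNS = 10


def _split_feats(feats: str) -> tuple[Optional[str], str]:
    """Separate the biodiv feature from the rest of a FEATS cell.

    Returns (bio_tag_or_None, remaining_feats_string). The remaining string
    is "" when no other features are present.
    """
    if feats == "_" or feats == "":
        return None, ""
    bio: Optional[str] = None
    rest: list[str] = []
    for item in feats.split("|"):
        if item.startswith("biodiv="):
            bio = item[len("biodiv="):]
        else:
            rest.append(item)
    return bio, "|".join(rest)


def parse_conllu_biodiv(text: str, doc_id: str = "doc") -> Document:
    """Parse CoNLL-U text carrying ``biodiv=`` BIO features into a Document."""
    sentences: list[Sentence] = []
    cur_tokens: list[Token] = []
    cur_tags: list[str] = []
    cur_sent_id: Optional[str] = None
    cur_doc_id: Optional[str] = None
    id_remap: dict[int, int] = {}  # CoNLL-U 1-based id -> internal 0-based index
    raw_heads: list[Optional[int]] = []

    def flush(line_no: int) -> None:
        nonlocal cur_tokens, cur_tags, cur_sent_id, id_remap, raw_heads
        if not cur_tokens:
            cur_sent_id = None
            return
        # resolve heads now that the remap is complete
        for tok, raw in zip(cur_tokens, raw_heads):
            if raw is None:
                tok.head = None
            elif raw == 0:
                tok.head = ROOT
            else:
                if raw not in id_remap:
                    raise ConlluParseError(
                        f"HEAD {raw} does not refer to a word token", line_no
                    )
                tok.head = id_remap[raw]
        sid = cur_sent_id if cur_sent_id is not None else f"s{len(sentences) + 1}"
        try:
            mentions = decode_bio_tags(cur_tags, cur_tokens)
        except BioTagError as exc:
            raise ConlluParseError(str(exc), line_no) from exc
        sentences.append(
            Sentence(sent_id=sid, tokens=cur_tokens, mentions=mentions,
                     doc_id=cur_doc_id or doc_id)
        )
        cur_tokens, cur_tags, cur_sent_id = [], [], None
        id_remap, raw_heads = {}, []

    for line_no, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush(line_no)
            continue
        if line.startswith("#"):
            comment = line[1:].strip()
            if comment.startswith("sent_id"):
                _, _, value = comment.partition("=")
                cur_sent_id = value.strip()
            elif comment.startswith("newdoc id"):
                _, _, value = comment.partition("=")
                cur_doc_id = value.strip()
            continue
        cols = line.split("\t")
        if len(cols) != _N_COLUMNS:
            raise ConlluParseError(
                f"expected {_N_COLUMNS} tab-separated columns, got {len(cols)}",
                line_no,
            )
        tok_id, form, _lemma, upos, _xpos, feats, head, deprel, _deps, _misc = cols
        if "-" in tok_id or "." in tok_id:
            continue  # multiword-token range or empty node
        try:
            conllu_id = int(tok_id)
        except ValueError as exc:
            raise ConlluParseError(f"bad token ID {tok_id!r}", line_no) from exc
        bio, rest = _split_feats(feats)
        if bio is not None:
            try:
                from .model import parse_bio_tag

                parse_bio_tag(bio)
            except BioTagError as exc:
                raise ConlluParseError(str(exc), line_no) from exc
        index = len(cur_tokens)
        id_remap[conllu_id] = index
        if head == "_":
            raw_head: Optional[int] = None
        else:
            try:
                raw_head = int(head)
            except ValueError as exc:
                raise ConlluParseError(f"bad HEAD {head!r}", line_no) from exc
        raw_heads.append(raw_head)
        cur_tokens.append(
            Token(
                index=index,
                text=form,
                upos=None if upos == "_" else upos,
                head=None,  # resolved at flush
                deprel=None if deprel == "_" else deprel,
                feats=rest or None,
            )
        )
        cur_tags.append(bio if bio is not None else "O")
    flush(len(text.splitlines()) + 1)
    return Document(doc_id=cur_doc_id or doc_id, sentences=sentences)


def format_conllu_biodiv(doc: Document) -> str:
    """Serialize a Document to CoNLL-U text with biodiv FEATS annotations."""
    blocks: list[str] = []
    for sentence in doc.sentences:
        lines = [f"# sent_id = {sentence.sent_id}"]
        tags = encode_bio_tags(sentence)
        for tok, tag in zip(sentence.tokens, tags):
            parts = []
            if tok.feats:
                parts.append(tok.feats)
            if tag != "O":
                parts.append(f"biodiv={tag}")
            feats = "|".join(parts) if parts else "_"
            if tok.head is None:
                head = "_"
            elif tok.head == ROOT:
                head = "0"
            else:
                head = str(tok.head + 1)
            lines.append(
                "\t".join(
                    [
                        str(tok.index + 1),
                        tok.text,
                        "_",
                        tok.upos or "_",
                        "_",
                        feats,
                        head,
                        tok.deprel or "_",
                        "_",
                        "_",
                    ]
                )
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def read_conllu_biodiv(source: PathOrIO, doc_id: Optional[str] = None) -> Document:
    """Read a biodiv-annotated CoNLL-U file (path or open text handle)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        return parse_conllu_biodiv(
            path.read_text(encoding="utf-8"), doc_id=doc_id or path.stem
        )
    return parse_conllu_biodiv(source.read(), doc_id=doc_id or "doc")


def write_conllu_biodiv(doc: Document, dest: PathOrIO) -> None:
    text = format_conllu_biodiv(doc)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


# ---------------------------------------------------------------------------
# JSONL relation instances
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("sent_id", "text", "tokens", "relation_type", "source", "target", "label")
_MENTION_KEYS = ("type", "start", "end", "text")


def _mention_to_obj(m: EntityMention) -> dict:
    return {"type": m.entity_type.value, "start": m.start, "end": m.end, "text": m.text}


def _mention_from_obj(obj: dict, line_no: int, role: str) -> EntityMention:
    for key in _MENTION_KEYS:
        if key not in obj:
            raise JsonlSchemaError(f"line {line_no}: {role} object missing key {key!r}")
    return EntityMention(
        entity_type=EntityType.from_label(obj["type"]),
        start=int(obj["start"]),
        end=int(obj["end"]),
        text=obj["text"],
    )


def instance_to_obj(inst: RelationInstance, sentence: Sentence) -> dict:
    return {
        "sent_id": inst.sent_id,
        "text": sentence.text,
        "tokens": [t.text for t in sentence.tokens],
        "relation_type": inst.relation_type.value,
        "source": _mention_to_obj(inst.source),
        "target": _mention_to_obj(inst.target),
        "label": inst.label,
        "predicted_by": inst.predicted_by,
    }


def write_instances_jsonl(
    instances: Iterable[RelationInstance],
    dest: PathOrIO,
    sentences: Optional[Mapping[str, Sentence]] = None,
) -> None:
    """Write relation instances as JSONL.

    ``sentences`` maps sent_id to Sentence for the text/tokens fields; when
    omitted, each instance must carry its in-memory ``sentence`` reference.
    """
    lines = []
    for inst in instances:
        sentence = inst.sentence
        if sentences is not None and inst.sent_id in sentences:
            sentence = sentences[inst.sent_id]
        if sentence is None:
            raise JsonlSchemaError(
                f"no sentence available for instance {inst.key}; pass `sentences`"
            )
        lines.append(json.dumps(instance_to_obj(inst, sentence), ensure_ascii=False))
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


def read_instances_jsonl(
    source: PathOrIO,
) -> tuple[list[RelationInstance], dict[str, Sentence]]:
    """Read JSONL relation instances.

    Returns the instances plus the sentences reconstructed from the
    ``text``/``tokens`` fields (tokens only; no dependency links), so that
    ``write_instances_jsonl(*read_instances_jsonl(f))`` is the identity.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    instances: list[RelationInstance] = []
    sentences: dict[str, Sentence] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise JsonlSchemaError(f"line {line_no}: invalid JSON: {exc}") from exc
        for key in _REQUIRED_KEYS:
            if key not in obj:
                raise JsonlSchemaError(f"line {line_no}: missing key {key!r}")
        source_m = _mention_from_obj(obj["source"], line_no, "source")
        target_m = _mention_from_obj(obj["target"], line_no, "target")
        label = obj["label"]
        if label not in (0, 1, None):
            raise JsonlSchemaError(f"line {line_no}: label must be 0, 1 or null")
        sent_id = obj["sent_id"]
        if sent_id not in sentences:
            tokens = [Token(index=i, text=t) for i, t in enumerate(obj["tokens"])]
            sentences[sent_id] = Sentence(
                sent_id=sent_id, tokens=tokens, mentions=[]
            )
        sentence = sentences[sent_id]
        # accumulate mentions (deduplicated) on the reconstructed sentence
        for m in (source_m, target_m):
            if m not in sentence.mentions:
                sentence.mentions.append(m)
        sentence.mentions.sort(key=lambda m: (m.start, m.end))
        inst = RelationInstance(
            sent_id=sent_id,
            relation_type=RelationType.from_name(obj["relation_type"]),
            source=source_m,
            target=target_m,
            label=label,
            predicted_by=obj.get("predicted_by"),
            sentence=sentence,
        )
        instances.append(inst)
    return instances, sentences
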