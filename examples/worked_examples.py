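"""Walk through the built-in worked examples: token-type encoding, the two
relation rules, compound detection, and the zero-shot templates.

Run:  python examples/worked_examples.py
"""

from biodiv_relex import (
    EntityType,
    RelationType,
    apply_regex_rules,
    detect_compound_entities,
    encode_token_types,
    generate_candidates,
    make_hypothesis,
    make_question,
    paper_fixture,
)
from biodiv_relex.rules import format_aligned_encoding

doc, gold = paper_fixture()

dongmakhai = doc.sentences[0]
print("=== has_location:", dongmakhai.text)
print(format_aligned_encoding(dongmakhai, RelationType.HAS_LOCATION))
cands = generate_candidates(dongmakhai, RelationType.HAS_LOCATION)
print(f"{len(cands)} candidate pairs (habitat x geographic location):")
tts = encode_token_types(dongmakhai, RelationType.HAS_LOCATION)
rule_pairs = apply_regex_rules(tts)
for c in cands:
    matched = (c.source, c.target) in rule_pairs
    print(f"  ({c.source.text!r} -> {c.target.text!r})  rule-matched={matched}")
# Both pairs fall inside one forward-rule match, so the regex step alone
# labels them related; note the comma inside the coordinate mention encodes
# as T, not as a delimiter.

flowered = doc.sentences[2]
print("\n=== has_time:", flowered.text)
print(format_aligned_encoding(flowered, RelationType.HAS_TIME))
pairs = apply_regex_rules(encode_token_types(flowered, RelationType.HAS_TIME))
print("rule-matched pairs:", sorted((a.text, b.text) for a, b in pairs))
# 'setting fruit only in 1968' encodes S o o T: two plain tokens between
# source and target defeat both rules, so that pair is left for the
# zero-shot step.

comp = detect_compound_entities(flowered, EntityType.TEMPORAL_EXPRESSION)[0]
print("compound temporal run:", comp.joined_text)
inst = next(
    c for c in generate_candidates(flowered, RelationType.HAS_TIME)
    if c.source.text == "flowered"
)
print("one hypothesis for the whole run:",
      make_hypothesis(inst, comp).query_text)

fruit_inst = next(
    c for c in generate_candidates(flowered, RelationType.HAS_TIME)
    if c.source.text == "fruit" and c.target.text == "1968"
)
print("\nboolean-QA question:", make_question(fruit_inst).query_text)
print("NLI hypothesis:     ", make_hypothesis(fruit_inst).query_text)
# The templates insert entity text verbatim -- no grammatical smoothing --
# and the backend answers Yes/No (QA) or entailment/neutral/contradiction
# (NLI); Yes or entailment means the relation holds.
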