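"""Evaluation metrics: precision, recall, F1, MCC, and annotator agreement.

Conventions follow the usual reporting practice for this task: any
zero-denominator precision/recall/F1 is 0.0, and MCC with any zero factor
under the square root is 0.0 — so the all-positive co-occurrence baseline
scores recall 1.0 and MCC 0.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import pandas as pd

from .model import RelationInstance


class AlignmentError(ValueError):
    """Prediction and gold sets do not cover the same instance keys."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    pred: Sequence[RelationInstance], gold: Sequence[RelationInstance]
) -> ConfusionCounts:
    """Binary confusion counts over instances matched by key."""
    gold_by_key = {inst.key: inst.label for inst in gold}
    pred_by_key = {inst.key: inst.label for inst in pred}
    missing = sorted(set(gold_by_key) - set(pred_by_key))
    extra = sorted(set(pred_by_key) - set(gold_by_key))
    if missing or extra:
        raise AlignmentError(
            f"prediction/gold key mismatch: {len(missing)} gold-only "
            f"(e.g. {missing[:3]}), {len(extra)} pred-only (e.g. {extra[:3]})"
        )
    tp = fp = fn = tn = 0
    for key, y in gold_by_key.items():
        if y not in (0, 1):
            raise AlignmentError(f"gold instance {key} is unlabelled")
        yhat = pred_by_key[key]
        if yhat not in (0, 1):
            raise AlignmentError(f"predicted instance {key} is unlabelled")
        if yhat == 1 and y == 1:
            tp += 1
        elif yhat == 1 and y == 0:
            fp += 1
        elif yhat == 0 and y == 1:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def prf1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 in [0, 1]; zero denominators give 0.0."""
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; any zero factor gives 0.0."""
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)


LabelVector = Union[Sequence[int], Mapping[object, int]]


def agreement_f1(labels_a: LabelVector, labels_b: LabelVector) -> float:
    """Inter-annotator agreement as the F1 of one label set against the other.

    Symmetric: swapping the annotators swaps precision and recall and leaves
    F1 unchanged. Label vectors may be sequences (aligned by position) or
    mappings aligned by key.
    """
    if isinstance(labels_a, Mapping) != isinstance(labels_b, Mapping):
        raise AlignmentError("annotator label containers must be of the same kind")
    if isinstance(labels_a, Mapping):
        if set(labels_a) != set(labels_b):
            raise AlignmentError("annotator label keys differ")
        keys = sorted(labels_a, key=repr)
        a = [labels_a[k] for k in keys]
        b = [labels_b[k] for k in keys]
    else:
        if len(labels_a) != len(labels_b):
            raise AlignmentError(
                f"annotator label lengths differ: {len(labels_a)} vs {len(labels_b)}"
            )
        a, b = list(labels_a), list(labels_b)
    tp = sum(1 for x, y in zip(a, b) if x == 1 and y == 1)
    fp = sum(1 for x, y in zip(a, b) if x == 0 and y == 1)
    fn = sum(1 for x, y in zip(a, b) if x == 1 and y == 0)
    tn = sum(1 for x, y in zip(a, b) if x == 0 and y == 0)
    _, _, f1 = prf1(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
    return f1


def evaluate(
    pred: Sequence[RelationInstance], gold: Sequence[RelationInstance]
) -> dict[str, float]:
    """P/R/F1/MCC plus raw counts for a prediction set against gold."""
    c = confusion(pred, gold)
    p, r, f1 = prf1(c)
    return {
        "precision": p,
        "recall": r,
        "f1": f1,
        "mcc": mcc(c),
        "tp": c.tp,
        "fp": c.fp,
        "fn": c.fn,
        "tn": c.tn,
        "n": c.total,
    }


def metrics_table(results: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Per-method report table with percentage columns, two decimals.

    ``results`` maps a method name to an :func:`evaluate` result dict.
    """
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "method": name,
                "P(%)": round(100 * res["precision"], 2),
                "R(%)": round(100 * res["recall"], 2),
                "F(%)": round(100 * res["f1"], 2),
                "MCC": round(res["mcc"], 2),
            }
        )
    return pd.DataFrame(rows).set_index("method")


def format_report(table: pd.DataFrame, fmt: str = "tsv") -> str:
    if fmt == "tsv":
        return table.to_csv(sep="\t", float_format="%.2f")
    if fmt == "markdown":
        cols = list(table.columns)
        header = "| method | " + " | ".join(cols) + " |"
        sep = "|" + "---|" * (len(cols) + 1)
        lines = [header, sep]
        for name, row in table.iterrows():
            cells = [f"{row[c]:.2f}" for c in cols]
            lines.append("| " + " | ".join([str(name)] + cells) + " |")
        return "\n".join(lines)
    raise ValueError(f"unknown report format {fmt!r} (use 'tsv' or 'markdown')")
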