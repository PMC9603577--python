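"""Confusion matrices, benchmark metrics, and the exhaustive
tool-combination sweep.

Metric definitions (predictions vs. a pathogenic/benign reference):

* accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)
* sensitivity = 100 * TP / (TP + FN)           (true-positive rate)
* specificity = 100 * TN / (TN + FP)           (true-negative rate)
* MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

The MCC is undefined whenever any of the four marginal sums is zero.  An
undefined MCC is a first-class value here, rendered as an em-dash ("―") in
reports and never coerced to 0 — coercion would silently corrupt counts of
"MCC above 0.5" on small reference sets, where zero marginals actually
occur (e.g. a predictor that calls everything pathogenic has TN+FN = 0).

With only 3 benign variants in a 36-variant reference, one misclassified
benign variant moves specificity by 33 points and can drive the MCC
negative even at 97% sensitivity, which is why the MCC rather than accuracy
orders the benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .consensus import combine
from .errors import ValidationError
from .tool_io import TOOLS, TOOL_LABELS, ReferenceVariant

#: Rendering of an undefined MCC in text reports.
UNDEFINED_MARK = "―"  # ―


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN of binary predictions against reference labels."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_pathogenic(self) -> int:
        """Reference pathogenic count (TP + FN)."""
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        """Reference benign count (TN + FP)."""
        return self.tn + self.fp

    def swapped(self) -> "ConfusionCounts":
        """The same table with the class roles exchanged."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class PerformanceMetrics:
    """Unrounded metrics; ``None`` marks an undefined value.

    ``accuracy_pct``/``sensitivity_pct``/``specificity_pct`` round half-up
    to one decimal and ``mcc_3dp`` to three decimals, matching how such
    benchmark tables are printed.
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    mcc: float | None

    @property
    def accuracy_pct(self) -> float:
        return round_half_up(self.accuracy, 1)

    @property
    def sensitivity_pct(self) -> float | None:
        return None if self.sensitivity is None else round_half_up(self.sensitivity, 1)

    @property
    def specificity_pct(self) -> float | None:
        return None if self.specificity is None else round_half_up(self.specificity, 1)

    @property
    def mcc_3dp(self) -> float | None:
        return None if self.mcc is None else round_half_up(self.mcc, 3)

    @property
    def mcc_text(self) -> str:
        return UNDEFINED_MARK if self.mcc is None else f"{self.mcc_3dp:.3f}"


def metrics(c: ConfusionCounts) -> PerformanceMetrics:
    """Accuracy, sensitivity, specificity and MCC from confusion counts."""
    if c.total == 0:
        raise ValidationError("empty confusion table")
    accuracy = 100.0 * (c.tp + c.tn) / c.total
    sensitivity = 100.0 * c.tp / c.n_pathogenic if c.n_pathogenic else None
    specificity = 100.0 * c.tn / c.n_benign if c.n_benign else None
    marginals = (c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn)
    if any(m == 0 for m in marginals):
        mcc = None
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(math.prod(marginals))
    return PerformanceMetrics(accuracy, sensitivity, specificity, mcc)


def confusion(
    predictions: Mapping[str, str], reference: Sequence[ReferenceVariant]
) -> ConfusionCounts:
    """Tally predictions (notation -> binary call) against reference labels."""
    missing = [v.substitution.notation for v in reference if v.substitution.notation not in predictions]
    if missing:
        raise ValidationError(f"no prediction for reference variants: {missing}")
    tp = tn = fp = fn = 0
    for v in reference:
        pred = predictions[v.substitution.notation]
        if pred not in ("pathogenic", "benign"):
            raise ValidationError(f"unknown call {pred!r} for {v.substitution.notation}")
        if v.label == "pathogenic":
            if pred == "pathogenic":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "benign":
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def derive_confusion(
    n_pathogenic: int, n_benign: int, sensitivity: float, specificity: float
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed class sizes and
    sensitivity/specificity percentages (nearest-integer inversion).

    The reconstruction is accepted only if re-deriving the percentages from
    the integer counts reproduces the inputs at one-decimal rounding; a
    failed round-trip means the printed marginals are mutually inconsistent.
    """
    if n_pathogenic <= 0 or n_benign < 0 or (n_pathogenic + n_benign) <= 0:
        raise ValidationError("class sizes must be positive")
    for name, p in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= p <= 100.0:
            raise ValidationError(f"{name} {p} outside [0, 100]")
    tp = int(round_half_up(n_pathogenic * sensitivity / 100.0, 0))
    tn = int(round_half_up(n_benign * specificity / 100.0, 0))
    c = ConfusionCounts(tp=tp, tn=tn, fp=n_benign - tn, fn=n_pathogenic - tp)
    m = metrics(c)
    got_sens = m.sensitivity_pct if m.sensitivity_pct is not None else None
    got_spec = m.specificity_pct if m.specificity_pct is not None else None
    if (got_sens is not None and abs(got_sens - round_half_up(sensitivity, 1)) > 0.05) or (
        got_spec is not None and abs(got_spec - round_half_up(specificity, 1)) > 0.05
    ):
        raise ValidationError(
            f"inconsistent marginals: sens/spec {sensitivity}/{specificity} "
            f"do not round-trip through counts {c}"
        )
    return c


def sweep_combinations(
    calls: pd.DataFrame,
    reference: Sequence[ReferenceVariant],
    tools: Sequence[str] = TOOLS,
) -> pd.DataFrame:
    """Benchmark every non-empty subset of ``tools`` against the reference.

    ``calls`` has columns ``notation, tool, call`` covering every reference
    variant for every tool.  Rows are ordered singles, pairs, triples, ...,
    each subset in the fixed tool order; for k tools there are 2^k - 1 rows.
    Single tools pass through unchanged; larger subsets are combined with
    the consensus rules.
    """
    tools = tuple(tools)
    per_tool: dict[str, dict[str, str]] = {}
    for t in tools:
        part = calls[calls["tool"] == t]
        per_tool[t] = dict(zip(part["notation"], part["call"]))
        missing = [
            v.substitution.notation
            for v in reference
            if v.substitution.notation not in per_tool[t]
        ]
        if missing:
            raise ValidationError(f"tool {t} lacks calls for {missing}")

    rows = []
    for k in range(1, len(tools) + 1):
        for subset in combinations(tools, k):
            preds: dict[str, str] = {}
            for v in reference:
                notation = v.substitution.notation
                subset_calls = [per_tool[t][notation] for t in subset]
                preds[notation] = (
                    subset_calls[0] if k == 1 else combine(subset_calls)
                )
            c = confusion(preds, reference)
            m = metrics(c)
            rows.append(
                {
                    "combination": " & ".join(TOOL_LABELS.get(t, t) for t in subset),
                    "tools": ",".join(subset),
                    "n_tools": k,
                    "tp": c.tp,
                    "tn": c.tn,
                    "fp": c.fp,
                    "fn": c.fn,
                    "accuracy": m.accuracy_pct,
                    "sensitivity": m.sensitivity_pct,
                    "specificity": m.specificity_pct,
                    "mcc": m.mcc_3dp,
                    "mcc_text": m.mcc_text,
                }
            )
    return pd.DataFrame(rows)


def count_mcc_above(table: pd.DataFrame, cutoff: float = 0.5) -> int:
    """Rows of a benchmark table with a *defined* MCC strictly above
    ``cutoff``; undefined MCCs are excluded, never treated as 0."""
    return int(sum(1 for v in table["mcc"] if v is not None and not pd.isna(v) and v > cutoff))
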