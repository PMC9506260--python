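"""Pixel-level confusion-matrix metrics and the stack/case detection
criteria.

Sensitivity is TP/(TP+FN) and specificity TN/(TN+FP) on pooled pixel
tallies.  A stack counts as detected when the per-slice lesion-pixel
recall reaches 40% in at least three slices; a case counts as detected
when at least one of its stacks does.  Undefined ratios (an empty class)
are surfaced as NaN plus an explicit flag, never silently as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "PixelMetrics",
    "StackCriteria",
    "StackOutcome",
    "confusion",
    "pixel_metrics",
    "slice_lesion_recall",
    "stack_detected",
    "case_detected",
    "aggregate_rates",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies; malignant is the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PixelMetrics:
    """Sensitivity/specificity and the row-normalized confusion matrix
    [[TN, FP], [FN, TP]] / row sums (row 0 = truth healthy)."""

    sensitivity: float
    specificity: float
    row_normalized: tuple[tuple[float, float], tuple[float, float]]
    undefined: frozenset = field(default_factory=frozenset)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel tallies of a predicted mask against the truth mask."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    for m, name in ((pred, "pred"), (truth, "truth")):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary {{0,1}}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def pixel_metrics(counts: ConfusionCounts) -> PixelMetrics:
    """Headline metrics from pooled tallies.

    An empty truth class makes the corresponding ratio undefined: the
    value is NaN and the metric name appears in ``undefined``.
    """
    undefined = set()
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos > 0:
        sens = counts.tp / pos
        row1 = (counts.fn / pos, counts.tp / pos)
    else:
        sens, row1 = float("nan"), (float("nan"), float("nan"))
        undefined.add("sensitivity")
    if neg > 0:
        spec = counts.tn / neg
        row0 = (counts.tn / neg, counts.fp / neg)
    else:
        spec, row0 = float("nan"), (float("nan"), float("nan"))
        undefined.add("specificity")
    return PixelMetrics(sensitivity=sens, specificity=spec,
                        row_normalized=(row0, row1),
                        undefined=frozenset(undefined))


@dataclass(frozen=True)
class StackCriteria:
    """A stack is detected when >= ``min_positive_slices`` slices reach a
    lesion-pixel recall of ``lesion_recall_threshold`` (inclusive)."""

    lesion_recall_threshold: float = 0.40
    min_positive_slices: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.lesion_recall_threshold <= 1:
            raise ValueError("lesion_recall_threshold must be in (0, 1]")
        if self.min_positive_slices < 1:
            raise ValueError("min_positive_slices must be >= 1")


def slice_lesion_recall(pred: np.ndarray, truth: np.ndarray) -> float:
    """Recall of truth lesion pixels on one slice: TP/(TP+FN).

    Undefined (raises) on a lesion-free truth mask; such slices are
    excluded from the stack criterion by the caller.
    """
    c = confusion(pred, truth)
    if c.tp + c.fn == 0:
        raise ValueError("slice has no lesion pixels; recall undefined")
    return c.tp / (c.tp + c.fn)


@dataclass(frozen=True)
class StackOutcome:
    """Detection outcome of one stack; ``evaluable`` is False when no
    slice carries lesion truth."""

    detected: bool
    evaluable: bool
    n_detected_slices: int
    n_lesion_slices: int

    def __bool__(self) -> bool:
        return self.detected


def stack_detected(stack_preds: list[np.ndarray], stack_truths: list[np.ndarray],
                   criteria: StackCriteria = StackCriteria()) -> StackOutcome:
    """Apply the stack criterion over aligned per-slice mask lists."""
    if len(stack_preds) != len(stack_truths):
        raise ValueError("pred and truth slice lists differ in length")
    n_lesion = 0
    n_hit = 0
    for pred, truth in zip(stack_preds, stack_truths):
        if np.count_nonzero(truth) == 0:
            continue
        n_lesion += 1
        if slice_lesion_recall(pred, truth) >= criteria.lesion_recall_threshold:
            n_hit += 1
    evaluable = n_lesion > 0
    return StackOutcome(
        detected=evaluable and n_hit >= criteria.min_positive_slices,
        evaluable=evaluable,
        n_detected_slices=n_hit,
        n_lesion_slices=n_lesion,
    )


def case_detected(case_stacks: list[StackOutcome]) -> bool:
    """A case is detected when any of its evaluable stacks is detected."""
    return any(o.detected for o in case_stacks if o.evaluable)


def aggregate_rates(results: dict[str, list[StackOutcome]]
                    ) -> tuple[float, float]:
    """(stack_rate, case_rate) over evaluable units.

    ``results`` maps case id -> outcomes of that case's stacks.
    """
    stacks = [o for outcomes in results.values() for o in outcomes if o.evaluable]
    if not stacks:
        raise ValueError("no evaluable stacks")
    stack_rate = sum(o.detected for o in stacks) / len(stacks)
    cases = {cid: outs for cid, outs in results.items()
             if any(o.evaluable for o in outs)}
    case_rate = sum(case_detected(outs) for outs in cases.values()) / len(cases)
    return stack_rate, case_rate
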