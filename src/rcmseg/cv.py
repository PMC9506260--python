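"""Grouped k-fold cross-validation over cases.

Folds partition whole cases (patients), so no slice from a validation
case ever enters training — the only leakage-safe reading of patient-wise
data.  Per fold: tile training slices into patches, train the classifier,
expand it, predict and postprocess every validation slice, and tally
pixel confusion plus stack/case detection.  Pooled metrics come from
summed confusion counts (one pooled matrix, not a mean of fold metrics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .classifier import BackboneSpec, TrainConfig, build_model, train
from .dense import ExpansionConfig, expand, mirror_pad, predict_heatmap
from .metrics import (ConfusionCounts, PixelMetrics, StackCriteria, StackOutcome,
                      aggregate_rates, confusion, pixel_metrics, stack_detected)
from .patches import AugmentConfig, PatchRule, tile_slice
from .postprocess import PostprocessConfig, run_postprocess
from .synthetic import Stack

logger = logging.getLogger("rcmseg")

__all__ = ["CVConfig", "FoldResult", "CVResult", "make_folds", "run_cv"]


@dataclass(frozen=True)
class CVConfig:
    k: int = 14
    grouping_unit: str = "case"
    seed: int = 0
    pooling: str = "sum_counts"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.grouping_unit != "case":
            raise ValueError("only case-wise grouping is supported")
        if self.pooling != "sum_counts":
            raise ValueError("only sum_counts pooling is supported")


@dataclass
class FoldResult:
    fold_index: int
    train_group_ids: tuple[str, ...]
    val_group_ids: tuple[str, ...]
    confusion: ConfusionCounts
    stack_outcomes: dict[str, list[StackOutcome]]  # case id -> outcomes
    training_log: list[dict]


@dataclass
class CVResult:
    folds: list[FoldResult]
    pooled_counts: ConfusionCounts
    pooled_metrics: PixelMetrics
    stack_rate: float
    case_rate: float


def make_folds(group_ids, cfg: CVConfig) -> list[tuple[str, ...]]:
    """Partition groups into k validation folds of near-equal size.

    Deterministic given the seed and independent of input ordering; each
    group appears in exactly one fold; fold sizes differ by at most one.
    """
    groups = sorted(set(group_ids))
    if len(groups) < cfg.k:
        raise ValueError(f"{len(groups)} groups but k={cfg.k}")
    rng = np.random.default_rng(cfg.seed)
    order = [groups[i] for i in rng.permutation(len(groups))]
    return [tuple(sorted(part)) for part in np.array_split(np.array(order), cfg.k)]


def _fold_seed(master: int, fold: int) -> int:
    seq = np.random.SeedSequence(master, spawn_key=(fold,))
    return int(seq.generate_state(1)[0] % (2**31))


class FoldError(RuntimeError):
    def __init__(self, fold_index: int, val_groups, cause: Exception) -> None:
        super().__init__(
            f"fold {fold_index} (validation groups {list(val_groups)}) failed: {cause}")
        self.fold_index = fold_index


def run_cv(stacks: list[Stack],
           backbone: BackboneSpec,
           patch_rule: PatchRule,
           train_cfg: TrainConfig,
           expansion_cfg: ExpansionConfig,
           post_cfg: PostprocessConfig,
           cv_cfg: CVConfig,
           criteria: StackCriteria = StackCriteria(),
           aug: AugmentConfig | None = None,
           dtype=np.float32) -> CVResult:
    """Full grouped-CV pipeline: train -> expand -> predict -> postprocess
    -> evaluate, per fold, with summed-count pooling.

    Evaluation runs on the mirror-padded canvas (with identically padded
    truth masks) when the expansion config says so, else on the cropped
    original frame.
    """
    by_case: dict[str, list[Stack]] = {}
    for st in stacks:
        by_case.setdefault(st.case_id, []).append(st)
    folds = make_folds(by_case.keys(), cv_cfg)

    results: list[FoldResult] = []
    all_outcomes: dict[str, list[StackOutcome]] = {}
    pooled = ConfusionCounts()
    for fi, val_groups in enumerate(folds):
        try:
            train_groups = tuple(sorted(set(by_case) - set(val_groups)))
            assert not set(train_groups) & set(val_groups), "fold leakage"
            seed = _fold_seed(cv_cfg.seed, fi)
            train_patches = [
                p
                for cid in train_groups
                for st in by_case[cid]
                for sl in st.slices
                for p in tile_slice(sl, patch_rule)
            ]
            logger.info("fold %d: %d training patches from %d cases",
                        fi, len(train_patches), len(train_groups))
            model = build_model(backbone, seed=seed,
                                patch_size=patch_rule.patch_size, dtype=dtype)
            model, log = train(model, train_patches,
                               replace(train_cfg, seed=seed), aug=aug)
            dense = expand(model, expansion_cfg)

            fold_counts = ConfusionCounts()
            fold_outcomes: dict[str, list[StackOutcome]] = {}
            for cid in val_groups:
                for st in by_case[cid]:
                    preds, truths = [], []
                    for sl in st.slices:
                        hm = predict_heatmap(dense, sl.image)
                        if expansion_cfg.evaluate_on_padded_canvas:
                            pred = run_postprocess(hm.probabilities, post_cfg)
                            truth = mirror_pad(sl.mask, expansion_cfg)
                        else:
                            pred = run_postprocess(hm.crop(), post_cfg)
                            truth = sl.mask
                        fold_counts = fold_counts + confusion(pred, truth)
                        preds.append(pred)
                        truths.append(truth)
                    outcome = stack_detected(preds, truths, criteria)
                    fold_outcomes.setdefault(cid, []).append(outcome)
            results.append(FoldResult(
                fold_index=fi, train_group_ids=train_groups,
                val_group_ids=tuple(val_groups), confusion=fold_counts,
                stack_outcomes=fold_outcomes, training_log=log))
            for cid, outs in fold_outcomes.items():
                all_outcomes.setdefault(cid, []).extend(outs)
            pooled = pooled + fold_counts
            logger.info("fold %d done: %s", fi, fold_counts)
        except Exception as exc:  # noqa: BLE001 - abort with fold identity
            raise FoldError(fi, val_groups, exc) from exc

    stack_rate, case_rate = aggregate_rates(all_outcomes)
    return CVResult(folds=results, pooled_counts=pooled,
                    pooled_metrics=pixel_metrics(pooled),
                    stack_rate=stack_rate, case_rate=case_rate)
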