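"""Segmentation and classification quality metrics.

Dice overlap, skeleton-length and volume ratios of predicted vs ground-truth
masks, support-weighted F1 over the three channel-occupancy classes, paired
Wilcoxon signed-rank comparison of per-sample Dice between models, and
pairwise inter-scorer Dice tables for human-annotation variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, f1_score

from .phenotype import BinaryMask, ChannelGeometry, body_volume, \
    skeleton_length

__all__ = [
    "EvalReport", "dice", "length_ratio", "volume_ratio", "weighted_f1",
    "compare_models", "inter_scorer_dice", "evaluate_masks",
]


@dataclass
class EvalReport:
    """Aggregate evaluation over a test set of M samples."""

    per_sample_dice: np.ndarray
    mean_dice: float
    sem_dice: float
    length_ratio_mean: float
    length_ratio_sem: float
    volume_ratio_mean: float
    volume_ratio_sem: float
    weighted_f1: float
    confusion: np.ndarray
    n_samples: int


def _as_grid(mask) -> np.ndarray:
    return mask.grid if hasattr(mask, "grid") else np.asarray(mask, bool)


def dice(pred, truth) -> float:
    """Dice overlap 2|P∩T| / (|P|+|T|); two empty masks score 1."""
    p, t = _as_grid(pred), _as_grid(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def length_ratio(pred: BinaryMask, truth: BinaryMask) -> float:
    """Predicted over ground-truth skeleton length."""
    if not _as_grid(truth).any():
        raise ValueError("ground-truth mask is empty")
    return skeleton_length(pred) / skeleton_length(truth)


def volume_ratio(pred: BinaryMask, truth: BinaryMask,
                 geometry: ChannelGeometry,
                 channel_origin_um: float = 0.0) -> float:
    """Predicted over ground-truth channel-height-weighted volume."""
    if not _as_grid(truth).any():
        raise ValueError("ground-truth mask is empty")
    return (
        body_volume(pred, geometry, channel_origin_um)
        / body_volume(truth, geometry, channel_origin_um)
    )


def weighted_f1(pred_labels, true_labels) -> float:
    """Per-class F1 averaged with weights equal to the true-class support."""
    if len(pred_labels) != len(true_labels):
        raise ValueError("label sequences must have equal length")
    return float(f1_score(true_labels, pred_labels, average="weighted",
                          zero_division=0))


def compare_models(dice_a, dice_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-sample Dice scores.

    Zero differences are dropped (standard signed-rank convention); if every
    pair is tied the statistic is 0 and p = 1 by convention.
    """
    a = np.asarray(dice_a, dtype=float)
    b = np.asarray(dice_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if np.all(a == b):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def inter_scorer_dice(mask_sets: dict[str, dict]) -> pd.DataFrame:
    """Pairwise Dice between scorers over shared samples.

    ``mask_sets`` maps scorer -> {sample_id -> mask}.  Every unordered
    scorer pair contributes one row per shared sample (5 scorers x 20
    samples = 10 pairs x 20 = 200 values); samples missing for either
    scorer are excluded from that pair.
    """
    if len(mask_sets) < 2:
        raise ValueError("need at least two scorers")
    rows = []
    for s1, s2 in combinations(sorted(mask_sets), 2):
        shared = sorted(set(mask_sets[s1]) & set(mask_sets[s2]))
        for sid in shared:
            rows.append(
                dict(scorer_a=s1, scorer_b=s2, sample=sid,
                     dice=dice(mask_sets[s1][sid], mask_sets[s2][sid]))
            )
    return pd.DataFrame(rows)


def evaluate_masks(pred_masks, truth_masks, pred_labels, true_labels,
                   geometry: ChannelGeometry | None = None,
                   labels=("full", "partial", "empty")) -> EvalReport:
    """Build the aggregate report: Dice/length/volume ratios + weighted F1.

    Ratio metrics are computed over sample pairs where the ground truth is a
    full worm (non-empty mask); Dice is computed over all mask pairs.
    """
    dices = np.array([dice(p, t) for p, t in zip(pred_masks, truth_masks)])
    lr, vr = [], []
    for p, t in zip(pred_masks, truth_masks):
        if _as_grid(t).any() and _as_grid(p).any():
            lr.append(length_ratio(p, t))
            if geometry is not None:
                vr.append(volume_ratio(p, t, geometry))
    lr = np.asarray(lr)
    vr = np.asarray(vr)

    def sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return EvalReport(
        per_sample_dice=dices,
        mean_dice=float(dices.mean()) if dices.size else float("nan"),
        sem_dice=sem(dices),
        length_ratio_mean=float(lr.mean()) if lr.size else float("nan"),
        length_ratio_sem=sem(lr),
        volume_ratio_mean=float(vr.mean()) if vr.size else float("nan"),
        volume_ratio_sem=sem(vr),
        weighted_f1=weighted_f1(pred_labels, true_labels),
        confusion=confusion_matrix(true_labels, pred_labels, labels=list(labels)),
        n_samples=len(dices),
    )
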