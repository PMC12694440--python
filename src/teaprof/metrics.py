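"""Detection and harvest-quality metrics.

Two metric families:

* pixel-level detection scores of a predicted shoot mask against a truth
  mask — precision P = TP/(TP+FP), recall R = TP/(TP+FN), and their
  harmonic mean F1;
* field harvest-quality rates from trial masses: bud-and-leaf integrity
  R1 = 100 W1/W, loss R2 = 100 W3/(W2+W3), leakage R3 = 100 W4/(W2+W3+W4),
  qualified-length R4 = 100 W5/W, and hourly productivity per unit cutting
  width E = sum(A) / (sum(T) * B) in m^2/(m*h).

Trial aggregation reports the mean and the population (divide-by-n)
standard deviation, the convention used for the reference field results.
Reported values round half-away-from-zero at the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import numpy as np

from .errors import ParameterError, TeaprofError
from .segmentation import ShootMask


class UndefinedMetricError(TeaprofError):
    """A metric's denominator is zero for the given inputs."""


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")


@dataclass(frozen=True)
class DetectionScore:
    precision: float
    recall: float
    f1: float

    def as_percent(self, ndigits_pr: int = 1, ndigits_f1: int = 0) -> dict:
        """Percent-scale report rounded to the printed precisions."""
        return {
            "precision": round_half_away(100.0 * self.precision, ndigits_pr),
            "recall": round_half_away(100.0 * self.recall, ndigits_pr),
            "f1": round_half_away(100.0 * self.f1, ndigits_f1),
        }


def _as_bool_mask(mask: ShootMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, ShootMask):
        mask = mask.pixels
    return np.asarray(mask).astype(bool)


def score_mask(predicted: ShootMask | np.ndarray, truth: ShootMask | np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts of a predicted mask against truth."""
    pred = _as_bool_mask(predicted)
    true = _as_bool_mask(truth)
    if pred.shape != true.shape:
        raise ParameterError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        tp=int((pred & true).sum()),
        fp=int((pred & ~true).sum()),
        fn=int((~pred & true).sum()),
    )


def detection_score(counts: ConfusionCounts) -> DetectionScore:
    """Precision, recall and F1 from confusion counts."""
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: no predicted positives")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: no true positives in truth")
    p = counts.tp / (counts.tp + counts.fp)
    r = counts.tp / (counts.tp + counts.fn)
    if p + r == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall is zero")
    return DetectionScore(precision=p, recall=r, f1=2.0 * p * r / (p + r))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (fractions or percents alike)."""
    if precision + recall == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall is zero")
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class FieldTrial:
    """Masses (g) and operating figures of one harvest trial.

    ``w_total``/``w1_intact``/``w5_qualified`` refer to the 300 g quartered
    sample; ``w2_sample``/``w3_dropped``/``w4_uncut`` are the area-collection
    masses feeding the loss and leakage rates.
    """

    w_total: float
    w1_intact: float
    w2_sample: float
    w3_dropped: float
    w4_uncut: float
    w5_qualified: float
    area_m2: float = 0.0
    time_h: float = 0.0
    cut_width_m: float = 0.0

    def __post_init__(self) -> None:
        masses = (
            self.w_total, self.w1_intact, self.w2_sample,
            self.w3_dropped, self.w4_uncut, self.w5_qualified,
        )
        if min(masses) < 0:
            raise ParameterError("masses must be non-negative")
        if self.w1_intact > self.w_total or self.w5_qualified > self.w_total:
            raise ParameterError("W1 and W5 cannot exceed the total sample mass")


def field_metrics(trial: FieldTrial) -> dict:
    """Harvest-quality rates (percent) and productivity for one trial.

    Returns keys ``integrity_rate``, ``loss_rate``, ``leakage_rate``,
    ``qualified_rate`` (percent) and, when area/time/width are given,
    ``productivity`` in m^2/(m*h).
    """
    def ratio(num: float, den: float, name: str) -> float:
        if den <= 0:
            raise UndefinedMetricError(f"{name} undefined: zero denominator")
        return 100.0 * num / den

    out = {
        "integrity_rate": ratio(trial.w1_intact, trial.w_total, "integrity rate"),
        "loss_rate": ratio(trial.w3_dropped, trial.w2_sample + trial.w3_dropped, "loss rate"),
        "leakage_rate": ratio(
            trial.w4_uncut,
            trial.w2_sample + trial.w3_dropped + trial.w4_uncut,
            "leakage rate",
        ),
        "qualified_rate": ratio(trial.w5_qualified, trial.w_total, "qualified rate"),
    }
    if trial.area_m2 > 0 or trial.time_h > 0 or trial.cut_width_m > 0:
        if trial.time_h <= 0 or trial.cut_width_m <= 0:
            raise UndefinedMetricError("productivity undefined: zero time or cut width")
        out["productivity"] = trial.area_m2 / (trial.time_h * trial.cut_width_m)
    return out


def productivity(trials: Iterable[FieldTrial]) -> float:
    """Multi-trial hourly productivity per unit width: sum(A) / (sum(T) * B)."""
    trials = list(trials)
    if not trials:
        raise ParameterError("need at least one trial")
    widths = {t.cut_width_m for t in trials}
    if len(widths) != 1 or next(iter(widths)) <= 0:
        raise ParameterError("trials must share one positive cutting width")
    total_t = sum(t.time_h for t in trials)
    if total_t <= 0:
        raise UndefinedMetricError("productivity undefined: zero total time")
    return sum(t.area_m2 for t in trials) / (total_t * next(iter(widths)))


@dataclass(frozen=True)
class TrialSummary:
    mean: float
    sd: float  # population (divide-by-n) standard deviation
    n: int


def summarize_trials(values: Sequence[float]) -> TrialSummary:
    """Mean and population standard deviation across trials (n >= 2)."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size < 2:
        raise ParameterError("need a flat sequence of at least two trial values")
    return TrialSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        n=int(values.size),
    )
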