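"""Leave-one-whale-out cross-validation and error metrics.

One fold holds out one whale; the model is refit on the remaining whales
of the same age class (using every available label) and the held-out
whale is decoded with rule-derived constraints only — never its video
labels.  Decoded track behaviours are compared against video labels,
accumulated one-vs-rest into a confusion matrix per behaviour per age
class.  Only video-labelled tracks are counted.

The false-positive rate here is FP/(FP+TP), as used throughout the
analysis this package implements; the textbook fall-out FP/(FP+TN) is
available separately as :func:`fall_out`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hhmm import BEHAVIOURS, HHMMParams, WhaleObs, fit_em, viterbi_decode

__all__ = [
    "ConfusionMatrix",
    "ErrorMetrics",
    "error_metrics",
    "fall_out",
    "loo_crossval",
]


@dataclass
class ConfusionMatrix:
    TP: int
    FN: int
    FP: int
    TN: int
    behaviour: Optional[str] = None
    age_class: Optional[str] = None

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


@dataclass
class ErrorMetrics:
    """Percentages in [0, 100]; ``None`` marks an undefined (0/0) value."""

    detection: Optional[float]
    fp_rate: Optional[float]
    precision: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]

    def rounded(self) -> dict[str, Optional[int]]:
        return {
            k: (None if v is None else round(v))
            for k, v in self.__dict__.items()
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def error_metrics(cm: ConfusionMatrix) -> ErrorMetrics:
    """Detection, FP rate (FP/(FP+TP)), precision, specificity, accuracy."""
    return ErrorMetrics(
        detection=_ratio(cm.TP, cm.TP + cm.FN),
        fp_rate=_ratio(cm.FP, cm.FP + cm.TP),
        precision=_ratio(cm.TP, cm.TP + cm.FP),
        specificity=_ratio(cm.TN, cm.TN + cm.FP),
        accuracy=_ratio(cm.TP + cm.TN, cm.total),
    )


def fall_out(cm: ConfusionMatrix) -> Optional[float]:
    """Textbook false-positive rate FP/(FP+TN), percent."""
    return _ratio(cm.FP, cm.FP + cm.TN)


def loo_crossval(
    whales: Sequence[WhaleObs],
    initial: HHMMParams,
    age_classes: Sequence[str] = ("juvenile", "adult_male"),
    behaviours: Sequence[str] = BEHAVIOURS,
    **fit_kwargs,
) -> dict[tuple[str, str], ConfusionMatrix]:
    """One-vs-rest confusion matrices from leave-one-whale-out folds.

    Raises ``ValueError`` when an age class has fewer than two whales.
    Fold order does not affect the result: counts only accumulate.  A small
    transition-count smoothing is applied by default so that a fold's
    estimates never assign exact zero probability to a state the held-out
    whale visits.
    """
    fit_kwargs.setdefault("smoothing", 0.5)
    out: dict[tuple[str, str], ConfusionMatrix] = {}
    for age_class in age_classes:
        group = [w for w in whales if w.age_class == age_class]
        if not group:
            continue
        if len(group) < 2:
            raise ValueError(f"age class {age_class!r} has a single whale; "
                             "cannot cross-validate")
        counts = {b: np.zeros(4, dtype=int) for b in behaviours}  # TP FN FP TN
        for held in sorted(group, key=lambda w: w.whale_id):
            rest = [w for w in group if w.whale_id != held.whale_id]
            params, _ = fit_em(initial, rest, **fit_kwargs)
            decoded = viterbi_decode(params, held, use_video=False)
            for t, track in enumerate(held.tracks):
                truth = track.video_behaviour
                if truth < 0:
                    continue
                pred = int(decoded.behaviours[t])
                for bi, b in enumerate(behaviours):
                    is_truth = truth == bi
                    is_pred = pred == bi
                    if is_truth and is_pred:
                        counts[b][0] += 1
                    elif is_truth:
                        counts[b][1] += 1
                    elif is_pred:
                        counts[b][2] += 1
                    else:
                        counts[b][3] += 1
        for b in behaviours:
            tp, fn, fp, tn = (int(x) for x in counts[b])
            out[(b, age_class)] = ConfusionMatrix(tp, fn, fp, tn,
                                                  behaviour=b, age_class=age_class)
    return out
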