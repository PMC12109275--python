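"""Confusion-matrix metrics for binary glaucoma screening.

Positive = predicted glaucoma (label 1).  Alongside the usual accuracy,
sensitivity (recall), specificity and precision, the report carries the
F-beta score and the three Pythagorean means of precision and recall:
arithmetic (A), geometric (G) and harmonic (H).  H equals F1 and
H <= G <= A always, with equality iff precision = recall; H is the most
conservative of the three, which is why it is the headline score.

Metrics with a zero denominator are reported as ``None`` (undefined)
rather than coerced to 0, and excluded from aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricReport:
    """Derived metrics; ``None`` marks an undefined (0/0) quantity."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f_beta: float | None
    beta: float
    a_mean: float | None
    g_mean: float | None
    h_mean: float | None
    counts: ConfusionCounts = field(compare=False)

    @property
    def f1(self) -> float | None:
        """F1 equals the harmonic mean of precision and recall."""
        return self.h_mean

    def as_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN with positive = predicted glaucoma (1)."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (np.all(np.isin(yt, (0, 1))) and np.all(np.isin(yp, (0, 1)))):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts, beta: float = 1.0) -> MetricReport:
    """Derive the metric report from confusion counts.

    accuracy = (TP+TN)/n, sensitivity = TP/(TP+FN),
    specificity = TN/(FP+TN), precision = TP/(TP+FP),
    F_beta = (1+beta^2) P R / (beta^2 P + R),
    A = (P+R)/2, G = sqrt(P R), H = 2 P R / (P+R).
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    acc = _ratio(c.TP + c.TN, c.total)
    sen = _ratio(c.TP, c.TP + c.FN)
    spe = _ratio(c.TN, c.FP + c.TN)
    pre = _ratio(c.TP, c.TP + c.FP)
    if pre is None or sen is None:
        fb = a = g = h = None
    else:
        fb_den = beta**2 * pre + sen
        fb = (1 + beta**2) * pre * sen / fb_den if fb_den > 0 else None
        a = (pre + sen) / 2.0
        g = math.sqrt(pre * sen)
        h = 2.0 * pre * sen / (pre + sen) if (pre + sen) > 0 else None
    return MetricReport(
        accuracy=acc,
        sensitivity=sen,
        specificity=spe,
        precision=pre,
        f_beta=fb,
        beta=beta,
        a_mean=a,
        g_mean=g,
        h_mean=h,
        counts=c,
    )


def evaluate(y_true, y_pred, beta: float = 1.0) -> MetricReport:
    """Convenience wrapper: confusion counts then the metric report."""
    return compute_metrics(confusion(y_true, y_pred), beta=beta)


_AGG_FIELDS = ("accuracy", "sensitivity", "specificity", "precision", "h_mean")


def aggregate_reports(reports: list[MetricReport]) -> dict:
    """Mean, sample SD and standard error of the mean across block-models.

    Undefined (``None``) values are excluded per metric; the count of
    contributing blocks is reported alongside.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict = {}
    for name in _AGG_FIELDS:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if not vals:
            out[name] = {"mean": None, "sd": None, "se": None, "n": 0}
            continue
        arr = np.asarray(vals, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        out[name] = {
            "mean": float(np.mean(arr)),
            "sd": sd,
            "se": sd / math.sqrt(arr.size) if arr.size > 1 else 0.0,
            "n": int(arr.size),
        }
    return out
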