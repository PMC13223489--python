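"""Confusion-matrix evaluation of the binary glaucoma/normal classifiers.

From confusion counts (TP, TN, FP, FN at a 0.5 threshold, ties classified
positive) the suite reports

    ACC  = (TP + TN) / (TP + TN + FP + FN)
    PREC = TP / (TP + FP)
    SEN  = TP / (TP + FN)
    F1   = 2 * PREC * SEN / (PREC + SEN)

per class (each class taken as positive in turn), macro averages (the
unweighted mean over the two classes), and AUC as the rank statistic: the
probability that a random positive is scored above a random negative, ties
counting one half.  Metrics with a zero denominator are reported as NaN and
flagged by name, never silently coerced to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "bce_loss",
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "confusion",
    "metrics",
    "f1_from",
    "auc",
    "report",
    "evaluate_scores",
    "format_report_table",
]


def bce_loss(y, y_hat, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy, -[y ln p + (1-y) ln(1-p)].

    Predictions are clipped to [eps, 1-eps] so saturated outputs stay
    finite.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(y_hat, dtype=np.float64), eps, 1.0 - eps)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log1p(-p))))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for f in ("TP", "TN", "FP", "FN"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class Metrics:
    """ACC/PREC/SEN/F1 with NaN + flag for undefined denominators."""

    acc: float
    prec: float
    sen: float
    f1: float
    undefined: tuple = ()


def _as_binary(labels, positive_class) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        known = {"glaucoma", "normal"}
        bad = set(np.unique(labels)) - known
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}; expected {sorted(known)}")
        if positive_class not in known:
            raise ValueError(f"unknown positive_class {positive_class!r}")
        return (labels == positive_class).astype(int)
    if positive_class == "glaucoma":
        positive_class = 1
    elif positive_class == "normal":
        positive_class = 0
    if positive_class not in (0, 1):
        raise ValueError(f"positive_class must be 0/1 or a class name, got {positive_class!r}")
    bad = set(np.unique(labels)) - {0, 1}
    if bad:
        raise ValueError(f"numeric labels must be 0/1, found {sorted(bad)}")
    return (labels == positive_class).astype(int)


def confusion(labels, probabilities, threshold: float = 0.5, positive_class="glaucoma") -> ConfusionCounts:
    """Confusion counts at a probability threshold (ties -> positive).

    ``probabilities`` score the glaucoma class; when ``positive_class`` is
    normal (or 0), scores are reflected so the counts describe that
    orientation.
    """
    p = np.asarray(probabilities, dtype=float)
    y = _as_binary(labels, positive_class)
    if len(p) != len(y):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(p)} probabilities")
    score = p if positive_class in ("glaucoma", 1) else 1.0 - p
    pred = (score >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )


def f1_from(prec: float, sen: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if prec + sen == 0:
        return math.nan
    return 2 * prec * sen / (prec + sen)


def metrics(counts: ConfusionCounts) -> Metrics:
    """ACC, PREC, SEN and F1 from confusion counts."""
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    acc = ratio(counts.TP + counts.TN, counts.n, "acc")
    prec = ratio(counts.TP, counts.TP + counts.FP, "prec")
    sen = ratio(counts.TP, counts.TP + counts.FN, "sen")
    if math.isnan(prec) or math.isnan(sen) or prec + sen == 0:
        undefined.append("f1")
        f1 = math.nan
    else:
        f1 = f1_from(prec, sen)
    return Metrics(acc=acc, prec=prec, sen=sen, f1=f1, undefined=tuple(undefined))


def auc(labels, scores, positive_class="glaucoma") -> float:
    """Rank-statistic AUC; NaN when only one class is present."""
    y = _as_binary(labels, positive_class)
    s = np.asarray(scores, dtype=float)
    if positive_class not in ("glaucoma", 1):
        s = 1.0 - s
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(s)  # midranks implement the half-credit tie convention
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Per-class and macro metrics for one model's scores."""

    per_class: dict  # label -> Metrics
    macro: Metrics
    acc: float
    auc: float
    counts: dict = field(default_factory=dict)  # label -> ConfusionCounts
    undefined: tuple = ()

    def to_dict(self) -> dict:
        return {
            "per_class": {k: asdict(v) for k, v in self.per_class.items()},
            "macro": asdict(self.macro),
            "acc": self.acc,
            "auc": self.auc,
            "counts": {k: asdict(v) for k, v in self.counts.items()},
            "undefined": list(self.undefined),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _macro(values):
    vals = list(values)
    if any(math.isnan(v) for v in vals):
        return math.nan
    return sum(vals) / len(vals)


def evaluate_scores(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Full report for one probability vector (glaucoma-oriented scores)."""
    per_class, counts = {}, {}
    for cls in ("normal", "glaucoma"):
        c = confusion(labels, scores, threshold=threshold, positive_class=cls)
        counts[cls] = c
        per_class[cls] = metrics(c)
    macro = Metrics(
        acc=_macro(m.acc for m in per_class.values()),
        prec=_macro(m.prec for m in per_class.values()),
        sen=_macro(m.sen for m in per_class.values()),
        f1=_macro(m.f1 for m in per_class.values()),
    )
    a = auc(labels, scores)
    undefined = tuple(
        sorted(
            {f"{cls}:{name}" for cls, m in per_class.items() for name in m.undefined}
            | ({"auc"} if math.isnan(a) else set())
        )
    )
    return EvalReport(
        per_class=per_class,
        macro=macro,
        acc=per_class["glaucoma"].acc,  # ACC is orientation-independent
        auc=a,
        counts=counts,
        undefined=undefined,
    )


def report(labels, model_scores: dict, threshold: float = 0.5) -> dict:
    """Reports for several models' scores over the same labels."""
    return {name: evaluate_scores(labels, s, threshold) for name, s in model_scores.items()}


def _pct(x):
    return "  -  " if math.isnan(x) else f"{100 * x:5.2f}"


def format_report_table(reports: dict) -> str:
    """Text table in the per-class/Average layout of the evaluation suite."""
    lines = [f"{'Model':28s} {'Label':9s} {'PREC':>6s} {'SEN':>6s} {'F1':>6s} {'ACC':>6s} {'AUC':>7s}"]
    for name, rep in reports.items():
        rows = [
            ("Normal", rep.per_class["normal"], f"{100 * rep.acc:5.2f}", f"{rep.auc:.4f}"),
            ("Glaucoma", rep.per_class["glaucoma"], "", ""),
            ("Average", rep.macro, "", ""),
        ]
        for i, (label, m, acc_txt, auc_txt) in enumerate(rows):
            lines.append(
                f"{name if i == 0 else '':28s} {label:9s} "
                f"{_pct(m.prec):>6s} {_pct(m.sen):>6s} {_pct(m.f1):>6s} "
                f"{acc_txt:>6s} {auc_txt:>7s}"
            )
    return "\n".join(lines) + "\n"
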