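"""Confusion matrices and the six binary-classification statistics.

Pathogenic is the positive truth class and a deleterious call the positive
prediction.  From the TP/FP/TN/FN counts the module derives sensitivity
(TPR), specificity (TNR), positive and negative predictive value (PPV, NPV),
total accuracy (ACC) and balanced accuracy (BACC = (TPR + TNR)/2).  A zero
denominator leaves that one statistic undefined (``None``) rather than
failing the whole report — the benchmark subsets here are small and empty
cells are routine.

:func:`benchmark_report` evaluates each predictor of a labelled score table
independently (rows lacking that predictor's score are dropped and counted),
and additionally summarises subsets of the table, including the fraction of
rows with ΔΔG > 0 — the raw "destabilising" criterion, deliberately distinct
from FoldX's 1 kcal/mol classification threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .calls import (
    Call,
    DEFAULT_THRESHOLDS,
    Predictor,
    PredictorScores,
    Thresholds,
    call_foldx,
    call_polyphen2,
    call_svm,
)
from .variants import Variant

__all__ = [
    "TruthLabel",
    "LabeledCall",
    "ConfusionCounts",
    "MetricSet",
    "MetricsError",
    "confusion",
    "metric_set",
    "benchmark_report",
    "BenchmarkRow",
    "BenchmarkReport",
    "PredictorBenchmark",
    "SubsetSummary",
]


class MetricsError(ValueError):
    """Raised for empty or degenerate metric inputs."""


class TruthLabel(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


@dataclass(frozen=True)
class LabeledCall:
    """A known truth label paired with a binary prediction for one variant."""

    variant: Variant
    truth: TruthLabel
    predicted: Call  # DELETERIOUS or NEUTRAL; MISSING is excluded upstream

    def __post_init__(self) -> None:
        if self.predicted == Call.MISSING:
            raise MetricsError("missing predictions must be excluded before scoring")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in (("tp", self.tp), ("fp", self.fp), ("tn", self.tn), ("fn", self.fn)):
            if not isinstance(v, int) or v < 0:
                raise MetricsError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The six statistics; ``None`` marks an undefined (zero-denominator) cell."""

    tpr: Optional[float]
    tnr: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    acc: Optional[float]
    bacc: Optional[float]


def confusion(calls: Sequence[LabeledCall]) -> ConfusionCounts:
    """Cross-tabulate truth against prediction (pathogenic/deleterious = positive)."""
    if not calls:
        raise MetricsError("no labelled calls to score")
    tp = fp = tn = fn = 0
    for c in calls:
        positive_truth = c.truth == TruthLabel.PATHOGENIC
        positive_pred = c.predicted == Call.DELETERIOUS
        if positive_truth and positive_pred:
            tp += 1
        elif positive_truth:
            fn += 1
        elif positive_pred:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def metric_set(c: ConfusionCounts) -> MetricSet:
    """Derive TPR, TNR, PPV, NPV, ACC and BACC from confusion counts.

    Statistics with a zero denominator come back as ``None``; BACC is
    defined only when both TPR and TNR are.
    """
    if c.total == 0:
        raise MetricsError("all confusion counts are zero")
    tpr = _ratio(c.tp, c.tp + c.fn)
    tnr = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    acc = (c.tp + c.tn) / c.total
    bacc = (tpr + tnr) / 2 if tpr is not None and tnr is not None else None
    return MetricSet(tpr, tnr, ppv, npv, acc, bacc)


# ---------------------------------------------------------------------------
# Benchmark report over a labelled score table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkRow:
    """One labelled input row: variant, score triple, truth, optional subset tag."""

    variant: Variant
    scores: PredictorScores
    truth: TruthLabel
    subset: Optional[str] = None


@dataclass(frozen=True)
class SubsetSummary:
    subset: str
    n: int
    n_deleterious: int

    @property
    def n_neutral(self) -> int:
        return self.n - self.n_deleterious

    @property
    def fraction_deleterious(self) -> float:
        return self.n_deleterious / self.n

    @property
    def fraction_neutral(self) -> float:
        return self.n_neutral / self.n


@dataclass(frozen=True)
class PredictorBenchmark:
    predictor: Predictor
    confusion: ConfusionCounts
    metrics: MetricSet
    n_scored: int
    n_missing: int
    subsets: Tuple[SubsetSummary, ...]


@dataclass(frozen=True)
class DestabilizationSummary:
    """Per-subset counts of the sign of ΔΔG (positive = destabilising)."""

    subset: str
    n: int
    n_positive_ddg: int
    n_negative_ddg: int

    @property
    def fraction_positive(self) -> float:
        return self.n_positive_ddg / self.n

    @property
    def fraction_negative(self) -> float:
        return self.n_negative_ddg / self.n


@dataclass(frozen=True)
class BenchmarkReport:
    per_predictor: Dict[Predictor, PredictorBenchmark]
    destabilization: Tuple[DestabilizationSummary, ...]
    thresholds: Thresholds
    n_rows: int


_CALLERS = {
    Predictor.SVM: (lambda r: r.scores.svm, call_svm),
    Predictor.FOLDX: (lambda r: r.scores.foldx_ddg, call_foldx),
    Predictor.POLYPHEN2: (lambda r: r.scores.polyphen2, call_polyphen2),
}


def benchmark_report(
    rows: Sequence[BenchmarkRow],
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> BenchmarkReport:
    """Score every predictor against the truth labels of a benchmark table.

    For each predictor, rows carrying that score are called at the default
    thresholds and cross-tabulated; rows without it are dropped and counted
    in ``n_missing``.  Subset summaries (calls per subset tag) and the
    sign-of-ΔΔG destabilisation summary are emitted alongside.  A predictor
    with no scored rows is omitted from the report.
    """
    if not rows:
        raise MetricsError("empty benchmark table")
    per_pred: Dict[Predictor, PredictorBenchmark] = {}
    subset_order = _unique_subsets(rows)
    for predictor, (getter, caller) in _CALLERS.items():
        scored: List[Tuple[BenchmarkRow, Call]] = []
        n_missing = 0
        for row in rows:
            score = getter(row)
            if score is None:
                n_missing += 1
                continue
            scored.append((row, caller(score, t).call))
        if not scored:
            continue
        labelled = [LabeledCall(r.variant, r.truth, c) for r, c in scored]
        counts = confusion(labelled)
        summaries = []
        for name in subset_order:
            members = [(r, c) for r, c in scored if r.subset == name]
            if members:
                n_del = sum(1 for _, c in members if c == Call.DELETERIOUS)
                summaries.append(SubsetSummary(name, len(members), n_del))
        per_pred[predictor] = PredictorBenchmark(
            predictor, counts, metric_set(counts), len(scored), n_missing, tuple(summaries)
        )
    destab = []
    for name in subset_order:
        members = [r for r in rows if r.subset == name and r.scores.foldx_ddg is not None]
        if members:
            pos = sum(1 for r in members if r.scores.foldx_ddg > 0)
            neg = sum(1 for r in members if r.scores.foldx_ddg < 0)
            destab.append(DestabilizationSummary(name, len(members), pos, neg))
    return BenchmarkReport(per_pred, tuple(destab), t, len(rows))


def _unique_subsets(rows: Iterable[BenchmarkRow]) -> List[str]:
    seen: List[str] = []
    for r in rows:
        if r.subset is not None and r.subset not in seen:
            seen.append(r.subset)
    return seen
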