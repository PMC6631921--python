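"""Per-predictor deleterious/neutral calls and the four-way consensus vote.

Three predictors score each missense variant:

* an SVM-derived probability of pathogenicity in [0, 1] — deleterious at or
  above 0.5;
* a FoldX folding free-energy change ΔΔG in kcal/mol (positive values
  destabilise the mutant) — deleterious when ΔΔG, rounded to one decimal as
  the scores are reported, reaches 1.0 kcal/mol (i.e. ΔΔG >= 0.95);
* a PolyPhen-2 posterior probability of damage in [0, 1] — deleterious at or
  above 0.5 for voting; the conventional descriptive ternary (benign /
  possibly damaging / probably damaging at 0.15 and 0.85) is reported
  alongside but does not enter the vote.

The consensus category is a pure function of the number of deleterious votes
among the predictors that produced a score: 3 -> probably deleterious,
2 -> possibly deleterious, 1 -> possibly neutral, 0 -> probably neutral.
A missing score (e.g. no ΔΔG for a residue absent from the structure) drops
out of the denominator rather than counting as a neutral vote.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .variants import Variant

__all__ = [
    "Predictor",
    "Call",
    "ConsensusLabel",
    "PredictorScores",
    "PredictorCall",
    "ConsensusCategory",
    "Thresholds",
    "ScoreValidationError",
    "round_half_away",
    "call_svm",
    "call_foldx",
    "call_polyphen2",
    "call_all",
    "pp2_ternary_label",
    "consensus_category",
    "classify_table",
]


class ScoreValidationError(ValueError):
    """A predictor score violates its documented range."""


class Predictor(str, Enum):
    SVM = "svm"
    FOLDX = "foldx"
    POLYPHEN2 = "polyphen2"


class Call(str, Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    MISSING = "missing"


class ConsensusLabel(str, Enum):
    PROBABLY_DELETERIOUS = "probably_deleterious"
    POSSIBLY_DELETERIOUS = "possibly_deleterious"
    POSSIBLY_NEUTRAL = "possibly_neutral"
    PROBABLY_NEUTRAL = "probably_neutral"


#: vote count -> consensus label (counted over available predictors)
_LABEL_BY_VOTES: Mapping[int, ConsensusLabel] = {
    3: ConsensusLabel.PROBABLY_DELETERIOUS,
    2: ConsensusLabel.POSSIBLY_DELETERIOUS,
    1: ConsensusLabel.POSSIBLY_NEUTRAL,
    0: ConsensusLabel.PROBABLY_NEUTRAL,
}


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Decimal rounding with ties away from zero (reporting convention)."""
    if x is None or not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PredictorScores:
    """The raw score triple for one variant; each component may be missing."""

    svm: Optional[float] = None
    foldx_ddg: Optional[float] = None
    polyphen2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.svm is not None and not 0.0 <= self.svm <= 1.0:
            raise ScoreValidationError(f"SVM probability {self.svm} outside [0, 1]")
        if self.polyphen2 is not None and not 0.0 <= self.polyphen2 <= 1.0:
            raise ScoreValidationError(f"PolyPhen-2 score {self.polyphen2} outside [0, 1]")
        if self.svm is None and self.foldx_ddg is None and self.polyphen2 is None:
            raise ScoreValidationError("at least one predictor score must be present")


@dataclass(frozen=True)
class PredictorCall:
    predictor: Predictor
    call: Call
    score: Optional[float] = None
    annotation: Optional[str] = None  # e.g. PolyPhen-2 ternary label

    def __post_init__(self) -> None:
        if self.call == Call.MISSING and self.score is not None:
            raise ScoreValidationError("a missing call cannot carry a score")


@dataclass(frozen=True)
class Thresholds:
    """Decision boundaries for the three predictors (all comparisons inclusive).

    ``foldx_round_decimals`` applies one-decimal rounding to ΔΔG before the
    comparison with ``foldx_cut``, matching the precision at which scores are
    reported; with the defaults a ΔΔG of 0.99 kcal/mol votes deleterious.
    ``pp2_ternary`` bounds only label the descriptive benign / possibly /
    probably-damaging bands and never affect the vote.
    """

    svm_cut: float = 0.5
    foldx_cut: float = 1.0
    foldx_round_decimals: Optional[int] = 1
    pp2_vote_cut: float = 0.5
    pp2_ternary: Tuple[float, float] = (0.15, 0.85)

    def __post_init__(self) -> None:
        if not 0.0 <= self.svm_cut <= 1.0:
            raise ScoreValidationError(f"svm_cut {self.svm_cut} outside [0, 1]")
        if not 0.0 <= self.pp2_vote_cut <= 1.0:
            raise ScoreValidationError(f"pp2_vote_cut {self.pp2_vote_cut} outside [0, 1]")
        lo, hi = self.pp2_ternary
        if not (0.0 <= lo < hi <= 1.0):
            raise ScoreValidationError(f"pp2_ternary bounds {self.pp2_ternary} invalid")


DEFAULT_THRESHOLDS = Thresholds()


def call_svm(p: Optional[float], t: Thresholds = DEFAULT_THRESHOLDS) -> PredictorCall:
    """Deleterious iff the SVM probability is at or above ``t.svm_cut``."""
    if p is None:
        return PredictorCall(Predictor.SVM, Call.MISSING)
    if not 0.0 <= p <= 1.0:
        raise ScoreValidationError(f"SVM probability {p} outside [0, 1]")
    call = Call.DELETERIOUS if p >= t.svm_cut else Call.NEUTRAL
    return PredictorCall(Predictor.SVM, call, p)


def call_foldx(ddg: Optional[float], t: Thresholds = DEFAULT_THRESHOLDS) -> PredictorCall:
    """Deleterious iff ΔΔG (rounded per ``t.foldx_round_decimals``) reaches ``t.foldx_cut``."""
    if ddg is None:
        return PredictorCall(Predictor.FOLDX, Call.MISSING)
    ddg = float(ddg)
    effective = ddg if t.foldx_round_decimals is None else round_half_away(ddg, t.foldx_round_decimals)
    call = Call.DELETERIOUS if effective >= t.foldx_cut else Call.NEUTRAL
    return PredictorCall(Predictor.FOLDX, call, ddg)


def pp2_ternary_label(s: float, t: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Descriptive PolyPhen-2 band: benign <= lower bound < possibly < upper bound <= probably."""
    lo, hi = t.pp2_ternary
    if s >= hi:
        return "probably_damaging"
    if s <= lo:
        return "benign"
    return "possibly_damaging"


def call_polyphen2(s: Optional[float], t: Thresholds = DEFAULT_THRESHOLDS) -> PredictorCall:
    """Deleterious iff the PolyPhen-2 score is at or above ``t.pp2_vote_cut``.

    The returned call is annotated with the descriptive ternary band.
    """
    if s is None:
        return PredictorCall(Predictor.POLYPHEN2, Call.MISSING)
    if not 0.0 <= s <= 1.0:
        raise ScoreValidationError(f"PolyPhen-2 score {s} outside [0, 1]")
    call = Call.DELETERIOUS if s >= t.pp2_vote_cut else Call.NEUTRAL
    return PredictorCall(Predictor.POLYPHEN2, call, s, annotation=pp2_ternary_label(s, t))


def call_all(scores: PredictorScores, t: Thresholds = DEFAULT_THRESHOLDS) -> Tuple[PredictorCall, PredictorCall, PredictorCall]:
    return (
        call_svm(scores.svm, t),
        call_foldx(scores.foldx_ddg, t),
        call_polyphen2(scores.polyphen2, t),
    )


@dataclass(frozen=True)
class ConsensusCategory:
    """Consensus label with its vote tally.

    ``reduced_evidence`` flags variants scored by fewer than three
    predictors, whose label rests on a shrunken vote denominator.
    """

    label: ConsensusLabel
    n_deleterious: int
    n_available: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_deleterious <= self.n_available <= 3:
            raise ScoreValidationError(
                f"inconsistent vote tally: {self.n_deleterious}/{self.n_available}"
            )

    @property
    def reduced_evidence(self) -> bool:
        return self.n_available < 3


def consensus_category(calls: Sequence[PredictorCall]) -> ConsensusCategory:
    """Map deleterious-vote count to the four-way consensus label.

    Missing calls shrink the denominator; the count-to-label map is fixed
    regardless of which predictors voted.  All calls missing is an error.
    """
    available = [c for c in calls if c.call != Call.MISSING]
    if not available:
        raise ScoreValidationError("no predictor produced a score; consensus undefined")
    n_del = sum(1 for c in available if c.call == Call.DELETERIOUS)
    return ConsensusCategory(_LABEL_BY_VOTES[n_del], n_del, len(available))


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: Variant
    scores: PredictorScores
    calls: Tuple[PredictorCall, PredictorCall, PredictorCall]
    category: ConsensusCategory


@dataclass
class ClassificationResult:
    rows: List[ClassifiedVariant]
    summary: Dict[ConsensusLabel, int] = field(default_factory=dict)
    thresholds: Thresholds = DEFAULT_THRESHOLDS


def classify_table(
    scores: Iterable[Tuple[Variant, PredictorScores]],
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> ClassificationResult:
    """Apply the three predictor calls and the consensus vote row by row.

    Returns the per-variant classifications plus a summary mapping each of
    the four labels to its count (all four labels always present).  Per-row
    validation failures are re-raised with the offending variant named.
    """
    rows: List[ClassifiedVariant] = []
    for variant, sc in scores:
        try:
            calls = call_all(sc, t)
            cat = consensus_category(calls)
        except ScoreValidationError as exc:
            raise ScoreValidationError(f"{variant}: {exc}") from exc
        rows.append(ClassifiedVariant(variant, sc, calls, cat))
    if not rows:
        raise ScoreValidationError("empty score table")
    counts = Counter(r.category.label for r in rows)
    summary = {label: counts.get(label, 0) for label in ConsensusLabel}
    return ClassificationResult(rows, summary, t)
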