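"""Score-table I/O, run configuration, packaged fixtures and report writers.

Score tables are TSV/CSV with header columns ``variant``, ``svm``,
``foldx_ddg``, ``polyphen2`` and optional ``label`` (pathogenic/benign),
``subset`` and ``scheme`` columns; empty cells and ``N/A``/``NA`` mark a
missing score.  Two curated tables ship with the package (integrity-checked
on load): predictor scores for 16 rare SERPINA1 missense variants, and a
57-variant labelled benchmark (17 ClinVar-pathogenic, 5 ClinVar-benign and
35 primate-derived neutral variants).

Report writers emit deterministic TSV and JSON (stable row order, fixed
number formatting, the full run configuration embedded for provenance).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml

from .benchmark import BenchmarkConfig, CandidateNeutralVariant
from .calls import (
    ClassificationResult,
    Thresholds,
    round_half_away,
)
from .metrics import BenchmarkReport, BenchmarkRow, MetricsError, TruthLabel
from .variants import (
    NumberingScheme,
    SIGNAL_PEPTIDE_LEN,
    Variant,
    VariantError,
    parse_variant,
)
from .calls import PredictorScores, ScoreValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "FixtureIntegrityError",
    "RunConfig",
    "ScoreRow",
    "read_score_table",
    "to_benchmark_rows",
    "load_table2",
    "load_table3",
    "fixture_path",
    "write_classification",
    "write_benchmark",
    "write_candidates",
]

_MISSING_TOKENS = {"", "N/A", "NA", "n/a", "na", "None", "nan"}


class ConfigurationError(ValueError):
    """Bad run configuration or score-table layout."""


class FixtureIntegrityError(RuntimeError):
    """A packaged data file does not match its recorded checksum."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """All tunable settings; the defaults reproduce the reference analysis.

    Thresholds: SVM and PolyPhen-2 vote at 0.5, FoldX at 1.0 kcal/mol after
    one-decimal rounding.  Benchmark filters: 5 Å contacts, ±2 conserved
    flank, ±3 gap window, > 90% source identity.  The signal peptide is the
    24 residues of AAT by default.
    """

    thresholds: Thresholds = field(default_factory=Thresholds)
    contact_cutoff: float = 5.0
    flank_k: int = 2
    gap_window: int = 3
    identity_min: float = 90.0
    signal_peptide_len: int = SIGNAL_PEPTIDE_LEN
    chain_selector: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.identity_min < 0 or self.signal_peptide_len <= 0:
            raise ConfigurationError("numeric configuration fields must be positive")
        if self.flank_k < 0 or self.gap_window < 0:
            raise ConfigurationError("flank_k and gap_window must be non-negative")

    @property
    def benchmark_config(self) -> BenchmarkConfig:
        return BenchmarkConfig(
            identity_min=self.identity_min,
            flank_k=self.flank_k,
            gap_window=self.gap_window,
            contact_cutoff=self.contact_cutoff,
        )

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        """Load a flat-key YAML file; keyword overrides (e.g. from a CLI) win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"configuration in {path} is not a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_flat(raw)

    @classmethod
    def from_flat(cls, raw: Dict) -> "RunConfig":
        thr_keys = {"svm_cut", "foldx_cut", "foldx_round_decimals", "pp2_vote_cut", "pp2_ternary"}
        cfg_keys = {f.name for f in dataclasses.fields(cls)} - {"thresholds"}
        unknown = set(raw) - thr_keys - cfg_keys
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        thr_kwargs = {k: raw[k] for k in thr_keys if k in raw}
        if "pp2_ternary" in thr_kwargs:
            thr_kwargs["pp2_ternary"] = tuple(thr_kwargs["pp2_ternary"])
        try:
            thresholds = Thresholds(**thr_kwargs)
        except ScoreValidationError as exc:
            raise ConfigurationError(str(exc)) from exc
        return cls(thresholds=thresholds, **{k: raw[k] for k in cfg_keys if k in raw})


# ---------------------------------------------------------------------------
# Score-table reading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreRow:
    """One validated score-table row."""

    variant: Variant
    scores: PredictorScores
    label: Optional[TruthLabel] = None
    subset: Optional[str] = None
    line: int = 0


REQUIRED_COLUMNS = ("variant", "svm", "foldx_ddg", "polyphen2")


def _parse_score(raw, column: str, lo: Optional[float] = None, hi: Optional[float] = None) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw in _MISSING_TOKENS:
            return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ConfigurationError(f"column {column!r}: cannot parse {raw!r} as a number")
    if lo is not None and not (lo <= value <= (hi if hi is not None else value)):
        raise ConfigurationError(f"column {column!r}: {value} outside [{lo}, {hi}]")
    return value


def read_score_table(
    path: Union[str, Path],
    dialect: Optional[str] = None,
    strict: bool = True,
) -> List[ScoreRow]:
    """Read and validate a TSV/CSV score table.

    ``dialect`` forces ``"tsv"`` or ``"csv"``; by default it follows the file
    extension (TSV otherwise).  Malformed rows are reported with their line
    number; ``strict=True`` aborts on the first bad row, ``strict=False``
    logs and skips it.  Missing required columns raise
    :class:`ConfigurationError`.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(
        dialect or ("csv" if path.suffix.lower() == ".csv" else "tsv")
    )
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required columns {missing}")
    rows: List[ScoreRow] = []
    for idx, rec in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            scheme = NumberingScheme.MATURE
            if "scheme" in df.columns and rec["scheme"].strip():
                scheme = NumberingScheme(rec["scheme"].strip().lower())
            variant = parse_variant(rec["variant"], scheme)
            scores = PredictorScores(
                svm=_parse_score(rec["svm"], "svm", 0.0, 1.0),
                foldx_ddg=_parse_score(rec["foldx_ddg"], "foldx_ddg"),
                polyphen2=_parse_score(rec["polyphen2"], "polyphen2", 0.0, 1.0),
            )
            label = None
            if "label" in df.columns and rec["label"].strip():
                label = TruthLabel(rec["label"].strip().lower())
            subset = rec["subset"].strip() if "subset" in df.columns and rec["subset"].strip() else None
        except (VariantError, ScoreValidationError, ConfigurationError, ValueError) as exc:
            msg = f"{path}:{line}: {exc}"
            if strict:
                raise ConfigurationError(msg) from exc
            logger.warning("skipping malformed row — %s", msg)
            continue
        rows.append(ScoreRow(variant, scores, label, subset, line))
    if not rows:
        raise ConfigurationError(f"{path}: no valid rows")
    return rows


def to_benchmark_rows(rows: Sequence[ScoreRow]) -> List[BenchmarkRow]:
    """Convert reader rows to labelled benchmark rows (all must carry a label)."""
    out = []
    for r in rows:
        if r.label is None:
            raise MetricsError(f"row {r.variant} (line {r.line}) has no truth label")
        out.append(BenchmarkRow(r.variant, r.scores, r.label, r.subset))
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_file(name: str) -> Path:
    return Path(str(resources.files("serpinvar.data").joinpath(name)))


def _verify_checksum(name: str) -> Path:
    path = _data_file(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(_data_file("checksums.json")) as fh:
        recorded = json.load(fh)
    if recorded.get(name) != digest:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} does not match recorded {recorded.get(name)}"
        )
    return path


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture (``table2`` or ``table3``), checksum-verified."""
    mapping = {"table2": "table2_scores.tsv", "table3": "table3_benchmark.tsv"}
    if name not in mapping:
        raise ConfigurationError(f"unknown fixture {name!r}; expected one of {sorted(mapping)}")
    return _verify_checksum(mapping[name])


def load_table2() -> List[ScoreRow]:
    """The 16 rare SERPINA1 missense variants with their predictor scores."""
    return read_score_table(fixture_path("table2"))


def load_table3() -> List[ScoreRow]:
    """The 57-variant labelled benchmark (ClinVar pathogenic/benign + primate neutral)."""
    return read_score_table(fixture_path("table3"))


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def _fmt(x: Optional[float], nd: int = 4) -> str:
    if x is None:
        return "NA"
    return f"{x:.{nd}f}".rstrip("0").rstrip(".") if x != int(x) else str(int(x))


def _ensure_outdir(out_dir: Union[str, Path]) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def write_classification(
    result: ClassificationResult,
    out_dir: Union[str, Path],
    config: Optional[RunConfig] = None,
    formats: Sequence[str] = ("tsv", "json"),
    stem: str = "classification",
) -> List[Path]:
    """Write consensus-classification results as TSV and/or JSON.

    Output is deterministic: input row order is preserved and numbers are
    fixed-format.  The JSON file embeds the summary counts, thresholds and
    full run configuration.
    """
    if not result.rows:
        raise MetricsError("no classified rows to write")
    out = _ensure_outdir(out_dir)
    written: List[Path] = []
    records = []
    for row in result.rows:
        svm_c, foldx_c, pp2_c = row.calls
        records.append({
            "variant": str(row.variant),
            "scheme": row.variant.scheme.value,
            "svm": _fmt(row.scores.svm),
            "svm_call": svm_c.call.value,
            "foldx_ddg": _fmt(row.scores.foldx_ddg),
            "foldx_call": foldx_c.call.value,
            "polyphen2": _fmt(row.scores.polyphen2),
            "polyphen2_call": pp2_c.call.value,
            "polyphen2_band": pp2_c.annotation or "NA",
            "n_deleterious": row.category.n_deleterious,
            "n_available": row.category.n_available,
            "reduced_evidence": row.category.reduced_evidence,
            "category": row.category.label.value,
        })
    if "tsv" in formats:
        path = out / f"{stem}.tsv"
        pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
        written.append(path)
    if "json" in formats:
        path = out / f"{stem}.json"
        payload = {
            "rows": records,
            "summary": {label.value: n for label, n in result.summary.items()},
            "thresholds": dataclasses.asdict(result.thresholds),
            "config": config.to_dict() if config else None,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)
    return written


def write_benchmark(
    report: BenchmarkReport,
    out_dir: Union[str, Path],
    config: Optional[RunConfig] = None,
    formats: Sequence[str] = ("tsv", "json"),
    stem: str = "benchmark",
) -> List[Path]:
    """Write a benchmark report as JSON (full precision) and/or flat TSV.

    Displayed statistics are additionally rounded half-away-from-zero to 3
    decimals under ``*_display`` keys.
    """
    if not report.per_predictor:
        raise MetricsError("benchmark report contains no scored predictors")
    out = _ensure_outdir(out_dir)
    written: List[Path] = []
    per_pred = {}
    flat_rows = []
    for predictor, bench in report.per_predictor.items():
        metrics = dataclasses.asdict(bench.metrics)
        per_pred[predictor.value] = {
            "confusion": dataclasses.asdict(bench.confusion),
            "metrics": metrics,
            "metrics_display": {k: (round_half_away(v, 3) if v is not None else None)
                                for k, v in metrics.items()},
            "n_scored": bench.n_scored,
            "n_missing": bench.n_missing,
            "subsets": [
                {
                    "subset": s.subset, "n": s.n,
                    "n_deleterious": s.n_deleterious, "n_neutral": s.n_neutral,
                    "fraction_deleterious": s.fraction_deleterious,
                    "fraction_neutral": s.fraction_neutral,
                }
                for s in bench.subsets
            ],
        }
        flat_rows.append({
            "predictor": predictor.value,
            **dataclasses.asdict(bench.confusion),
            **{k: _fmt(round_half_away(v, 3) if v is not None else None)
               for k, v in metrics.items()},
            "n_scored": bench.n_scored,
            "n_missing": bench.n_missing,
        })
    payload = {
        "per_predictor": per_pred,
        "destabilization": [
            {
                "subset": d.subset, "n": d.n,
                "n_positive_ddg": d.n_positive_ddg, "n_negative_ddg": d.n_negative_ddg,
                "fraction_positive": d.fraction_positive,
                "fraction_negative": d.fraction_negative,
            }
            for d in report.destabilization
        ],
        "thresholds": dataclasses.asdict(report.thresholds),
        "n_rows": report.n_rows,
        "config": config.to_dict() if config else None,
    }
    if "json" in formats:
        path = out / f"{stem}.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)
    if "tsv" in formats:
        path = out / f"{stem}.tsv"
        pd.DataFrame.from_records(flat_rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def write_candidates(
    accepted: Sequence[CandidateNeutralVariant],
    candidates: Sequence[CandidateNeutralVariant],
    out_dir: Union[str, Path],
    stem: str = "neutral_candidates",
) -> Path:
    """Write every evaluated candidate with its filter booleans and accepted flag."""
    out = _ensure_outdir(out_dir)
    accepted_keys = {(c.variant.ref_aa, c.variant.position, c.variant.alt_aa, c.subject_id)
                     for c in accepted}
    records = []
    for c in sorted(candidates, key=lambda c: (c.variant.position, c.variant.alt_aa, c.subject_id)):
        key = (c.variant.ref_aa, c.variant.position, c.variant.alt_aa, c.subject_id)
        records.append({
            "variant": str(c.variant),
            "subject_id": c.subject_id,
            "source_identity": f"{c.source_identity:.4f}",
            "flank_ok": c.flank_ok,
            "gap_ok": c.gap_ok,
            "contacts_ok": c.contacts_ok,
            "reason": c.reason or "",
            "accepted": key in accepted_keys,
        })
    path = out / f"{stem}.tsv"
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
    return path
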