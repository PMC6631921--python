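"""Seeded generators for pipeline inputs with ground truth known by construction.

Paper-scale inputs to the benchmark builder (a curated homolog set and a
crystal structure) come from external databases, so each stage is instead
validated against synthetic inputs whose correct output is planted:

* :func:`gen_homolog_pair` builds a human-query/homolog alignment in which
  every substitution's filter outcome (flank conservation, gap proximity,
  contact conservation) is realised by construction, together with a toy
  structure providing the contacts, and returns the exact expected
  candidate and accepted sets;
* :func:`gen_toy_structure` places single-atom (or jittered three-atom)
  residues at controlled distances and returns the analytically expected
  contact map;
* :func:`gen_score_table` samples threshold-straddling predictor scores
  that reproduce a planted confusion matrix exactly.

All generators are deterministic functions of their spec and seed.  The
score distributions emulate only the threshold structure of real predictor
output, not its shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import gemmi
import numpy as np

from .benchmark import GAP, AlignedPair, CandidateNeutralVariant, ContactMap
from .calls import Predictor, PredictorScores, Thresholds, DEFAULT_THRESHOLDS
from .metrics import BenchmarkRow, ConfusionCounts, MetricSet, TruthLabel, metric_set
from .variants import AMINO_ACIDS, NumberingScheme, ReferenceSequence, Variant

__all__ = [
    "GenerationError",
    "PlantedOutcome",
    "SyntheticHomologSpec",
    "SyntheticHomologResult",
    "SyntheticScoreSpec",
    "SyntheticScoreResult",
    "gen_homolog_pair",
    "gen_toy_structure",
    "gen_score_table",
    "build_structure",
]

_AA = sorted(AMINO_ACIDS)

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: residue spacing (Å) along the backbone line; > 5 so line neighbours are
#: never contacts and every planted contact is explicit
_LINE_SPACING = 8.0
#: offset (Å) of a planted contact partner from its residue; < 5
_PARTNER_OFFSET = 4.0
#: minimum column separation between planted features so their +-2 flank and
#: +-3 gap windows (plus the helper at s+1 and gap at s+3) cannot interact
_FEATURE_SPACING = 8
#: minimum separation among background substitutions (flank window is +-2)
_BACKGROUND_SPACING = 3


class GenerationError(ValueError):
    """The requested synthetic spec is geometrically or numerically infeasible."""


@dataclass(frozen=True)
class PlantedOutcome:
    """Requested filter outcomes for one planted substitution."""

    flank_ok: bool = True
    gap_ok: bool = True
    contacts_ok: bool = True

    @property
    def accepted(self) -> bool:
        return self.flank_ok and self.gap_ok and self.contacts_ok


@dataclass(frozen=True)
class SyntheticHomologSpec:
    """Recipe for one query/homolog alignment with planted filter outcomes.

    ``target_identity`` is hit to within one percentage point by adding
    isolated background substitutions (which pass every filter and belong
    to the expected accepted set); ``gap_positions`` may add extra subject
    gaps away from all substitutions.
    """

    query_length: int = 120
    target_identity: float = 95.0
    planted_outcomes: Tuple[PlantedOutcome, ...] = (PlantedOutcome(),)
    gap_positions: Tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.query_length < 20:
            raise GenerationError("query_length must be at least 20")
        if not 0 < self.target_identity <= 100:
            raise GenerationError("target_identity must be in (0, 100]")


@dataclass
class SyntheticHomologResult:
    pair: AlignedPair
    structure: gemmi.Structure
    query: ReferenceSequence
    candidates: List[CandidateNeutralVariant]
    accepted: List[CandidateNeutralVariant]
    realized_identity: float


def build_structure(
    residues: Sequence[Tuple[int, str, Sequence[Tuple[float, float, float]]]],
    name: str = "synthetic",
) -> gemmi.Structure:
    """Assemble a single-chain gemmi structure from (resnum, aa, atom coords)."""
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    atom_names = ("CA", "CB", "CG", "CD", "CE")
    for num, aa, coords in residues:
        res = gemmi.Residue()
        res.name = _THREE_LETTER[aa]
        res.seqid = gemmi.SeqId(num, " ")
        for i, (x, y, z) in enumerate(coords):
            atom = gemmi.Atom()
            atom.name = atom_names[i % len(atom_names)]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _place(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    taken: List[Tuple[int, int]],
    radius: int,
    tries: int = 500,
) -> int:
    """Sample a column in [lo, hi] at >= max(radius, r_other) from all taken."""
    if hi < lo:
        raise GenerationError("sequence too short for the requested features")
    for _ in range(tries):
        pos = int(rng.integers(lo, hi + 1))
        if all(abs(pos - p) >= max(radius, r) for p, r in taken):
            return pos
    raise GenerationError("could not place all features; sequence too short or spec too dense")


def _random_alt(rng: np.random.Generator, ref: str) -> str:
    choices = [a for a in _AA if a != ref]
    return choices[int(rng.integers(0, len(choices)))]


def gen_homolog_pair(spec: SyntheticHomologSpec) -> SyntheticHomologResult:
    """Generate an alignment + structure realising each planted filter outcome.

    Construction (0-based columns; query carries no gaps so query position =
    column + 1):

    * the toy structure puts one CA per residue on a line 8 Å apart (no
      incidental contacts); every planted substitution ``s`` gets a contact
      partner ``q`` placed 4 Å off the line next to ``s``;
    * ``flank_ok=False`` plants a helper substitution at ``s+1`` (which is
      itself rejected by its own flank filter);
    * ``gap_ok=False`` deletes the subject residue three columns right of
      ``s`` (outside the flank window, inside the gap window);
    * ``contacts_ok=False`` substitutes the subject at the partner ``q``
      (the helper at ``q`` is itself rejected by contact conservation,
      since ``q`` contacts the substituted ``s``);
    * isolated background substitutions bring the realised identity to
      within one point of the target; they pass all filters.

    Returns the pair, the structure, the ground-truth candidate list with
    outcomes, and the expected accepted set under the default filters.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.query_length
    query = "".join(_AA[i] for i in rng.integers(0, 20, size=L))

    lo, hi = 5, L - 7
    taken: List[Tuple[int, int]] = []
    planted_cols: List[int] = []
    partner_cols: List[int] = []
    for _ in spec.planted_outcomes:
        s = _place(rng, lo, hi, taken, _FEATURE_SPACING)
        taken.append((s, _FEATURE_SPACING))
        planted_cols.append(s)
    for _ in spec.planted_outcomes:
        q = _place(rng, lo, hi, taken, _FEATURE_SPACING)
        taken.append((q, _FEATURE_SPACING))
        partner_cols.append(q)
    for g in spec.gap_positions:
        if not 0 <= g < L:
            raise GenerationError(f"gap position {g} outside the sequence")
        if any(abs(g - p) < max(_FEATURE_SPACING, r) for p, r in taken):
            raise GenerationError(f"gap position {g} interferes with a planted feature")
        taken.append((g, _FEATURE_SPACING))

    subject = list(query)
    mismatch_cols: List[int] = []
    gap_cols: List[int] = list(spec.gap_positions)
    helper_flank: List[int] = []
    helper_contact: List[int] = []
    for s, q, outcome in zip(planted_cols, partner_cols, spec.planted_outcomes):
        subject[s] = _random_alt(rng, query[s])
        mismatch_cols.append(s)
        if not outcome.flank_ok:
            subject[s + 1] = _random_alt(rng, query[s + 1])
            mismatch_cols.append(s + 1)
            helper_flank.append(s + 1)
        if not outcome.gap_ok:
            gap_cols.append(s + 3)
        if not outcome.contacts_ok:
            subject[q] = _random_alt(rng, query[q])
            mismatch_cols.append(q)
            helper_contact.append(q)

    n_residue_cols = L - len(gap_cols)
    target_mismatches = int(round(n_residue_cols * (1.0 - spec.target_identity / 100.0)))
    n_background = target_mismatches - len(mismatch_cols)
    if n_background < 0:
        raise GenerationError(
            f"target identity {spec.target_identity}% too high for "
            f"{len(mismatch_cols)} planted mismatches on length {L}"
        )
    background_cols: List[int] = []
    for _ in range(n_background):
        b = _place(rng, lo, hi, taken, _BACKGROUND_SPACING)
        taken.append((b, _BACKGROUND_SPACING))
        subject[b] = _random_alt(rng, query[b])
        mismatch_cols.append(b)
        background_cols.append(b)

    for g in gap_cols:
        subject[g] = GAP
    realized = 100.0 * (n_residue_cols - len(mismatch_cols)) / n_residue_cols
    if abs(realized - spec.target_identity) > 1.0:
        raise GenerationError(
            f"realised identity {realized:.2f}% misses target {spec.target_identity}% by > 1 point"
        )

    subject_id = f"synthetic_homolog_seed{spec.seed}"
    pair = AlignedPair("query", subject_id, query, "".join(subject))

    # structure: line at 8 Å spacing; partners moved next to their residue
    partner_of = dict(zip(partner_cols, planted_cols))
    residues = []
    for col in range(L):
        if col in partner_of:
            x, y = _LINE_SPACING * partner_of[col], _PARTNER_OFFSET
        else:
            x, y = _LINE_SPACING * col, 0.0
        residues.append((col + 1, query[col], [(x, y, 0.0)]))
    structure = build_structure(residues, name=f"synthetic_seed{spec.seed}")

    candidates: List[CandidateNeutralVariant] = []

    def _cand(col: int, flank: bool, gap: bool, contacts: bool) -> CandidateNeutralVariant:
        v = Variant(query[col], col + 1, subject[col], NumberingScheme.MATURE)
        return CandidateNeutralVariant(
            v, subject_id, realized, col,
            flank_ok=flank, gap_ok=gap, contacts_ok=contacts,
        )

    for s, outcome in zip(planted_cols, spec.planted_outcomes):
        candidates.append(_cand(s, outcome.flank_ok, outcome.gap_ok, outcome.contacts_ok))
    for h in helper_flank:
        # the gap planted at s+3 sits two columns from this helper at s+1
        has_gap_near = any(abs(g - h) <= 3 for g in gap_cols)
        candidates.append(_cand(h, False, not has_gap_near, True))
    for q in helper_contact:
        candidates.append(_cand(q, True, True, False))
    for b in background_cols:
        candidates.append(_cand(b, True, True, True))
    candidates.sort(key=lambda c: c.variant.position)
    accepted = [c for c in candidates if c.accepted_filters] if realized > 90.0 else []

    return SyntheticHomologResult(
        pair=pair,
        structure=structure,
        query=ReferenceSequence("query", query),
        candidates=candidates,
        accepted=accepted,
        realized_identity=realized,
    )


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def gen_toy_structure(
    n_residues: int,
    seed: int = 0,
    mode: str = "random",
    spacing: float = 4.0,
    atoms_per_residue: int = 1,
    jitter: float = 0.8,
    cutoff: float = 5.0,
) -> Tuple[gemmi.Structure, ContactMap]:
    """A toy structure plus its expected contact map at ``cutoff``.

    ``mode="chain"`` spaces residues ``spacing`` Å apart on a line (contacts
    exactly the pairs whose centre distance is below the cutoff; e.g. 4 Å
    spacing gives {i, i+1} and a pair at exactly 5.0 Å is not a contact).
    ``mode="random"`` scatters residues in a cube sized for moderate contact
    density.  ``atoms_per_residue=3`` adds jittered side-chain atoms to
    exercise the min-over-atom-pairs rule; the expected map is computed from
    the actual atom coordinates.
    """
    if n_residues < 2:
        raise GenerationError("need at least two residues")
    if atoms_per_residue < 1 or atoms_per_residue > 5:
        raise GenerationError("atoms_per_residue must be in 1..5")
    if jitter < 0 or spacing <= 0 or cutoff <= 0:
        raise GenerationError("spacing, cutoff must be positive and jitter non-negative")
    rng = np.random.default_rng(seed)
    if mode == "chain":
        centers = np.column_stack(
            [spacing * np.arange(n_residues), np.zeros(n_residues), np.zeros(n_residues)]
        )
    elif mode == "random":
        side = max(6.0, (n_residues * 100.0) ** (1.0 / 3.0))
        centers = rng.uniform(0.0, side, size=(n_residues, 3))
    else:
        raise GenerationError(f"unknown mode {mode!r}")

    residues = []
    atom_coords: List[np.ndarray] = []
    for i, c in enumerate(centers):
        coords = [tuple(c)]
        for _ in range(atoms_per_residue - 1):
            offset = rng.uniform(-jitter, jitter, size=3)
            coords.append(tuple(c + offset))
        aa = _AA[int(rng.integers(0, 20))]
        residues.append((i + 1, aa, coords))
        atom_coords.append(np.asarray(coords))
    structure = build_structure(residues, name=f"toy_seed{seed}")

    contacts: Dict[int, set] = {i + 1: set() for i in range(n_residues)}
    for i in range(n_residues):
        for j in range(i + 1, n_residues):
            d = np.linalg.norm(atom_coords[i][:, None, :] - atom_coords[j][None, :, :], axis=-1)
            if float(d.min()) < cutoff:
                contacts[i + 1].add(j + 1)
                contacts[j + 1].add(i + 1)
    expected = ContactMap(cutoff, {k: frozenset(v) for k, v in contacts.items()})
    return structure, expected


# ---------------------------------------------------------------------------
# Labelled score tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticScoreSpec:
    """Planted per-predictor confusion counts for a labelled score table.

    ``planted`` maps predictors to the confusion matrix their thresholded
    calls must reproduce; a bare :class:`ConfusionCounts` applies to all
    three.  Every predictor must agree on the number of pathogenic
    (tp + fn) and benign (fp + tn) rows, since rows share truth labels.
    """

    planted: Union[ConfusionCounts, Mapping[Predictor, ConfusionCounts]]
    seed: int = 0

    def per_predictor(self) -> Dict[Predictor, ConfusionCounts]:
        if isinstance(self.planted, ConfusionCounts):
            return {p: self.planted for p in Predictor}
        return {Predictor(k): v for k, v in self.planted.items()}


@dataclass
class SyntheticScoreResult:
    rows: List[BenchmarkRow]
    expected_confusion: Dict[Predictor, ConfusionCounts]
    expected_metrics: Dict[Predictor, MetricSet]


# score sampling ranges straddling the default thresholds with a margin
_DELETERIOUS_RANGE = {"svm": (0.55, 0.99), "polyphen2": (0.55, 1.0), "foldx": (1.5, 6.0)}
_NEUTRAL_RANGE = {"svm": (0.01, 0.45), "polyphen2": (0.0, 0.45), "foldx": (-2.0, 0.5)}


def gen_score_table(
    spec: SyntheticScoreSpec,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> SyntheticScoreResult:
    """Sample a labelled score table reproducing the planted confusion exactly.

    Each predictor independently picks which pathogenic rows it calls
    deleterious (tp of them) and which benign rows it flags (fp of them),
    then draws scores from ranges that stay clear of the decision boundary.
    Predictors absent from the spec get missing scores.
    """
    planted = spec.per_predictor()
    if not planted:
        raise GenerationError("no predictor confusion counts planted")
    totals = {(c.tp + c.fn, c.fp + c.tn) for c in planted.values()}
    if len(totals) != 1:
        raise GenerationError("planted counts disagree on class sizes across predictors")
    (n_pos, n_neg), = totals
    if n_pos + n_neg == 0:
        raise GenerationError("planted confusion is empty")

    rng = np.random.default_rng(spec.seed)
    truths = [TruthLabel.PATHOGENIC] * n_pos + [TruthLabel.BENIGN] * n_neg

    # per predictor: boolean deleterious-call vector over rows, or None
    calls: Dict[Predictor, np.ndarray] = {}
    for pred, c in planted.items():
        vec = np.zeros(n_pos + n_neg, dtype=bool)
        pos_idx = rng.permutation(n_pos)[: c.tp]
        neg_idx = n_pos + rng.permutation(n_neg)[: c.fp]
        vec[pos_idx] = True
        vec[neg_idx] = True
        calls[pred] = vec

    def _draw(pred: Predictor, deleterious: bool) -> float:
        lo, hi = (_DELETERIOUS_RANGE if deleterious else _NEUTRAL_RANGE)[pred.value]
        return float(rng.uniform(lo, hi))

    rows: List[BenchmarkRow] = []
    for i, truth in enumerate(truths):
        ref = _AA[int(rng.integers(0, 20))]
        variant = Variant(ref, i + 1, _random_alt(rng, ref))
        scores = PredictorScores(
            svm=_draw(Predictor.SVM, bool(calls[Predictor.SVM][i])) if Predictor.SVM in calls else None,
            foldx_ddg=_draw(Predictor.FOLDX, bool(calls[Predictor.FOLDX][i])) if Predictor.FOLDX in calls else None,
            polyphen2=_draw(Predictor.POLYPHEN2, bool(calls[Predictor.POLYPHEN2][i])) if Predictor.POLYPHEN2 in calls else None,
        )
        rows.append(BenchmarkRow(variant, scores, truth, subset="synthetic"))

    expected_metrics = {p: metric_set(c) for p, c in planted.items()}
    return SyntheticScoreResult(rows, dict(planted), expected_metrics)
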