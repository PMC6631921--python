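"""Ortholog-derived neutral-variant benchmark construction.

A residue substituted in a close ortholog of a human protein is presumed
neutral in the human sequence, provided its context is otherwise preserved.
This module turns pairwise human-vs-homolog alignments into such a neutral
benchmark set using four filters:

1. **flank conservation** — the two alignment columns on either side of the
   substitution hold identical residues in both rows;
2. **gap proximity** — no gap in either row within three columns;
3. **contact conservation** — every residue in 3D contact with the
   substituted residue (any atom pair closer than 5 Å in the reference
   structure) is aligned to an identical residue in the homolog;
4. **identity** — the source alignment exceeds 90% sequence identity
   (identical residue pairs over ungapped aligned columns).

When the same substitution is found in several homologs, the record from
the highest-identity alignment is kept (closest homolog first), with ties
broken by subject id.

Structures are read with gemmi; waters and non-amino-acid residues are
excluded and alternate conformations collapsed to the highest-occupancy
atom.  Unaligned homolog sequences can be aligned internally with a global
affine-gap aligner (BLOSUM62) since the filters are defined on alignment
columns, not on any particular search tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .variants import AMINO_ACIDS, NumberingScheme, ReferenceSequence, Variant

logger = logging.getLogger(__name__)

__all__ = [
    "GAP",
    "AlignmentError",
    "StructureError",
    "ResidueNotResolvableError",
    "AlignedPair",
    "CandidateNeutralVariant",
    "ContactMap",
    "BenchmarkConfig",
    "percent_identity",
    "extract_substitutions",
    "flank_conserved",
    "gap_ok",
    "contact_map",
    "contact_map_for_query",
    "contacts_conserved",
    "align_homolog",
    "build_neutral_set",
    "evaluate_candidates",
]

GAP = "-"


class AlignmentError(ValueError):
    """Malformed alignment rows or degenerate alignment content."""


class StructureError(ValueError):
    """Structure lacks usable polymer atoms."""


class ResidueNotResolvableError(KeyError):
    """A variant position has no residue in the contact map's structure."""


# ---------------------------------------------------------------------------
# Aligned pairs and column filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedPair:
    """A pairwise alignment of the human query against one homolog.

    Rows are equal-length gapped sequences; a column may not be a gap in
    both rows.  Columns are 0-based; query residue positions are 1-based
    ungapped query coordinates.
    """

    query_id: str
    subject_id: str
    query_row: str
    subject_row: str

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.subject_row):
            raise AlignmentError(
                f"rows differ in length ({len(self.query_row)} vs {len(self.subject_row)})"
            )
        if not self.query_row:
            raise AlignmentError("empty alignment")
        for q, s in zip(self.query_row, self.subject_row):
            if q == GAP and s == GAP:
                raise AlignmentError("column gapped in both rows")

    def __len__(self) -> int:
        return len(self.query_row)

    def query_position_of_column(self, column: int) -> Optional[int]:
        """1-based ungapped query position at ``column``, or None on a query gap."""
        if self.query_row[column] == GAP:
            return None
        return column + 1 - self.query_row[:column + 1].count(GAP)

    def column_of_query_position(self, position: int) -> int:
        """Alignment column (0-based) holding ungapped query position ``position``."""
        seen = 0
        for col, ch in enumerate(self.query_row):
            if ch != GAP:
                seen += 1
                if seen == position:
                    return col
        raise AlignmentError(f"query position {position} beyond aligned query length {seen}")

    @property
    def percent_identity(self) -> float:
        return percent_identity(self)


def percent_identity(pair: AlignedPair) -> float:
    """Identity over ungapped columns: 100 x identical pairs / residue-residue columns."""
    both = [(q, s) for q, s in zip(pair.query_row, pair.subject_row) if q != GAP and s != GAP]
    if not both:
        raise AlignmentError("no ungapped aligned columns; identity undefined")
    identical = sum(1 for q, s in both if q == s)
    return 100.0 * identical / len(both)


@dataclass(frozen=True)
class CandidateNeutralVariant:
    """A human->homolog substitution with its filter outcomes.

    ``contacts_ok`` may be None when the position could not be resolved in
    the structure (reason recorded); such candidates are never accepted.
    """

    variant: Variant
    subject_id: str
    source_identity: float
    column: int
    flank_ok: Optional[bool] = None
    gap_ok: Optional[bool] = None
    contacts_ok: Optional[bool] = None
    reason: Optional[str] = None

    @property
    def accepted_filters(self) -> bool:
        return bool(self.flank_ok) and bool(self.gap_ok) and bool(self.contacts_ok)


def extract_substitutions(pair: AlignedPair) -> List[CandidateNeutralVariant]:
    """One candidate per column where both rows hold residues and they differ.

    Insertions/deletions are not substitutions and are skipped.  Positions
    are 1-based ungapped query coordinates; filter fields are left unset.
    """
    pid = percent_identity(pair)
    out: List[CandidateNeutralVariant] = []
    qpos = 0
    for col, (q, s) in enumerate(zip(pair.query_row, pair.subject_row)):
        if q != GAP:
            qpos += 1
        if q == GAP or s == GAP or q == s:
            continue
        variant = Variant(q, qpos, s, NumberingScheme.MATURE)
        out.append(CandidateNeutralVariant(variant, pair.subject_id, pid, col))
    return out


def flank_conserved(pair: AlignedPair, column: int, k: int = 2) -> bool:
    """True iff the ``k`` columns on each side all hold identical residues.

    Columns running off either alignment end count as not conserved; a gap
    in a flank column is not a conserved residue.
    """
    n = len(pair)
    for off in range(1, k + 1):
        for col in (column - off, column + off):
            if col < 0 or col >= n:
                return False
            q, s = pair.query_row[col], pair.subject_row[col]
            if q == GAP or s == GAP or q != s:
                return False
    return True


def gap_ok(pair: AlignedPair, column: int, window: int = 3) -> bool:
    """True iff neither row has a gap within ``window`` columns of ``column``."""
    lo = max(0, column - window)
    hi = min(len(pair), column + window + 1)
    segment_q = pair.query_row[lo:hi]
    segment_s = pair.subject_row[lo:hi]
    return GAP not in segment_q and GAP not in segment_s


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactMap:
    """Residue-residue contacts at an atomic distance cutoff (strict less-than).

    ``contacts`` maps a residue position to the set of positions with at
    least one atom pair closer than ``cutoff``; every resolved residue has
    an entry (possibly empty).  Symmetric and irreflexive by construction.
    """

    cutoff: float
    contacts: Mapping[int, FrozenSet[int]]

    def __post_init__(self) -> None:
        for i, nbrs in self.contacts.items():
            if i in nbrs:
                raise StructureError(f"residue {i} listed as its own contact")
            for j in nbrs:
                if i not in self.contacts.get(j, frozenset()):
                    raise StructureError(f"asymmetric contact {i}->{j}")

    @property
    def positions(self) -> FrozenSet[int]:
        return frozenset(self.contacts)

    def neighbors(self, position: int) -> FrozenSet[int]:
        try:
            return self.contacts[position]
        except KeyError:
            raise ResidueNotResolvableError(
                f"position {position} not resolved in the structure"
            ) from None


def _highest_occupancy_atoms(res: gemmi.Residue) -> List[gemmi.Atom]:
    """Collapse alternate locations to the highest-occupancy atom per name."""
    best: Dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def _polymer_residues(structure: gemmi.Structure, chain: Optional[str]) -> List[Tuple[int, str, List[gemmi.Atom]]]:
    """Amino-acid residues of one chain of the first model.

    Returns (author residue number, one-letter code, atoms) triples; waters
    and non-amino-acid hetero residues are dropped.
    """
    if len(structure) == 0:
        raise StructureError("structure has no models")
    model = structure[0]
    names = [ch.name for ch in model]
    if chain is None:
        selected = None
        for ch in model:
            if any(_is_amino(res) for res in ch):
                selected = ch
                break
        if selected is None:
            raise StructureError("no chain with amino-acid residues")
    else:
        matches = [ch for ch in model if ch.name == chain]
        if not matches:
            raise StructureError(f"chain {chain!r} not found (have {names})")
        selected = matches[0]
    out = []
    for res in selected:
        if not _is_amino(res):
            continue
        atoms = _highest_occupancy_atoms(res)
        if atoms:
            out.append((res.seqid.num, _one_letter(res.name), atoms))
    if len(out) < 2:
        raise StructureError("fewer than two amino-acid residues with atoms")
    return out


def _is_amino(res: gemmi.Residue) -> bool:
    if res.is_water():
        return False
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    code = info.one_letter_code.upper() if info else "X"
    return code if code in AMINO_ACIDS else "X"


def _load_structure(structure: Union[gemmi.Structure, str, Path]) -> gemmi.Structure:
    if isinstance(structure, gemmi.Structure):
        return structure
    return gemmi.read_structure(str(structure))


def contact_map(
    structure: Union[gemmi.Structure, str, Path],
    cutoff: float = 5.0,
    chain: Optional[str] = None,
) -> ContactMap:
    """Residue contact map at a strict atomic distance cutoff (default 5 Å).

    Two residues are in contact when any inter-residue atom pair is closer
    than ``cutoff``.  All atoms of each amino-acid residue count (backbone
    included, sequence neighbours not excluded); only the first model and
    one chain are used.  Keys are author residue numbers.
    """
    st = _load_structure(structure)
    residues = _polymer_residues(st, chain)
    coords = []
    owner = []
    keys = []
    for idx, (num, _aa, atoms) in enumerate(residues):
        keys.append(num)
        for atom in atoms:
            coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
            owner.append(idx)
    pts = np.asarray(coords)
    owner_arr = np.asarray(owner)
    tree = cKDTree(pts)
    neighbor_sets: Dict[int, set] = {num: set() for num in keys}
    for a, b in tree.query_pairs(cutoff):
        ia, ib = owner_arr[a], owner_arr[b]
        if ia == ib:
            continue
        # query_pairs uses <=; enforce the strict less-than contact rule
        if np.linalg.norm(pts[a] - pts[b]) < cutoff:
            neighbor_sets[keys[ia]].add(keys[ib])
            neighbor_sets[keys[ib]].add(keys[ia])
    return ContactMap(cutoff, {k: frozenset(v) for k, v in neighbor_sets.items()})


def contact_map_for_query(
    structure: Union[gemmi.Structure, str, Path],
    query: ReferenceSequence,
    cutoff: float = 5.0,
    chain: Optional[str] = None,
) -> ContactMap:
    """Contact map re-keyed to 1-based positions of the query sequence.

    Author residue numbering is used directly when it is consistent with
    the query (at least 90% of numbered residues match the query residue at
    that position); otherwise the structure-derived sequence is globally
    aligned to the query and positions mapped through the alignment.
    Structure residues that map to no query position are dropped.
    """
    st = _load_structure(structure)
    residues = _polymer_residues(st, chain)
    raw = contact_map(st, cutoff, chain)

    n = len(query)
    numbered = [(num, aa) for num, aa, _atoms in residues]
    in_range = [(num, aa) for num, aa in numbered if 1 <= num <= n]
    agree = sum(1 for num, aa in in_range if query.residues[num - 1] == aa)
    if in_range and agree / len(in_range) >= 0.9:
        mapping = {num: num for num, _aa in in_range}
    else:
        seq = "".join(aa for _num, aa in numbered)
        aligned = align_homolog(query, seq, subject_id="structure")
        # structure residue index (0-based along seq) -> query position
        mapping = {}
        sidx = 0
        qpos = 0
        for q, s in zip(aligned.query_row, aligned.subject_row):
            if q != GAP:
                qpos += 1
            if s != GAP:
                if q != GAP:
                    mapping[numbered[sidx][0]] = qpos
                sidx += 1
    remapped: Dict[int, set] = {}
    for num, nbrs in raw.contacts.items():
        if num not in mapping:
            continue
        remapped[mapping[num]] = {mapping[j] for j in nbrs if j in mapping}
    return ContactMap(cutoff, {k: frozenset(v) for k, v in remapped.items()})


def contacts_conserved(pair: AlignedPair, variant_position: int, cmap: ContactMap) -> bool:
    """True iff every 3D contact of the variant residue is identical in the homolog.

    A contact residue aligned to a gap, or aligned to a different residue,
    breaks conservation; an isolated residue passes vacuously.  A position
    absent from the contact map raises :class:`ResidueNotResolvableError`.
    """
    for contact_pos in cmap.neighbors(variant_position):
        try:
            col = pair.column_of_query_position(contact_pos)
        except AlignmentError:
            return False  # contact residue outside the aligned region
        q, s = pair.query_row[col], pair.subject_row[col]
        if s == GAP or q != s:
            return False
    return True


# ---------------------------------------------------------------------------
# Alignment of unaligned homologs
# ---------------------------------------------------------------------------

def align_homolog(
    query: Union[ReferenceSequence, str],
    subject: str,
    subject_id: str = "subject",
    query_id: Optional[str] = None,
) -> AlignedPair:
    """Global affine-gap alignment (BLOSUM62, open -11 / extend -1)."""
    if isinstance(query, ReferenceSequence):
        qseq, qid = query.residues, query.id
    else:
        qseq, qid = query, query_id or "query"
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    aln = aligner.align(qseq, subject)[0]
    qrow, srow = str(aln[0]), str(aln[1])
    return AlignedPair(query_id or qid, subject_id, qrow, srow)


# ---------------------------------------------------------------------------
# Neutral-set construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkConfig:
    """Filter settings; the defaults are the standard pipeline values."""

    identity_min: float = 90.0  # strict greater-than
    flank_k: int = 2
    gap_window: int = 3
    contact_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.identity_min <= 100):
            raise AlignmentError(f"identity_min {self.identity_min} outside [0, 100]")
        if self.flank_k < 0 or self.gap_window < 0 or self.contact_cutoff <= 0:
            raise AlignmentError("flank_k/gap_window must be >= 0 and contact_cutoff > 0")


def evaluate_candidates(
    pairs: Sequence[AlignedPair],
    cmap: ContactMap,
    config: BenchmarkConfig = BenchmarkConfig(),
) -> List[CandidateNeutralVariant]:
    """All substitutions from all pairs with their three filter outcomes filled in.

    Candidates whose position is missing from the structure get
    ``contacts_ok=None`` with a reason; they can never be accepted.
    """
    out: List[CandidateNeutralVariant] = []
    for pair in pairs:
        for cand in extract_substitutions(pair):
            fl = flank_conserved(pair, cand.column, config.flank_k)
            gp = gap_ok(pair, cand.column, config.gap_window)
            try:
                ct: Optional[bool] = contacts_conserved(pair, cand.variant.position, cmap)
                reason = None
            except ResidueNotResolvableError as exc:
                ct = None
                reason = str(exc)
                logger.warning("candidate %s dropped: %s", cand.variant, exc)
            out.append(replace(cand, flank_ok=fl, gap_ok=gp, contacts_ok=ct, reason=reason))
    return out


def build_neutral_set(
    query: ReferenceSequence,
    pairs: Sequence[AlignedPair],
    structure: Union[gemmi.Structure, ContactMap, str, Path],
    config: BenchmarkConfig = BenchmarkConfig(),
    chain: Optional[str] = None,
    return_all: bool = False,
):
    """Construct the accepted neutral-variant set from pairwise alignments.

    For every distinct (ref, position, alt) substitution the record from the
    highest-identity pair is kept (closest homolog first; ties broken by the
    lexicographically smaller subject id), then accepted iff its source
    identity strictly exceeds ``config.identity_min`` and all three filters
    pass.  Output is sorted by position, then alternate residue.

    ``structure`` may be a ready-made :class:`ContactMap` keyed to query
    positions, or a structure/path from which one is built.  With
    ``return_all=True`` the full evaluated candidate list is returned too.
    """
    if not pairs:
        raise AlignmentError("no aligned pairs supplied")
    if isinstance(structure, ContactMap):
        cmap = structure
    else:
        cmap = contact_map_for_query(structure, query, config.contact_cutoff, chain)
    candidates = evaluate_candidates(pairs, cmap, config)

    best: Dict[Tuple[str, int, str], CandidateNeutralVariant] = {}
    for cand in candidates:
        key = (cand.variant.ref_aa, cand.variant.position, cand.variant.alt_aa)
        prev = best.get(key)
        if prev is None or (cand.source_identity, _neg_id(cand)) > (prev.source_identity, _neg_id(prev)):
            best[key] = cand
    accepted = [
        c for c in best.values()
        if c.source_identity > config.identity_min and c.accepted_filters
    ]
    accepted.sort(key=lambda c: (c.variant.position, c.variant.alt_aa, c.variant.ref_aa))
    if return_all:
        return accepted, candidates
    return accepted


class _neg_id:
    """Ordering helper: smaller subject_id wins, so invert the comparison."""

    def __init__(self, cand: CandidateNeutralVariant) -> None:
        self.sid = cand.subject_id

    def __lt__(self, other: "_neg_id") -> bool:
        return self.sid > other.sid

    def __gt__(self, other: "_neg_id") -> bool:
        return self.sid < other.sid

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_id) and self.sid == other.sid
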