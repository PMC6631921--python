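"""Protein-level missense variant parsing, renumbering and validation.

Clinical reports for alpha-1 antitrypsin (AAT, the SERPINA1 gene product)
describe substitutions against two coordinate systems: *mature* numbering,
which starts at the first residue of the secreted protein, and *precursor*
numbering, which includes the signal peptide (24 residues for AAT).  A
precursor position equals the mature position plus the signal-peptide
length.  This module parses variant strings such as ``E342K`` (tolerating
internal whitespace, e.g. ``M385 T`` as printed in some tables), converts
between the two numbering schemes, and checks a variant's reference residue
against a reference sequence.

Only protein-level single-residue substitutions (and stop gains written
with ``X``) are in scope.  Nucleotide-level HGVS, frameshift and splice
notations are rejected with :class:`VariantParseError`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "STOP_SYMBOL",
    "SIGNAL_PEPTIDE_LEN",
    "NumberingScheme",
    "Variant",
    "ReferenceSequence",
    "VariantError",
    "VariantParseError",
    "VariantValidationError",
    "SignalPeptideError",
    "PositionOutOfRangeError",
    "parse_variant",
    "format_variant",
    "convert_numbering",
    "validate_against_reference",
    "read_fasta",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Symbol accepted for a stop gain (e.g. ``Q156X``).  Stop gains parse but
#: carry no predictor scores and are excluded from classification.
STOP_SYMBOL = "X"

#: Signal-peptide length of alpha-1 antitrypsin, the default offset between
#: precursor and mature numbering.  Override per protein via configuration.
SIGNAL_PEPTIDE_LEN = 24


class VariantError(ValueError):
    """Base class for variant-related errors."""


class VariantParseError(VariantError):
    """The text is not a parseable single-residue substitution."""


class VariantValidationError(VariantError):
    """The parsed fields violate a Variant invariant."""


class SignalPeptideError(VariantError):
    """Precursor position lies inside the signal peptide; no mature equivalent."""


class PositionOutOfRangeError(VariantError, IndexError):
    """Variant position beyond the reference sequence length."""


class NumberingScheme(str, Enum):
    MATURE = "mature"
    PRECURSOR = "precursor"


@dataclass(frozen=True)
class Variant:
    """A single-residue protein substitution in an explicit numbering scheme.

    Invariants (enforced at construction): ``ref_aa != alt_aa``; position is
    a positive 1-based residue index; ``ref_aa`` is a standard amino acid and
    ``alt_aa`` is a standard amino acid or the stop symbol ``X``.
    """

    ref_aa: str
    position: int
    alt_aa: str
    scheme: NumberingScheme = NumberingScheme.MATURE

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS:
            raise VariantValidationError(
                f"reference residue {self.ref_aa!r} is not a standard amino acid"
            )
        if self.alt_aa not in AMINO_ACIDS and self.alt_aa != STOP_SYMBOL:
            raise VariantValidationError(
                f"alternate residue {self.alt_aa!r} is not a standard amino acid or '{STOP_SYMBOL}'"
            )
        if self.ref_aa == self.alt_aa:
            raise VariantValidationError(
                f"reference and alternate residues are identical ({self.ref_aa}{self.position}{self.alt_aa})"
            )
        if not isinstance(self.position, int) or self.position < 1:
            raise VariantValidationError(f"position must be a positive integer, got {self.position!r}")
        if not isinstance(self.scheme, NumberingScheme):
            object.__setattr__(self, "scheme", NumberingScheme(self.scheme))

    @property
    def is_stop_gain(self) -> bool:
        return self.alt_aa == STOP_SYMBOL

    def __str__(self) -> str:
        return format_variant(self)


@dataclass(frozen=True)
class ReferenceSequence:
    """A protein sequence with a stated numbering scheme (1-based)."""

    id: str
    residues: str
    scheme: NumberingScheme = NumberingScheme.MATURE

    def __post_init__(self) -> None:
        if not self.residues:
            raise VariantValidationError("reference sequence is empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise VariantValidationError(f"non-standard residues in reference sequence: {sorted(bad)}")
        if not isinstance(self.scheme, NumberingScheme):
            object.__setattr__(self, "scheme", NumberingScheme(self.scheme))

    def __len__(self) -> int:
        return len(self.residues)


_VARIANT_RE = re.compile(
    r"^\s*([A-Za-z])\s*(\d+)\s*([A-Za-z])\s*(\[[^\]]*\])?\s*$"
)


def parse_variant(text: str, scheme: Union[NumberingScheme, str] = NumberingScheme.MATURE) -> Variant:
    """Parse a substitution string like ``E342K`` into a :class:`Variant`.

    Internal whitespace between position and alternate residue is tolerated
    (tables sometimes print ``M385 T``).  A trailing bracketed annotation
    containing the word "precursor" (e.g. ``I9N [includes precursor]``)
    switches the scheme to precursor, as does ``scheme="precursor"``.

    Frameshift, splice-site and other nucleotide-level notations (e.g.
    ``A347fs``, ``917 + 1G > A``) raise :class:`VariantParseError`.
    """
    if not isinstance(text, str):
        raise VariantParseError(f"expected a string, got {type(text).__name__}")
    m = _VARIANT_RE.match(text)
    if m is None:
        raise VariantParseError(f"not a single-residue substitution: {text!r}")
    ref, pos, alt, annot = m.groups()
    sch = NumberingScheme(scheme)
    if annot and "precursor" in annot.lower():
        sch = NumberingScheme.PRECURSOR
    return Variant(ref.upper(), int(pos), alt.upper(), sch)


def format_variant(v: Variant) -> str:
    """Canonical ``<ref><pos><alt>`` writer (inverse of :func:`parse_variant`)."""
    return f"{v.ref_aa}{v.position}{v.alt_aa}"


def convert_numbering(
    v: Variant,
    to: Union[NumberingScheme, str],
    signal_peptide_len: int = SIGNAL_PEPTIDE_LEN,
) -> Variant:
    """Convert a variant between mature and precursor numbering.

    Mature -> precursor adds the signal-peptide length to the position;
    the reverse subtracts it.  Converting a precursor position that lies
    within the signal peptide (position <= signal_peptide_len) to mature
    numbering raises :class:`SignalPeptideError` — such residues have no
    mature-coordinate equivalent.
    """
    to = NumberingScheme(to)
    if v.scheme == to:
        return v
    if to == NumberingScheme.PRECURSOR:
        return replace(v, position=v.position + signal_peptide_len, scheme=to)
    if v.position <= signal_peptide_len:
        raise SignalPeptideError(
            f"{v} lies within the {signal_peptide_len}-residue signal peptide; "
            "no mature-numbering equivalent exists"
        )
    return replace(v, position=v.position - signal_peptide_len, scheme=to)


def validate_against_reference(v: Variant, ref: ReferenceSequence) -> bool:
    """True iff the reference residue at ``v.position`` (1-based) matches ``v.ref_aa``.

    The variant and reference must be in the same numbering scheme (convert
    first otherwise).  A position beyond the sequence raises
    :class:`PositionOutOfRangeError`, distinct from a residue mismatch.
    """
    if v.scheme != ref.scheme:
        raise VariantValidationError(
            f"scheme mismatch: variant is {v.scheme.value}, reference is {ref.scheme.value}"
        )
    if v.position > len(ref):
        raise PositionOutOfRangeError(
            f"position {v.position} beyond reference length {len(ref)}"
        )
    return ref.residues[v.position - 1] == v.ref_aa


def read_fasta(
    path: Union[str, Path],
    record_id: Optional[str] = None,
    scheme: Union[NumberingScheme, str] = NumberingScheme.MATURE,
) -> ReferenceSequence:
    """Read a reference sequence from FASTA.

    Uses the first record unless ``record_id`` is given.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise VariantValidationError(f"no FASTA records in {path}")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise VariantValidationError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    return ReferenceSequence(rec.id, str(rec.seq).upper(), NumberingScheme(scheme))
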