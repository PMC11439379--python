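"""Canonical peptide representation, validation and provenance bookkeeping.

Peptides are short (here typically 24–26 residue) sequences over the 20
standard amino acids. Every other module consumes the :class:`Peptide` type
defined here; validation happens once, at parse time. Positions are 1-based
everywhere a position crosses the API surface, matching how substitutions
are written in the peptide literature (e.g. "p22 T>R").
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD20 = "ACDEFGHIKLMNPQRSTVWY"

#: The 18 residues actually enumerated in some peptide-design protocols that
#: nominally use "twenty amino acids" (isoleucine and valine omitted).
PAPER18 = "ARNDCQEGHLKMFPSTWY"


class InvalidResidueError(ValueError):
    """Raised when a sequence contains a character outside the standard 20."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position  # 1-based
        super().__init__(
            f"invalid residue {residue!r} at position {position} "
            f"(allowed: {STANDARD20})"
        )


@dataclass(frozen=True)
class Substitution:
    """A single-residue substitution record: ``parent`` position ``original>replacement``."""

    parent_id: str
    position: int  # 1-based
    original: str
    replacement: str

    def apply(self, parent_sequence: str) -> str:
        """Apply this substitution to the parent sequence, with consistency checks."""
        if not (1 <= self.position <= len(parent_sequence)):
            raise IndexError(
                f"substitution position {self.position} outside 1..{len(parent_sequence)}"
            )
        i = self.position - 1
        if parent_sequence[i] != self.original:
            raise ValueError(
                f"parent has {parent_sequence[i]!r} at position {self.position}, "
                f"substitution record says {self.original!r}"
            )
        return parent_sequence[:i] + self.replacement + parent_sequence[i + 1 :]

    def label(self) -> str:
        return f"parent={self.parent_id} pos={self.position} {self.original}>{self.replacement}"


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with an identifier and optional provenance."""

    id: str
    sequence: str
    provenance: Substitution | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet (subset of the standard 20, no duplicates)."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError(f"alphabet {self.name!r} has duplicate residues")
        bad = set(self.residues) - set(STANDARD20)
        if bad:
            raise ValueError(f"alphabet {self.name!r} has non-standard residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __contains__(self, residue: str) -> bool:
        return residue in self.residues


STANDARD_ALPHABET = Alphabet("standard20", STANDARD20)
PAPER_ALPHABET = Alphabet("paper18", PAPER18)

ALPHABETS = {a.name: a for a in (STANDARD_ALPHABET, PAPER_ALPHABET)}


def get_alphabet(name: str) -> Alphabet:
    try:
        return ALPHABETS[name]
    except KeyError:
        raise KeyError(f"unknown alphabet {name!r}; known: {sorted(ALPHABETS)}") from None


def parse_peptide(id: str, raw: str, provenance: Substitution | None = None) -> Peptide:
    """Validate and normalise a raw sequence into a :class:`Peptide`.

    Whitespace is stripped, case is folded to upper. Any character outside
    the 20 standard one-letter codes raises :class:`InvalidResidueError`
    naming the character and its 1-based position. Ambiguity codes
    (B, J, O, U, X, Z) are rejected, not coerced.
    """
    seq = "".join(raw.split()).upper()
    if not seq:
        raise ValueError(f"peptide {id!r}: empty sequence")
    for i, ch in enumerate(seq, start=1):
        if ch not in STANDARD20:
            raise InvalidResidueError(ch, i)
    if provenance is not None:
        # invariant: provenance must reproduce this sequence from its parent
        if seq[provenance.position - 1] != provenance.replacement:
            raise ValueError(
                f"peptide {id!r}: provenance says {provenance.replacement!r} at "
                f"position {provenance.position}, sequence has "
                f"{seq[provenance.position - 1]!r}"
            )
    return Peptide(id=id, sequence=seq, provenance=provenance)


def residue_counts(p: Peptide | str) -> Counter:
    """Residue → count mapping; counts always sum to the sequence length."""
    seq = p.sequence if isinstance(p, Peptide) else p
    return Counter(seq)


_PROVENANCE_RE = re.compile(
    r"parent=(?P<parent>\S+)\s+pos=(?P<pos>\d+)\s+(?P<orig>[A-Z])>(?P<sub>[A-Z])"
)


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides to FASTA; provenance goes on the description line."""
    records = []
    for p in peptides:
        desc = p.provenance.label() if p.provenance else ""
        records.append(SeqRecord(Seq(p.sequence), id=p.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read a peptide FASTA, recovering any provenance from description lines."""
    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        prov = None
        m = _PROVENANCE_RE.search(rec.description)
        if m:
            prov = Substitution(
                parent_id=m["parent"],
                position=int(m["pos"]),
                original=m["orig"],
                replacement=m["sub"],
            )
        peptides.append(parse_peptide(rec.id, str(rec.seq), provenance=prov))
    return peptides
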