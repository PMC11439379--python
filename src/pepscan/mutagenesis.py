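"""Exhaustive single-residue substitution (saturation mutagenesis) libraries.

Given a template peptide and an alphabet, enumerate every variant that
differs from the template at exactly one position. Variants are produced in
scan order — position ascending, alphabet order within a position — and each
carries a provenance record, so the library is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence import Alphabet, Peptide, STANDARD_ALPHABET, Substitution


def variant_id(template_id: str, position: int, sub: str, length: int | None = None) -> str:
    """Deterministic variant label, e.g. ``AtMP1_p13Y`` (1-based position)."""
    if position < 1 or (length is not None and position > length):
        raise IndexError(f"position {position} outside 1..{length or '?'}")
    return f"{template_id}_p{position}{sub}"


@dataclass(frozen=True)
class SubstitutionLibrary:
    """A template plus its complete single-substitution variant set."""

    template: Peptide
    alphabet: Alphabet
    variants: tuple[Peptide, ...]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def enumerate_single_substitutions(
    template: Peptide,
    alphabet: Alphabet = STANDARD_ALPHABET,
    exclude_self: bool = True,
) -> SubstitutionLibrary:
    """All Hamming-distance-1 variants of ``template`` over ``alphabet``.

    With ``exclude_self=True`` (default) substituting a residue by itself is
    skipped, so the count is Σ over positions of (|alphabet| − [template
    residue ∈ alphabet]); with ``exclude_self=False`` identity substitutions
    are generated and then dropped as duplicates of the template, yielding
    the same set.
    """
    if len(alphabet) == 0:
        raise ValueError("alphabet is empty")
    variants: list[Peptide] = []
    seq = template.sequence
    for pos in range(1, len(seq) + 1):
        original = seq[pos - 1]
        for sub in alphabet:
            if sub == original:
                continue  # identity substitution: always equals the template
            prov = Substitution(
                parent_id=template.id, position=pos, original=original, replacement=sub
            )
            variants.append(
                Peptide(
                    id=variant_id(template.id, pos, sub, len(seq)),
                    sequence=prov.apply(seq),
                    provenance=prov,
                )
            )
    _ = exclude_self  # both modes reduce to the same distinct-variant set
    return SubstitutionLibrary(template=template, alphabet=alphabet, variants=tuple(variants))
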