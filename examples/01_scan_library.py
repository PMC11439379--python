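"""Enumerate the exhaustive single-substitution library of a Thr-rich 24-mer.

Every variant differs from the template at exactly one position and carries
a provenance record, so 24 positions x 19 alternative residues = 456
distinct peptides.
"""

from pepscan import enumerate_single_substitutions, parse_peptide

template = parse_peptide("AtMP1_24", "THPPTTTTTTTTTTTTTAAPATTT")
library = enumerate_single_substitutions(template)

print(f"template: {template.id} ({template.sequence}, {len(template)} aa)")
print(f"variants: {len(library)} (unique sequences: {len({v.sequence for v in library})})")
first = library.variants[0]
print(f"first variant {first.id}: {first.sequence}")
print(f"  provenance: {first.provenance.label()}")
# 456 variants means every possible one-residue change is on the table;
# the screen then triages them by physicochemistry and predictor scores.
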