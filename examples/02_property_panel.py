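"""Compute the full physicochemical panel for the two selected candidates.

The two fixed-contribution charge conventions differ only in the histidine
weight (+0.25 vs +0.5); the isoelectric point comes from bisection on the
Henderson-Hasselbalch net-charge curve with the calibrated pKa set.
"""

from pepscan import parse_peptide, property_panel

for name, seq in [
    ("ATMP5", "THPPTTTTTTTTTTTYTAAPATTT"),
    ("ATMP6", "THPPTTTTTTTTTTTTTAAPARTT"),
]:
    p = property_panel(parse_peptide(name, seq))
    print(f"{name}: length={p.length}")
    print(f"  net charge  quarter={p.net_charge_quarter:+.2f}  "
          f"integer-plus-half={p.net_charge_anticp:+.2f}  "
          f"Henderson-Hasselbalch(pH 7)={p.net_charge_hh:+.2f}")
    print(f"  pI={p.pI:.2f}  GRAVY={p.gravy:.2f}  "
          f"hydrophobic={p.hydrophobic_percent_rounded}%")
    print(f"  MW={p.molecular_weight:.2f} Da  instability={p.instability_index:.2f}  "
          f"aliphatic={p.aliphatic_index:.1f}")
# Negative GRAVY marks both candidates as hydrophilic; the Arg-bearing one
# is the more cationic (+1.25 / +1.50) with a correspondingly basic pI.
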