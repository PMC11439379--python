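"""Run the staged selection funnel over the ten screened variants.

Scores are transcribed predictor outputs: all ten are AMP-positive; only
the two final candidates carry anticancer scores above the 0.5 threshold.
The funnel applies AMP status, the charge window (0, +9], the hydrophobic
window [13%, 50%] and the anticancer threshold, then ranks the survivors.
"""

import dataclasses

from pepscan import (
    PAPER_SELECTED,
    ScoreRecord,
    build_score_table,
    funnel_summary,
    parse_peptide,
    property_panel,
    run_cascade,
)

VARIANTS = [
    ("seq_3541", "THPPTTTTTTTTYTTTTAAPATTT", 0.30),
    ("seq_3577", "THPPTTTTTTTTTYTTTAAPATTT", 0.30),
    ("seq_3628", "THPPTTTTTTTTTHTTTAAPATTT", 0.30),
    ("seq_3668", "THPPTTTTTTTTTTHTTAAPATTT", 0.30),
    ("seq_3690", "THPPTTTTTTTTKTTTTAAPATTT", 0.30),
    ("seq_3712", "THPPTTTTTTTTTKTTTAAPATTT", 0.30),
    ("seq_3738", "THPPTTTTTTTTTTTTTAAPATTK", 0.30),
    ("seq_3760", "THPPTTTTTTTTTTTYTAAPATTT", 0.57),  # ATMP5
    ("seq_3785", "THPPTTTTTTTTTTTTTAAPAKTT", 0.30),
    ("seq_3833", "THPPTTTTTTTTTTTTTAAPARTT", 0.59),  # ATMP6
]

peptides = [parse_peptide(pid, seq) for pid, seq, _ in VARIANTS]
scores = build_score_table(
    [ScoreRecord(id=pid, amp_flag="AMP", anticancer_score=s, source="transcribed")
     for pid, _, s in VARIANTS],
    source="transcribed",
)
panels = {p.id: property_panel(p) for p in peptides}
criteria = dataclasses.replace(PAPER_SELECTED, top_k=2)
result = run_cascade([p.id for p in peptides], panels, scores, criteria)
print(funnel_summary(result))
# All ten clear the AMP, charge and hydrophobicity stages; the anticancer
# threshold keeps only the two scored candidates, the 0.59 scorer first.
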