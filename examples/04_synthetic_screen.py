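"""A fully synthetic end-to-end screen: seeded library, scores, funnel.

No external predictor output is needed: the generator draws Thr-rich
24-mers and predictor-shaped scores (AMP ~ Bernoulli(0.505), anticancer ~
Beta(2, 6)), so every funnel stage is exercised reproducibly.
"""

from pepscan import (
    SyntheticSpec,
    funnel_summary,
    generate_library,
    generate_scores,
    property_panel,
    run_cascade,
)

spec = SyntheticSpec(seed=42, n_variants=456)
library = generate_library(spec)
scores = generate_scores(library, spec)
panels = {p.id: property_panel(p) for p in library}
result = run_cascade([p.id for p in library], panels, scores)
print(funnel_summary(result))
print(f"survivors: {len(result.survivors)} of {len(library)}")
# Roughly half fall at the AMP stage (rate 0.505); the charge and
# hydrophobicity windows prune peptides whose random composition lacks a
# basic residue or carries <13% hydrophobics; few Beta(2,6) scores reach 0.5.
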