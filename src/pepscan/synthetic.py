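"""Seeded synthetic peptide libraries and predictor score tables.

Real screens consume score tables exported from external web predictors;
those outputs are not redistributable, so this module generates libraries
and score tables with the same statistical shape, letting every funnel
stage be exercised end-to-end with no downloads.

What is emulated: a low-complexity Thr-rich composition (matching the kind
of template the screen mutates), an AMP-positive rate near one half (about
half of a saturation library typically fails the AMP call), a right-skewed
anticancer score distribution with little mass above the 0.5 decision
threshold, and Bernoulli toxicity/allergenicity flags. What is *not*
emulated: any sequence–score dependence — synthetic scores are independent
of the sequences, unlike real predictors.

All randomness flows through one ``numpy`` generator constructed from the
mandatory seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .predictors import ScoreRecord, ScoreTable, build_score_table
from .sequence import Peptide, STANDARD20

#: Thr-rich default composition mirroring a 24-mer with 16 T, 3 P, 3 A, 1 H, 1 R.
THR_RICH = MappingProxyType({"T": 16.0, "P": 3.0, "A": 3.0, "H": 1.0, "R": 1.0})


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic screen; the seed is mandatory.

    Defaults mirror the study conditions this generator emulates: 24-residue
    Thr-rich peptides, a library the size of a 24 x 19 saturation scan, an
    AMP-positive rate of 0.505 (216 of 428 passing), and Beta(2, 6)
    anticancer scores, whose tail mass above 0.5 is ~6%.
    """

    seed: int
    length: int = 24
    composition: Mapping[str, float] = field(default_factory=lambda: THR_RICH)
    n_variants: int = 456
    amp_positive_rate: float = 0.505
    anticancer_beta_params: tuple[float, float] = (2.0, 6.0)
    toxic_rate: float = 0.10
    allergen_rate: float = 0.50

    def __post_init__(self) -> None:
        for name in ("amp_positive_rate", "toxic_rate", "allergen_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} {v} outside [0, 1]")
        a, b = self.anticancer_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.length < 1 or self.n_variants < 0:
            raise ValueError("length must be >= 1 and n_variants >= 0")
        bad = set(self.composition) - set(STANDARD20)
        if bad:
            raise ValueError(f"composition has non-standard residues {sorted(bad)}")
        if not self.composition or sum(self.composition.values()) <= 0:
            raise ValueError("composition weights must have positive total")
        object.__setattr__(self, "composition", MappingProxyType(dict(self.composition)))


def _rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def generate_library(spec: SyntheticSpec) -> list[Peptide]:
    """Draw ``n_variants`` peptides i.i.d. from the composition bias."""
    rng = _rng(spec)
    residues = sorted(spec.composition)
    weights = np.array([spec.composition[r] for r in residues], dtype=float)
    probs = weights / weights.sum()
    width = len(str(max(spec.n_variants, 1)))
    peptides = []
    for i in range(spec.n_variants):
        seq = "".join(rng.choice(residues, size=spec.length, p=probs))
        peptides.append(Peptide(id=f"syn_{i + 1:0{width}d}", sequence=seq))
    return peptides


def generate_scores(library: list[Peptide], spec: SyntheticSpec) -> ScoreTable:
    """Per-peptide synthetic predictor outputs, deterministic per seed.

    AMP status ~ Bernoulli(amp_positive_rate), anticancer score ~ Beta(a, b),
    toxicity and allergen flags ~ Bernoulli of their rates. Scores are drawn
    independently of the sequences.
    """
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from the library
    n = len(library)
    amp = rng.random(n) < spec.amp_positive_rate
    a, b = spec.anticancer_beta_params
    anticancer = rng.beta(a, b, size=n)
    toxic = rng.random(n) < spec.toxic_rate
    allergen = rng.random(n) < spec.allergen_rate
    records = [
        ScoreRecord(
            id=p.id,
            amp_flag="AMP" if amp[i] else "non-AMP",
            anticancer_score=float(anticancer[i]),
            toxicity_flag="toxic" if toxic[i] else "non-toxic",
            allergen_flag="allergen" if allergen[i] else "non-allergen",
            source="synthetic",
        )
        for i, p in enumerate(library)
    ]
    return build_score_table(records, source="synthetic")
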