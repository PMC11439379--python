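# Methods

## Scope and model

pepscan implements the deterministic half of an in-silico directed-evolution
screen for short cationic peptides: saturation mutagenesis of a template,
per-peptide physicochemistry, and a staged triage funnel. The stochastic
half — trained AMP/anticancer/toxicity/allergenicity predictors — is out of
scope by design; their value lies in trained weights that cannot be
reproduced from formulas, so the package ingests their exported score
tables (or generates synthetic stand-ins) instead of imitating them.

## Mutagenesis

A single-substitution library over a template of length `L` and alphabet of
size `k` contains exactly `Σ_positions (k − [template residue ∈ alphabet])`
distinct variants — `L × (k − 1)` when the alphabet contains every template
residue. Identity substitutions reproduce the template and are excluded;
the `exclude_self` flag exists for API fidelity but both settings yield the
same distinct-variant set. Variants are emitted in scan order (position
ascending, alphabet order within a position) with 1-based positions on
every external surface. Two alphabets ship: `standard20`, the default, and
`paper18` (the 20 standard residues minus Ile and Val), because screening
protocols sometimes enumerate an 18-letter "set of twenty"; screens with
either are supported, and library sizes are always reported, never assumed.

## Charge conventions

Screening tables print fixed-contribution net charges under conventions
that differ only in the histidine weight. Both are implemented exactly
(rational arithmetic, so +1.25 is +1.25, not 1.2500000000000002):

| convention | K/R | D/E | H | termini |
|---|---|---|---|---|
| `quarter_ph7` | +1 | −1 | +0.25 | cancel |
| `anticp_integer` | +1 | −1 | +0.50 | cancel |

The +0.25 histidine weight is the Henderson–Hasselbalch His fraction at
pH 7 (pKa ≈ 6.5) rounded to quarters. The funnel defaults to
`quarter_ph7`, the convention of the tables screening funnels are usually
run on; the convention in force is echoed in every run log because the
coexistence of the two is the main reproducibility hazard in this kind of
screen.

The continuous model is the standard Henderson–Hasselbalch sum over
ionizable groups (N-terminus, H, K, R positive; C-terminus, D, E, C, Y
negative). It is strictly decreasing in pH — each term is — which
guarantees a unique root; the isoelectric point solver is plain bisection
on (0, 14) to a configurable tolerance (default 1e-4 pH units).

## pKa sets

Published pKa sets disagree by up to a pH unit per group and single-peptide
web calculators rarely document theirs. Three sets ship as plain-text data
(`pepscan/data/pka_sets.tsv`): `emboss`, `lehninger`, and the default
`calibrated` set (N-terminus 7.7, C-terminus 3.55, D 4.05, E 4.45, C 9.0,
Y 10.0, H 6.5, K 10.0, R 12.5). The calibrated set was chosen once so that
the bisection pI of the two reference 24-mers (His/Tyr- and
His/Arg-containing Thr-rich peptides) lands at 7.10 and 10.11, matching the
values single-protein web calculators report for them; the arginine pKa of
12.5 (EMBOSS's value) is required for the basic peptide — at R = 12.0 its
pI drops to 9.86. The His/Tyr peptide's pI is insensitive to the arginine
value.

## Scales, rounding, degenerate inputs

- Hydropathy is fixed to Kyte–Doolittle; hydrophilicity defaults to
  Hopp–Woods; both ship as versioned TSVs and are cross-checked against
  Biopython's copies of the published tables in the test suite. Custom
  scales can be registered from two-column files.
- The hydrophobic set defaults to {A, C, F, I, L, M, V, W}: Gly and Pro are
  excluded as at best weakly hydrophobic, and this is the set under which a
  3-Ala 24-mer reports 12.5% → 13%, the behaviour screening tables show.
- Percents round half-up to integers and reported means/charges to two
  decimals, matching table precision; internal values are full precision.
- Molecular weight uses standard average residue masses plus one water.
  The instability index uses the published 400-entry Guruprasad DIWV
  dipeptide table (taken from Biopython's data module rather than
  re-transcribed) and requires length ≥ 2; length-1 peptides raise.
- Sequences are validated once at parse time: uppercase, 20 standard
  residues only; ambiguity codes are rejected with the offending character
  and 1-based position.

## Funnel semantics

Stages apply conjunctively in a fixed default order — AMP status, charge,
hydrophobicity, anticancer — so per-stage exclusion counts are comparable
across runs; the order is configurable, and because the filters are
conjunctive the survivor *set* is order-invariant (a tested property).
Decisions at the edges:

- "Favourable" charge means strictly positive: the window is (0, +9], the
  lower edge exclusive, the upper inclusive.
- The hydrophobicity window is evaluated on the *rounded* integer percent,
  both edges inclusive. The default minimum is 13% (`paper-selected`
  preset) because screens select 13%-hydrophobic candidates even while
  quoting a 17–50% optimum; the stricter window ships as the
  `paper-optimal` preset.
- The anticancer threshold is ≥ 0.5: scores *below* the cut fail, so
  exactly 0.5 passes.
- Peptides missing an AMP call or anticancer score fail those stages as
  "unscored" — a defined degradation, recorded per peptide in the stage
  report, rather than an error.
- Ranking is by anticancer score descending, then net charge descending,
  then id ascending — a total, deterministic order.
- Toxicity and allergenicity are annotations on survivors, not filters;
  when sources disagree, the merge keeps every source's call under
  `per_source` and resolves the headline flag by explicit precedence.
  Multi-predictor AMP consensus defaults to majority (ties count as
  positive) since screening write-ups rarely state their reconciliation
  rule; `all` is available.

## Synthetic data

The generator emulates the statistical shape of a real screen's inputs so
the pipeline is testable offline: 24-residue peptides drawn i.i.d. from a
Thr-rich composition (weights 16 T : 3 P : 3 A : 1 H : 1 R, mirroring the
template family this screen targets), a library of 456 (the 24 × 19 scan
size), AMP calls ~ Bernoulli(0.505) (about half of a saturation library
fails the AMP call in practice), anticancer scores ~ Beta(2, 6) (right-
skewed, ~6% mass above the 0.5 threshold, emulating how few variants score
as anticancer), and Bernoulli toxicity (0.10) / allergenicity (0.50) flags.
What it does **not** emulate: any dependence of scores on sequence, real
predictors' correlations between endpoints, or the single-substitution
structure of a scan library (sequences are i.i.d. draws). Passing the
parameter-recovery tests therefore demonstrates that the funnel's
bookkeeping and thresholds behave correctly under known rates — not that
the synthetic peptides resemble real AMP sequence space.

All randomness flows through one `numpy` generator per call, constructed
from the mandatory seed (scores use seed + 1 so library and score streams
are independent); there is no global random state.

## Problem sizes and verification

Every published worked value asserted in the tests (charges, GRAVY,
percents, pI, funnel outcome) is a desk-scale computation over 24-mers and
runs in milliseconds. Property-based suites (hypothesis, derandomized)
check the structural invariants: enumeration counts vs brute force, charge
monotonicity in pH, the two-group closed-form pI, scale means vs an
independent summation oracle and Biopython's ProteinAnalysis, funnel
conservation and monotonicity under threshold relaxation, and end-to-end
parameter recovery on a 10,000-peptide synthetic screen (stage keep-rates
within 3 binomial standard errors of their expectations). The full suite
runs in a few seconds on one CPU.

## Known limitations

- The fixed-contribution conventions ignore composition context (termini,
  neighbouring charges) by construction; they reproduce screening tables,
  not solution chemistry.
- pI depends entirely on the pKa set; the calibrated default is tuned to
  two reference peptides and is not a general-purpose replacement for
  documented sets — use `emboss`/`lehninger` for comparability.
- Average (not monoisotopic) masses only; no PTMs, no non-proteinogenic
  residues, no structure-derived properties (helicity, amphipathic moment).
- External predictor scores are taken at face value; the package validates
  ranges and vocabulary, not scientific plausibility.
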