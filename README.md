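# pepscan

Desk-side tooling for directed-evolution screens of short peptides: given a
template antimicrobial peptide (AMP), enumerate every single-residue
substitution, compute the physicochemical panel screeners filter on, ingest
external predictor scores, and run a staged selection funnel down to a
ranked short-list of anticancer-peptide candidates.

It is written for peptide-engineering groups who run this kind of screen
through a patchwork of web servers (AMP databases, anticancer/toxicity/
allergenicity predictors, a property calculator) and want the deterministic
parts — library enumeration, physicochemistry, filtering, ranking,
bookkeeping — reproducible offline. The trained ML predictors themselves
are *not* reimplemented: their exported score tables are the interface.

## The model

For a template of length `L` over an alphabet of size `k`, saturation
(single-substitution) mutagenesis yields `L × (k − 1)` distinct variants,
each tracked with provenance `(parent, position, orig>sub)`.

Per peptide, the property engine computes from first principles:

- **Net charge, fixed conventions.** `z = Σ_r n_r · w_r` with `w_K = w_R = +1`,
  `w_D = w_E = −1`, and a histidine weight of `+0.25` (`quarter_ph7`, the
  Henderson–Hasselbalch His fraction at pH 7 rounded to quarters) or `+0.5`
  (`anticp_integer`); termini cancel. Both conventions circulate in AMP
  screening tables, so both are first-class.
- **Net charge, Henderson–Hasselbalch.**
  `z(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))`,
  including both termini, over a named pKa set.
- **Isoelectric point.** The unique root of `z(pH)` on (0, 14), found by
  bisection — `z` is strictly decreasing in pH, so the root exists and is
  unique for every peptide.
- **GRAVY** (mean Kyte–Doolittle hydropathy), mean **hydrophilicity**
  (Hopp–Woods by default), **hydrophobic percent** (fraction of residues in
  {A, C, F, I, L, M, V, W}, half-up integer rounding), average **molecular
  weight**, Guruprasad **instability index** (DIWV dipeptide weights) and
  **aliphatic index**.

The selection funnel applies conjunctive stages in order — AMP status,
net-charge window (0, +9], hydrophobic percent [13%, 50%], anticancer score
≥ 0.5 — with per-stage kept/excluded bookkeeping, then ranks survivors by
anticancer score, net charge, then id. A stricter 17–50% hydrophobicity
preset (`paper-optimal`) is also provided. A seeded synthetic generator
produces Thr-rich libraries and predictor-shaped score tables so the whole
pipeline is testable with no downloads.

## Worked example

```python
from pepscan import parse_peptide, property_panel

p = property_panel(parse_peptide("ATMP6", "THPPTTTTTTTTTTTTTAAPARTT"))
print(p.net_charge_quarter, p.net_charge_anticp, round(p.gravy, 2),
      round(p.pI, 2), p.hydrophobic_percent_rounded)
```

prints `1.25 1.5 -0.76 10.11 13`: this Arg-bearing 24-mer carries +1.25 e
under the quarter convention (+1.50 under the integer-plus-half one), is
hydrophilic overall (GRAVY −0.76), has a basic isoelectric point of 10.11
with the calibrated pKa set, and 3 of its 24 residues (13%) are
hydrophobic — inside the funnel's selection window.

Running the funnel over ten screened single-substitution variants with
transcribed predictor scores (`python examples/03_selection_funnel.py`):

```
amp             in=   10 kept=   10 excluded=    0  [classified AMP (flag, or probability >= 0.5)]
charge          in=   10 kept=   10 excluded=    0  [net charge (quarter_ph7) in (0.0, 9.0]]
hydrophobicity  in=   10 kept=   10 excluded=    0  [hydrophobic percent in [13, 50]]
anticancer      in=   10 kept=    2 excluded=    8  [anticancer score >= 0.5]
ranking: seq_3833 (score=0.59, charge=+1.25), seq_3760 (score=0.57, charge=+0.25)
```

Only the two variants with anticancer scores above 0.5 survive, the
0.59-scorer ranked first. The other `examples/` scripts cover library
enumeration, the full property panel and an end-to-end synthetic screen;
the same pipeline is scriptable via the thin `pepscan` CLI
(`scan`, `props`, `filter`, `rank`, `synth`, `run`).

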