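"""End-to-end pipeline (scan → props → filter → report) and run configuration.

A :class:`RunConfig` names every registry entry a run depends on (alphabet,
charge convention, pKa set, scales, filter thresholds) and round-trips
through YAML, so a run is reproducible from its config echo alone. The two
printed charge conventions are the main reproducibility hazard in this kind
of screen, so the run log records the exact convention and pKa set used.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cascade import (
    CascadeResult,
    FilterCriteria,
    PRESETS,
    funnel_report,
    funnel_summary,
    run_cascade,
)
from .mutagenesis import enumerate_single_substitutions
from .physchem import PanelConfig, PropertyPanel, property_panel
from .predictors import ScoreTable
from .sequence import Peptide, get_alphabet, write_fasta

logger = logging.getLogger(__name__)

#: PropertyPanel columns reported to 2 decimals in CSV output (table precision).
_TWO_DP = (
    "net_charge_quarter",
    "net_charge_anticp",
    "net_charge_hh",
    "pI",
    "gravy",
    "hydrophilicity",
    "molecular_weight",
    "instability_index",
    "aliphatic_index",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, by registry name; YAML round-trippable."""

    alphabet: str = "standard20"
    panel: PanelConfig = field(default_factory=PanelConfig)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    preset: str | None = None

    def resolved_criteria(self) -> FilterCriteria:
        return PRESETS[self.preset] if self.preset else self.criteria

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        panel = PanelConfig(**raw.pop("panel", {}))
        criteria = FilterCriteria(**raw.pop("criteria", {}))
        return cls(panel=panel, criteria=criteria, **raw)


def panels_frame(panels: list[PropertyPanel]) -> pd.DataFrame:
    """Property panels as a DataFrame with table-precision (2 dp) numeric columns."""
    df = pd.DataFrame([dataclasses.asdict(p) for p in panels])
    for col in _TWO_DP:
        df[col] = df[col].round(2)
    df["hydrophobic_fraction"] = df["hydrophobic_fraction"].round(4)
    return df


def run_pipeline(
    template: Peptide,
    config: RunConfig,
    scores: ScoreTable,
    out_dir: str | Path,
) -> CascadeResult:
    """Scan a template, compute panels, run the funnel, write all artifacts.

    Writes ``variants.fasta``, ``properties.csv``, ``funnel.csv``,
    ``selection.fasta`` and ``run.log`` (config echo plus funnel summary)
    into ``out_dir``. Re-running with identical inputs and config
    byte-reproduces the CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    library = enumerate_single_substitutions(template, get_alphabet(config.alphabet))
    peptides = [template, *library.variants]
    write_fasta(library.variants, out / "variants.fasta")

    panels = {p.id: property_panel(p, config.panel) for p in peptides}
    df = panels_frame(list(panels.values()))
    df.to_csv(out / "properties.csv", index=False)

    criteria = config.resolved_criteria()
    result = run_cascade([p.id for p in peptides], panels, scores, criteria)
    funnel_report(result).to_csv(out / "funnel.csv", index=False)

    by_id = {p.id: p for p in peptides}
    write_fasta([by_id[r.id] for r in result.final_ranking], out / "selection.fasta")

    (out / "run.log").write_text(
        "# pepscan run\n## config\n" + config.to_yaml() + "\n## funnel\n"
        + funnel_summary(result) + "\n"
    )
    logger.info(
        "pipeline: %d peptides -> %d survivors (convention=%s, pKa set=%s)",
        len(peptides), len(result.survivors), criteria.charge_convention,
        config.panel.pka_set,
    )
    return result
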