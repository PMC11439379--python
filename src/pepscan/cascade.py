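"""The staged candidate-selection funnel.

Candidates pass through conjunctive filters in a fixed order — AMP status,
net-charge window, hydrophobic-percent window, anticancer classification —
with per-stage bookkeeping of who was kept and who was excluded (and why),
ending in a deterministic ranked top-k. Toxicity and allergenicity calls are
attached to survivors as annotations, not used as filters.

Default windows follow common AMP-screening practice for cationic peptides:
net charge strictly positive and at most +9, hydrophobic content of at
least 13% (the ``paper_selected`` preset; a stricter 17–50% ``paper_optimal``
window is also provided) and an anticancer score of at least 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .physchem import PropertyPanel
from .predictors import ScoreRecord, ScoreTable

DEFAULT_STAGE_ORDER = ("amp", "charge", "hydrophobicity", "anticancer")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for each funnel stage.

    ``charge_min`` is exclusive by default ("favourable" charge means
    strictly positive); ``charge_max`` inclusive. The hydrophobicity window
    is evaluated on the rounded integer percent, inclusive at both edges,
    so a 12.5% peptide reported as 13% passes a ≥13 minimum.
    """

    require_amp: bool = True
    amp_probability_threshold: float = 0.5
    charge_min: float = 0.0
    charge_min_inclusive: bool = False
    charge_max: float = 9.0
    hydrophobic_percent_min: int = 13
    hydrophobic_percent_max: int = 50
    anticancer_threshold: float = 0.5
    charge_convention: str = "quarter_ph7"
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.charge_min >= self.charge_max:
            raise ValueError("charge_min must be below charge_max")
        if self.hydrophobic_percent_min >= self.hydrophobic_percent_max:
            raise ValueError("hydrophobic window min must be below max")
        if not 0 < self.anticancer_threshold < 1:
            raise ValueError("anticancer_threshold must lie in (0, 1)")
        if self.top_k < 0:
            raise ValueError("top_k must be non-negative")


#: Window the screen's own selected candidates satisfy (13% hydrophobic).
PAPER_SELECTED = FilterCriteria()
#: The stricter window often quoted as optimal for membrane-active peptides.
PAPER_OPTIMAL = replace(PAPER_SELECTED, hydrophobic_percent_min=17)

PRESETS = {"paper-selected": PAPER_SELECTED, "paper-optimal": PAPER_OPTIMAL}


@dataclass(frozen=True)
class StageReport:
    name: str
    criterion: str
    input_count: int
    kept: tuple[str, ...]
    excluded: tuple[str, ...]
    reasons: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class RankedCandidate:
    id: str
    anticancer_score: float
    net_charge: float


@dataclass(frozen=True)
class CascadeResult:
    stages: tuple[StageReport, ...]
    final_ranking: tuple[RankedCandidate, ...]
    criteria: FilterCriteria

    @property
    def survivors(self) -> tuple[str, ...]:
        return self.stages[-1].kept if self.stages else ()


def _charge(panel: PropertyPanel, convention: str) -> float:
    return {
        "quarter_ph7": panel.net_charge_quarter,
        "anticp_integer": panel.net_charge_anticp,
        "henderson_hasselbalch": panel.net_charge_hh,
    }[convention]


def _stage_pass(
    stage: str,
    pid: str,
    panels: Mapping[str, PropertyPanel],
    scores: ScoreTable,
    c: FilterCriteria,
) -> tuple[bool, str]:
    """(passes, reason-if-excluded) for one peptide at one stage."""
    if stage == "amp":
        if not c.require_amp:
            return True, ""
        rec = scores.get(pid)
        status = rec.is_amp(c.amp_probability_threshold) if rec else None
        if status is None:
            return False, "unscored"
        return (True, "") if status else (False, "non-AMP")
    if stage == "charge":
        q = _charge(panels[pid], c.charge_convention)
        lo_ok = q >= c.charge_min if c.charge_min_inclusive else q > c.charge_min
        if lo_ok and q <= c.charge_max:
            return True, ""
        return False, f"charge {q:+.2f} outside window"
    if stage == "hydrophobicity":
        pct = panels[pid].hydrophobic_percent_rounded
        if c.hydrophobic_percent_min <= pct <= c.hydrophobic_percent_max:
            return True, ""
        return False, f"hydrophobic {pct}% outside window"
    if stage == "anticancer":
        rec = scores.get(pid)
        if rec is None or rec.anticancer_score is None:
            return False, "unscored"
        if rec.anticancer_score >= c.anticancer_threshold:
            return True, ""
        return False, f"anticancer score {rec.anticancer_score:.3f} below threshold"
    raise ValueError(f"unknown stage {stage!r}")


_CRITERION_TEXT = {
    "amp": "classified AMP (flag, or probability >= {c.amp_probability_threshold})",
    "charge": "net charge ({c.charge_convention}) in ({c.charge_min}, {c.charge_max}]",
    "hydrophobicity": "hydrophobic percent in [{c.hydrophobic_percent_min}, {c.hydrophobic_percent_max}]",
    "anticancer": "anticancer score >= {c.anticancer_threshold}",
}


def rank_candidates(
    candidates: Iterable[RankedCandidate],
) -> tuple[RankedCandidate, ...]:
    """Total deterministic order: anticancer score desc, net charge desc, id asc."""
    return tuple(
        sorted(candidates, key=lambda r: (-r.anticancer_score, -r.net_charge, r.id))
    )


def run_cascade(
    peptide_ids: Sequence[str],
    panels: Mapping[str, PropertyPanel],
    scores: ScoreTable,
    criteria: FilterCriteria = PAPER_SELECTED,
    stage_order: Sequence[str] = DEFAULT_STAGE_ORDER,
) -> CascadeResult:
    """Run the funnel over a library and return the full stage bookkeeping.

    ``peptide_ids`` fixes the library and its order; every id must have a
    :class:`PropertyPanel`. Score coverage may be partial — peptides missing
    an AMP or anticancer score fail those stages as "unscored".
    """
    missing = [pid for pid in peptide_ids if pid not in panels]
    if missing:
        raise KeyError(f"no PropertyPanel for ids {missing[:5]}")
    if sorted(stage_order) != sorted(DEFAULT_STAGE_ORDER):
        raise ValueError(f"stage_order must be a permutation of {DEFAULT_STAGE_ORDER}")

    current = list(peptide_ids)
    stage_reports = []
    for stage in stage_order:
        kept, excluded, reasons = [], [], {}
        for pid in current:
            ok, why = _stage_pass(stage, pid, panels, scores, criteria)
            (kept if ok else excluded).append(pid)
            if not ok:
                reasons[pid] = why
        stage_reports.append(
            StageReport(
                name=stage,
                criterion=_CRITERION_TEXT[stage].format(c=criteria),
                input_count=len(current),
                kept=tuple(kept),
                excluded=tuple(excluded),
                reasons=reasons,
            )
        )
        current = kept

    ranked = rank_candidates(
        RankedCandidate(
            id=pid,
            anticancer_score=scores.get(pid).anticancer_score,  # survivors are scored
            net_charge=_charge(panels[pid], criteria.charge_convention),
        )
        for pid in current
    )[: criteria.top_k]
    return CascadeResult(
        stages=tuple(stage_reports), final_ranking=ranked, criteria=criteria
    )


def funnel_report(result: CascadeResult) -> pd.DataFrame:
    """One row per stage: name, criterion, input, kept and excluded counts."""
    rows = [
        {
            "stage": s.name,
            "criterion": s.criterion,
            "input": s.input_count,
            "kept": len(s.kept),
            "excluded": len(s.excluded),
        }
        for s in result.stages
    ]
    return pd.DataFrame(rows, columns=["stage", "criterion", "input", "kept", "excluded"])


def funnel_summary(result: CascadeResult) -> str:
    """Human-readable funnel summary with the final ranking."""
    lines = []
    for s in result.stages:
        lines.append(
            f"{s.name:15s} in={s.input_count:5d} kept={len(s.kept):5d} "
            f"excluded={len(s.excluded):5d}  [{s.criterion}]"
        )
    if result.final_ranking:
        lines.append("ranking: " + ", ".join(
            f"{r.id} (score={r.anticancer_score:.3g}, charge={r.net_charge:+.2f})"
            for r in result.final_ranking
        ))
    else:
        lines.append("ranking: (no survivors)")
    return "\n".join(lines)
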