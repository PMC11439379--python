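"""Ingestion and merging of external predictor scores.

The ML predictors behind AMP/anticancer/toxicity/allergenicity calls (web
servers with trained weights) are deliberately not reimplemented; their
exported score tables are the interface. This module validates those tables,
merges multiple sources under an explicit precedence, and applies the simple
threshold classifications the selection funnel needs.

Column vocabulary for delimited tables (comma or tab, sniffed):

====================  =====================================================
``id``                peptide identifier (required, unique)
``amp_probability``   probability in [0, 1] that the peptide is an AMP
``amp_flag``          ``AMP`` / ``non-AMP``
``anticancer_score``  anticancer classifier score in [0, 1]
``toxicity_score``    raw toxicity score (any real)
``toxicity_flag``     ``toxic`` / ``non-toxic``
``allergen_flag``     ``allergen`` / ``non-allergen``
``source``            source label (may also be passed at load time)
====================  =====================================================

Unknown columns are preserved as opaque annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

TOXICITY_FLAGS = {"toxic", "non-toxic"}
ALLERGEN_FLAGS = {"allergen", "non-allergen"}
AMP_FLAGS = {"AMP", "non-AMP"}

_KNOWN_COLUMNS = {
    "id",
    "amp_probability",
    "amp_flag",
    "anticancer_score",
    "toxicity_score",
    "toxicity_flag",
    "allergen_flag",
    "source",
}


@dataclass(frozen=True)
class ScoreRecord:
    """Per-peptide predictor outputs; absent fields are ``None``."""

    id: str
    amp_probability: float | None = None
    amp_flag: str | None = None
    anticancer_score: float | None = None
    toxicity_score: float | None = None
    toxicity_flag: str | None = None
    allergen_flag: str | None = None
    source: str = ""
    annotations: Mapping[str, object] = field(default_factory=dict)
    per_source: Mapping[str, Mapping[str, object]] = field(default_factory=dict)

    def is_amp(self, probability_threshold: float = 0.5) -> bool | None:
        """AMP status: explicit flag wins, else threshold on probability;
        ``None`` when unscored."""
        if self.amp_flag is not None:
            return self.amp_flag == "AMP"
        if self.amp_probability is not None:
            return self.amp_probability >= probability_threshold
        return None


@dataclass(frozen=True)
class ScoreTable:
    """Validated id → :class:`ScoreRecord` mapping from one or more sources."""

    records: Mapping[str, ScoreRecord]
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pid: str) -> bool:
        return pid in self.records

    def get(self, pid: str) -> ScoreRecord | None:
        return self.records.get(pid)


def _validate_record(rec: ScoreRecord) -> None:
    for name, value in (
        ("amp_probability", rec.amp_probability),
        ("anticancer_score", rec.anticancer_score),
    ):
        if value is not None and not 0 <= value <= 1:
            raise ValueError(f"{rec.id}: {name} {value} outside [0, 1]")
    if rec.toxicity_flag is not None and rec.toxicity_flag not in TOXICITY_FLAGS:
        raise ValueError(f"{rec.id}: toxicity_flag {rec.toxicity_flag!r} not in {TOXICITY_FLAGS}")
    if rec.allergen_flag is not None and rec.allergen_flag not in ALLERGEN_FLAGS:
        raise ValueError(f"{rec.id}: allergen_flag {rec.allergen_flag!r} not in {ALLERGEN_FLAGS}")
    if rec.amp_flag is not None and rec.amp_flag not in AMP_FLAGS:
        raise ValueError(f"{rec.id}: amp_flag {rec.amp_flag!r} not in {AMP_FLAGS}")


def build_score_table(records: Iterable[ScoreRecord], source: str = "") -> ScoreTable:
    """Assemble and validate a :class:`ScoreTable`; duplicate ids are an error."""
    table: dict[str, ScoreRecord] = {}
    for rec in records:
        if rec.id in table:
            raise ValueError(f"duplicate peptide id {rec.id!r}")
        _validate_record(rec)
        table[rec.id] = rec
    return ScoreTable(records=table, source=source)


def load_score_table(path: str | Path, source: str | None = None) -> ScoreTable:
    """Load a delimited (comma/tab, sniffed by header) score table.

    Requires an ``id`` column plus at least one score or flag column; raises
    on duplicate ids, out-of-range probabilities or unknown flag values.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype={"id": str})
    except Exception as exc:  # empty file / undetectable delimiter
        raise ValueError(f"{path}: empty or unparseable score table ({exc})") from exc
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required 'id' column")
    if not (set(df.columns) & (_KNOWN_COLUMNS - {"id", "source"})):
        raise ValueError(f"{path}: no score or flag columns found")
    if df.empty:
        raise ValueError(f"{path}: score table has a header but no records")

    extra_cols = [c for c in df.columns if c not in _KNOWN_COLUMNS]
    records = []
    for row in df.to_dict("records"):
        def val(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and pd.isna(v)) else v

        records.append(
            ScoreRecord(
                id=str(row["id"]),
                amp_probability=val("amp_probability"),
                amp_flag=val("amp_flag"),
                anticancer_score=val("anticancer_score"),
                toxicity_score=val("toxicity_score"),
                toxicity_flag=val("toxicity_flag"),
                allergen_flag=val("allergen_flag"),
                source=val("source") or source or str(path),
                annotations={c: val(c) for c in extra_cols if val(c) is not None},
            )
        )
    return build_score_table(records, source=source or str(path))


def classify_anticancer(score: float, threshold: float = 0.5) -> str:
    """``anticancer`` iff score ≥ threshold (scores *below* the cut fail)."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    return "anticancer" if score >= threshold else "non-anticancer"


def consensus_amp(flags: Iterable[bool], rule: str = "majority") -> bool:
    """Combine AMP calls from several predictors (``majority`` or ``all``)."""
    flags = list(flags)
    if not flags:
        raise ValueError("no AMP calls to combine")
    if rule == "majority":
        return sum(flags) * 2 >= len(flags)
    if rule == "all":
        return all(flags)
    raise ValueError(f"unknown consensus rule {rule!r}")


_FIELDS = (
    "amp_probability",
    "amp_flag",
    "anticancer_score",
    "toxicity_score",
    "toxicity_flag",
    "allergen_flag",
)


def merge_scores(tables: list[ScoreTable], precedence: list[str]) -> ScoreTable:
    """Merge tables into one record per id; higher-precedence source wins.

    ``precedence`` lists source labels, most authoritative first, and must
    cover every source present. Field conflicts are logged; every source's
    raw fields are retained under ``per_source`` so disagreements (e.g. two
    allergenicity predictors voting differently) are never silently lost.
    """
    observed = {t.source for t in tables}
    missing = observed - set(precedence)
    if missing:
        raise ValueError(f"precedence omits observed sources {sorted(missing)}")

    ordered = sorted(tables, key=lambda t: precedence.index(t.source))
    merged: dict[str, ScoreRecord] = {}
    for table in ordered:
        for pid, rec in table.records.items():
            incoming = {f: getattr(rec, f) for f in _FIELDS}
            if pid not in merged:
                merged[pid] = replace(rec, per_source={rec.source: incoming})
                continue
            kept = merged[pid]
            updates: dict[str, object] = {}
            for f in _FIELDS:
                new = getattr(rec, f)
                if new is None:
                    continue
                cur = getattr(kept, f)
                if cur is None:
                    updates[f] = new  # fill a gap from the lower-precedence source
                elif cur != new:
                    logger.warning(
                        "conflict for %s.%s: keeping %r from %s, ignoring %r from %s",
                        pid, f, cur, kept.source, new, rec.source,
                    )
            per_source = dict(kept.per_source)
            per_source[rec.source] = incoming
            merged[pid] = replace(kept, per_source=per_source, **updates)
    return ScoreTable(records=merged, source="+".join(precedence))
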