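"""Screening-library pre-filter: molecular weight and rotatable bonds.

Before virtual screening, a compound library is narrowed to molecules a
docking engine handles reliably and that are plausible CNS drugs: weight
within 100-1000 Da (inclusive) and fewer than 13 rotatable bonds, drawn
from the approved / nutraceutical drug groups.  Weights can be computed
from a Hill-notation molecular formula with standard average atomic
masses; rotatable-bond counts are accepted precomputed, or (optionally)
computed from SMILES when a cheminformatics backend is importable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence
import re

__all__ = [
    "CompoundRecord",
    "FilterResult",
    "formula_mw",
    "filter_library",
    "rotatable_bonds_from_smiles",
    "ATOMIC_WEIGHTS",
]

# IUPAC 2021 standard atomic weights (conventional values), g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ar": 39.95, "Ca": 40.078,
    "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546,
    "Zn": 65.38, "As": 74.922, "Se": 78.971, "Br": 79.904, "Mo": 95.95,
    "Ag": 107.868, "I": 126.904, "Ba": 137.327, "Pt": 195.084,
    "Au": 196.967, "Hg": 200.592,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mw(formula: str) -> float:
    """Molecular weight (g/mol, 2 decimals) from a Hill-notation formula."""
    formula = formula.strip()
    if not formula:
        raise ValueError("empty formula")
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        element, count = m.group(1), int(m.group(2) or 1)
        weight = ATOMIC_WEIGHTS.get(element)
        if weight is None:
            raise ValueError(f"unknown element symbol {element!r} in {formula!r}")
        total += weight * count
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return round(total, 2)


def rotatable_bonds_from_smiles(smiles: str) -> int:
    """Rotatable-bond count via the optional cheminformatics backend."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return int(Descriptors.NumRotatableBonds(mol))


@dataclass
class CompoundRecord:
    """One library compound with the descriptors the filter needs."""

    id: str
    formula: str | None = None
    mw: float | None = None
    rotatable_bonds: int | None = None
    group: str = "other"
    excluded: bool = False          # manual curation (e.g. unacceptable side effects)

    def __post_init__(self) -> None:
        if self.mw is None and self.formula:
            self.mw = formula_mw(self.formula)
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"{self.id}: non-positive molecular weight")
        if self.rotatable_bonds is not None and self.rotatable_bonds < 0:
            raise ValueError(f"{self.id}: negative rotatable-bond count")


@dataclass
class FilterResult:
    kept: list[CompoundRecord]
    rejected: list[tuple[CompoundRecord, list[str]]]

    def rejection_reasons(self) -> dict[str, list[str]]:
        return {c.id: reasons for c, reasons in self.rejected}


def filter_library(
    compounds: Iterable[CompoundRecord],
    mw_window: tuple[float, float] = (100.0, 1000.0),
    max_rotbonds: int = 13,
    groups: Sequence[str] = ("approved", "nutraceutical"),
) -> FilterResult:
    """Partition a library into kept and rejected-with-reasons.

    Kept ⟺ weight within the closed window, rotatable bonds strictly below
    ``max_rotbonds``, drug group among ``groups`` and not manually
    excluded.  Compounds with unresolvable descriptors are rejected with a
    "missing descriptor" reason.
    """
    lo, hi = mw_window
    kept: list[CompoundRecord] = []
    rejected: list[tuple[CompoundRecord, list[str]]] = []
    for comp in compounds:
        reasons: list[str] = []
        if comp.mw is None:
            reasons.append("missing descriptor: mw")
        elif not lo <= comp.mw <= hi:
            reasons.append(f"mw {comp.mw} outside [{lo}, {hi}]")
        if comp.rotatable_bonds is None:
            reasons.append("missing descriptor: rotatable_bonds")
        elif comp.rotatable_bonds >= max_rotbonds:
            reasons.append(f"rotatable bonds {comp.rotatable_bonds} >= {max_rotbonds}")
        if comp.group not in groups:
            reasons.append(f"group {comp.group!r} not in {tuple(groups)}")
        if comp.excluded:
            reasons.append("manually excluded")
        if reasons:
            rejected.append((comp, reasons))
        else:
            kept.append(comp)
    return FilterResult(kept=kept, rejected=rejected)
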