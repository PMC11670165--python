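"""Structural context around mutation sites.

Implements the 5 Å-neighbourhood analysis used to judge how well a region
of a structure is defined: residues within 5 Å of a mutation site are
collected, their B-factor (experimental structures) or pLDDT (predicted
models) is averaged, and the mean is classified High / Medium / Low.
High means a rigid, well-resolved (or confidently predicted) region;
Low means flexibility or low model confidence, i.e. poor reliability of
any structure-based inference at that site.

Also provides per-residue averaging of per-substitution pathogenicity
matrices (19 alternative residues per position) and mapping of
protein-level variants onto a structure with wild-type verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structmodel import Residue, StructureModel, VariantRecord

__all__ = [
    "Neighborhood",
    "DefinitionLabel",
    "SubstitutionMatrix",
    "SiteDefinitionReport",
    "MappingReport",
    "neighborhood",
    "classify_definition",
    "site_definition",
    "aggregate_substitution_scores",
    "map_variants",
]

Label = Literal["High", "Medium", "Low"]

# B-factor (Å²): below 30 the site is well resolved, above 60 poorly.
# pLDDT: above 70 is confident, below 50 is not.
_BFACTOR_BOUNDS = (30.0, 60.0)
_PLDDT_BOUNDS = (50.0, 70.0)


@dataclass
class Neighborhood:
    """Residues with any heavy atom within ``radius`` Å of the centre."""

    center: Residue
    radius: float
    members: list[Residue]
    mean_value: float | None = None

    def member_ids(self) -> list[tuple[str, int, str]]:
        return [r.id for r in self.members]


@dataclass(frozen=True)
class DefinitionLabel:
    value: Label
    basis: Literal["bfactor", "plddt"]
    score: float


@dataclass
class SubstitutionMatrix:
    """Per-position pathogenicity scores for the 19 alternative residues."""

    scores: dict[int, dict[str, float]]

    def __post_init__(self) -> None:
        for pos, alts in self.scores.items():
            if len(alts) > 19:
                raise ValueError(f"position {pos}: more than 19 alternatives")
            for aa, s in alts.items():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"position {pos} {aa}: score {s} outside [0,1]")


@dataclass
class SiteDefinitionReport:
    """Per-site classification plus the pooled member-label census."""

    basis: Literal["bfactor", "plddt"]
    radius: float
    site_labels: dict[str, DefinitionLabel]
    site_neighborhoods: dict[str, Neighborhood]
    census: dict[Label, int]
    census_residues: dict[tuple[str, int, str], Label]
    unmappable: list[str] = field(default_factory=list)

    @property
    def n_census_residues(self) -> int:
        return len(self.census_residues)


@dataclass
class MappingReport:
    mapped: dict[str, Residue]
    mismatches: list[tuple[str, str]]      # (label, found residue name)
    out_of_range: list[str]

    @property
    def ok(self) -> bool:
        return not self.mismatches and not self.out_of_range


def _heavy_atom_index(model: StructureModel):
    coords, owner = [], []
    for res in model.residues(amino_only=True):
        for atom in res.heavy_atoms():
            coords.append(atom.coords)
            owner.append(res)
    if not coords:
        raise ValueError("model has no amino-acid heavy atoms")
    return np.asarray(coords), owner


def neighborhood(model: StructureModel, center: Residue,
                 radius: float = 5.0) -> Neighborhood:
    """All residues having a heavy atom within ``radius`` Å of any heavy
    atom of ``center`` (the centre itself included), ordered by
    (chain, number, insertion code)."""
    all_ids = {r.id for r in model.residues()}
    if center.id not in all_ids:
        raise KeyError(f"centre residue {center.id} not in model")
    coords, owner = _heavy_atom_index(model)
    tree = cKDTree(coords)
    center_coords = center.heavy_coords()
    if center_coords.size == 0:
        raise ValueError(f"centre residue {center.id} has no heavy atoms")
    hit_ids: set[tuple[str, int, str]] = {center.id}
    for idx_list in tree.query_ball_point(center_coords, radius):
        for j in idx_list:
            hit_ids.add(owner[j].id)
    members = sorted(
        (r for r in model.residues(amino_only=True) if r.id in hit_ids),
        key=lambda r: (r.chain_id, r.number, r.insertion_code),
    )
    return Neighborhood(center=center, radius=radius, members=members)


def classify_definition(value: float,
                        basis: Literal["bfactor", "plddt"]) -> DefinitionLabel:
    """High/Medium/Low from a B-factor or pLDDT value.

    B-factor below 30 Å² is High, above 60 Å² Low; pLDDT above 70 is High,
    below 50 Low.  Values on a boundary are classified Medium.
    """
    if value < 0:
        raise ValueError(f"negative {basis} value {value}")
    if basis == "bfactor":
        lo, hi = _BFACTOR_BOUNDS
        label: Label = "High" if value < lo else ("Medium" if value <= hi else "Low")
    elif basis == "plddt":
        if value > 100:
            raise ValueError(f"pLDDT {value} above 100")
        lo, hi = _PLDDT_BOUNDS
        label = "Low" if value < lo else ("Medium" if value <= hi else "High")
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return DefinitionLabel(value=label, basis=basis, score=float(value))


def _residue_value(res: Residue, basis: str) -> float:
    # B-factor: mean over heavy atoms; pLDDT is constant per residue so the
    # mean reads it off equally well.
    return res.mean_bfactor()


def site_definition(
    model: StructureModel,
    sites: Sequence[VariantRecord],
    radius: float = 5.0,
    basis: Literal["bfactor", "plddt", "auto"] = "auto",
    chain_id: str | None = None,
) -> SiteDefinitionReport:
    """Structural-definition assessment of a set of mutation sites.

    For each site the neighbourhood mean (centre included) is classified;
    the census pools the *surrounding* residues of all sites (centres
    excluded, each residue counted once across overlapping neighbourhoods)
    and labels each individually.  Sites whose position falls outside the
    chain are reported as unmappable rather than raising.
    """
    if basis == "auto":
        basis = "plddt" if model.source_kind == "predicted" else "bfactor"
    positions = model.sequence_positions(chain_id)

    site_labels: dict[str, DefinitionLabel] = {}
    site_neighborhoods: dict[str, Neighborhood] = {}
    unmappable: list[str] = []
    centers: set[tuple[str, int, str]] = set()
    pooled: dict[tuple[str, int, str], float] = {}

    for site in sites:
        res = positions.get(site.position)
        if res is None:
            unmappable.append(site.label)
            continue
        nb = neighborhood(model, res, radius)
        values = [_residue_value(r, basis) for r in nb.members]
        nb.mean_value = float(np.mean(values))
        site_neighborhoods[site.label] = nb
        site_labels[site.label] = classify_definition(nb.mean_value, basis)
        centers.add(res.id)
        for member in nb.members:
            pooled[member.id] = _residue_value(member, basis)

    census_residues = {
        rid: classify_definition(val, basis).value
        for rid, val in pooled.items() if rid not in centers
    }
    census: dict[Label, int] = {"High": 0, "Medium": 0, "Low": 0}
    for label in census_residues.values():
        census[label] += 1
    return SiteDefinitionReport(
        basis=basis, radius=radius, site_labels=site_labels,
        site_neighborhoods=site_neighborhoods, census=census,
        census_residues=census_residues, unmappable=unmappable,
    )


def aggregate_substitution_scores(matrix: SubstitutionMatrix) -> dict[int, float]:
    """Mean pathogenicity over the available alternative residues, per
    position.  Positions with no scores are excluded (with a warning)."""
    import warnings

    out: dict[int, float] = {}
    for pos in sorted(matrix.scores):
        alts = matrix.scores[pos]
        if not alts:
            warnings.warn(f"position {pos} has no substitution scores; skipped",
                          stacklevel=2)
            continue
        out[pos] = float(np.mean(list(alts.values())))
    return out


def map_variants(
    model: StructureModel,
    variants: Sequence[VariantRecord],
    chain_id: str | None = None,
) -> MappingReport:
    """Locate each variant on the model and verify its wild-type residue.

    Mismatching wild-type letters and out-of-range positions are reported,
    never silently dropped.
    """
    positions = model.sequence_positions(chain_id)
    mapped: dict[str, Residue] = {}
    mismatches: list[tuple[str, str]] = []
    out_of_range: list[str] = []
    for var in variants:
        res = positions.get(var.position)
        if res is None:
            out_of_range.append(var.label)
        elif res.one_letter != var.wt:
            mismatches.append((var.label, res.name))
        else:
            mapped[var.label] = res
    return MappingReport(mapped=mapped, mismatches=mismatches,
                        out_of_range=out_of_range)
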