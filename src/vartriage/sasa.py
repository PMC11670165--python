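"""Shrake-Rupley solvent-accessible surface area and relative accessibility.

SASA is computed by sampling a deterministic golden-spiral point lattice on
each atom's solvent-expanded sphere (radius r + probe) and counting the
points not occluded by any neighbouring sphere.  Relative solvent
accessibility (RSA) normalises a residue's SASA by the same residue's SASA
in an extended Ala-X-Ala tripeptide (the maximum attainable exposure given
minimal steric hindrance from alanine neighbours), expressed as a
percentage.  Residues with RSA above 20% are called solvent-exposed, the
rest buried.

Radii follow the NACCESS convention by default (C 1.87, N 1.65, O 1.40,
S 1.85 Å; backbone carbonyl carbon 1.76 Å); hydrogens and hetero atoms are
excluded from the calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .structmodel import AA1_TO_3, AA3_TO_1, Residue, StructureModel, build_fixture

__all__ = [
    "RadiiSet",
    "NACCESS_RADII",
    "SasaResult",
    "MaxSasaTable",
    "shrake_rupley",
    "compute_max_sasa",
    "max_sasa_table",
    "relative_accessibility",
    "classify_exposure",
]


@dataclass(frozen=True)
class RadiiSet:
    """Van der Waals radii, resolved per atom.

    ``by_element`` maps element symbols to radii; ``overrides`` maps
    (residue name or "*", atom name) to radii and wins over the element
    default.  A ``fallback`` radius, if set, is used for unknown elements.
    """

    name: str
    by_element: Mapping[str, float]
    overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    fallback: float | None = None

    def __post_init__(self) -> None:
        for r in list(self.by_element.values()) + list(self.overrides.values()):
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius {r} outside the plausible (0.5, 3.0) Å range")

    def radius_of(self, residue_name: str, atom_name: str, element: str) -> float:
        for key in ((residue_name.upper(), atom_name), ("*", atom_name)):
            if key in self.overrides:
                return self.overrides[key]
        r = self.by_element.get(element.upper())
        if r is None:
            r = self.fallback
        if r is None:
            raise KeyError(
                f"no radius for atom {atom_name} ({element}) in {residue_name}; "
                f"set RadiiSet.fallback to tolerate unknown elements"
            )
        return r


#: NACCESS-style radii: aliphatic/aromatic carbons 1.87 Å, backbone carbonyl
#: carbon 1.76 Å, nitrogen 1.65 Å, oxygen 1.40 Å, sulfur 1.85 Å.
NACCESS_RADII = RadiiSet(
    name="naccess",
    by_element={"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90,
                "SE": 1.90},
    overrides={("*", "C"): 1.76},
    fallback=None,
)


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible areas in Å²."""

    atom_areas: np.ndarray
    residue_areas: dict[tuple[str, int, str], float]
    probe_radius: float
    n_points: int

    def residue_sasa(self, residue: Residue) -> float:
        return self.residue_areas[residue.id]


@dataclass
class MaxSasaTable:
    """Reference maximum SASA (Å²) per residue type, from Ala-X-Ala."""

    values: dict[str, float]
    probe_radius: float = 1.4
    n_points: int = 960
    radii_name: str = "naccess"

    def __post_init__(self) -> None:
        for aa, v in self.values.items():
            if v <= 0:
                raise ValueError(f"non-positive reference SASA for {aa}")

    def __getitem__(self, aa: str) -> float:
        try:
            return self.values[aa]
        except KeyError:
            raise KeyError(f"residue type {aa!r} absent from reference table") from None


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (Fibonacci spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _local_frame(coords: np.ndarray, i: int, tree: cKDTree) -> np.ndarray:
    """Orthonormal frame tied to atom i's two nearest neighbours.

    Rotating the whole coordinate set rotates the frame identically, so
    sphere points expressed in this frame are rigid-motion covariant.
    Falls back to the identity for isolated or collinear environments.
    """
    n = coords.shape[0]
    if n < 2:
        return np.eye(3)
    k = min(3, n)
    _, idx = tree.query(coords[i], k=k)
    idx = np.atleast_1d(idx)
    neighbors = [j for j in idx if j != i]
    e1 = coords[neighbors[0]] - coords[i]
    norm1 = np.linalg.norm(e1)
    if norm1 == 0.0:
        return np.eye(3)
    e1 = e1 / norm1
    if len(neighbors) > 1:
        v = coords[neighbors[1]] - coords[i]
        v = v - np.dot(v, e1) * e1
        norm2 = np.linalg.norm(v)
    else:
        norm2 = 0.0
    if norm2 < 1e-8:
        # any perpendicular direction; derived from e1, hence covariant
        # only up to the arbitrary choice, which degenerate cases tolerate
        v = np.array([1.0, 0.0, 0.0])
        if abs(e1[0]) > 0.9:
            v = np.array([0.0, 1.0, 0.0])
        v = v - np.dot(v, e1) * e1
        norm2 = np.linalg.norm(v)
    e2 = v / norm2
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _collect_atoms(model: StructureModel, radii: RadiiSet,
                   include_hetero: bool) -> tuple[list, np.ndarray, np.ndarray]:
    atoms, coords, rads = [], [], []
    for res in model.residues():
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            if atom.is_hetero and not include_hetero:
                continue
            atoms.append((res, atom))
            coords.append(atom.coords)
            rads.append(radii.radius_of(res.name, atom.name, atom.element))
    if not atoms:
        raise ValueError("no heavy atoms to compute SASA on")
    return atoms, np.asarray(coords), np.asarray(rads)


def shrake_rupley(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: RadiiSet = NACCESS_RADII,
    include_hetero: bool = False,
) -> SasaResult:
    """Shrake-Rupley SASA over all heavy atoms of the model.

    For each atom, ``n_points`` lattice points are placed on the sphere of
    radius r_atom + probe; a point is accessible if it lies outside every
    neighbour's expanded sphere.  The atom's area is the accessible
    fraction of 4π(r+probe)².  Neighbour candidates come from a k-d tree
    query, which returns exactly the atoms an all-pairs scan would.

    The lattice is oriented per atom in a frame built from the directions
    to its two nearest neighbours, so the sampling pattern travels with
    the molecule and the result is exactly invariant under rigid-body
    rotation and translation.
    """
    if n_points < 12:
        raise ValueError("n_points must be >= 12")
    atoms, coords, rads = _collect_atoms(model, radii, include_hetero)
    sphere = golden_spiral_points(n_points)
    expanded = rads + probe
    tree = cKDTree(coords)
    max_expanded = expanded.max()

    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + expanded[i] * (sphere @ _local_frame(coords, i, tree).T)
        # any neighbour with |c_i - c_j| < (r_i + probe) + (r_j + probe)
        # can occlude; the tree query is a superset-free exact candidate set
        cand = tree.query_ball_point(coords[i], expanded[i] + max_expanded)
        cand = [j for j in cand if j != i
                and np.dot(coords[i] - coords[j], coords[i] - coords[j])
                < (expanded[i] + expanded[j]) ** 2]
        if cand:
            diff = pts[:, None, :] - coords[cand][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            occluded = (d2 < (expanded[cand] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - occluded.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac

    residue_areas: dict[tuple[str, int, str], float] = {}
    for (res, _atom), area in zip(atoms, areas):
        residue_areas[res.id] = residue_areas.get(res.id, 0.0) + float(area)
    # residues whose atoms were all excluded still get an entry of 0 if amino
    for res in model.residues(amino_only=True):
        residue_areas.setdefault(res.id, 0.0)
    return SasaResult(atom_areas=areas, residue_areas=residue_areas,
                      probe_radius=probe, n_points=n_points)


def compute_max_sasa(
    center: str,
    probe: float = 1.4,
    n_points: int = 960,
    radii: RadiiSet = NACCESS_RADII,
) -> float:
    """Maximum SASA of residue type ``center`` in an extended Ala-X-Ala.

    Only the atoms of the centre residue X contribute to the returned area.
    """
    if center not in AA1_TO_3:
        raise ValueError(f"unknown residue code {center!r}")
    tri = build_fixture("tripeptide", center)
    result = shrake_rupley(tri, probe=probe, n_points=n_points, radii=radii)
    return result.residue_areas[("A", 2, "")]


def max_sasa_table(
    probe: float = 1.4,
    n_points: int = 960,
    radii: RadiiSet = NACCESS_RADII,
) -> MaxSasaTable:
    """Reference table over the 20 standard residues (cached per parameters)."""
    key = (probe, n_points, radii.name)
    if key not in _MAX_TABLE_CACHE:
        values = {aa: compute_max_sasa(aa, probe, n_points, radii)
                  for aa in sorted(AA1_TO_3)}
        _MAX_TABLE_CACHE[key] = MaxSasaTable(
            values=values, probe_radius=probe, n_points=n_points,
            radii_name=radii.name)
    return _MAX_TABLE_CACHE[key]


_MAX_TABLE_CACHE: dict[tuple, MaxSasaTable] = {}


def relative_accessibility(
    model: StructureModel,
    residue: Residue,
    max_table: MaxSasaTable | None = None,
    sasa_result: SasaResult | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    radii: RadiiSet = NACCESS_RADII,
) -> float:
    """RSA of one residue as a percentage: 100 × SASA / SASAmax.

    May exceed 100 for chain termini or distorted geometry.  A precomputed
    :class:`SasaResult` for the whole model can be passed to avoid
    recomputation when scanning many residues.
    """
    aa = residue.one_letter
    if aa is None:
        raise ValueError(f"residue {residue.name} is not a standard amino acid")
    if max_table is None:
        max_table = max_sasa_table(probe, n_points, radii)
    if sasa_result is None:
        sasa_result = shrake_rupley(model, probe=probe, n_points=n_points,
                                    radii=radii)
    return 100.0 * sasa_result.residue_areas[residue.id] / max_table[aa]


def classify_exposure(rsa: float, threshold: float = 20.0) -> Literal["exposed", "buried"]:
    """Exposure call: RSA strictly above the threshold is exposed.

    The boundary value itself is classified buried, since exposure is
    defined strictly as RSA > 20%.
    """
    if rsa < 0:
        raise ValueError(f"negative RSA {rsa}")
    return "exposed" if rsa > threshold else "buried"
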