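"""Macromolecular structure container, PDB/mmCIF I/O, and synthetic fixtures.

The in-memory model is a thin hierarchy (StructureModel > Chain > Residue >
Atom) tailored to variant triage: every atom carries a temperature-factor
channel that doubles as the per-residue pLDDT when the source is an
AlphaFold-style predicted model.  Only the first model of multi-model files
is kept, and for alternate locations the highest-occupancy conformer wins.

Synthetic fixture generation builds peptides from ideal internal geometry
(NeRF chain extension) with side chains taken from the chemical component
dictionary's ideal coordinates, so every downstream computation is testable
without network access.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "VariantRecord",
    "read_structure",
    "write_scored_structure",
    "build_fixture",
    "AA3_TO_1",
    "AA1_TO_3",
]

AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3: dict[str, str] = {v: k for k, v in AA3_TO_1.items()}


@dataclass
class Atom:
    """A single atom: label, element, Cartesian coordinates (Å) and the
    temperature-factor channel (B-factor in Å², or pLDDT 0-100 for
    predicted models)."""

    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name}: negative temperature factor")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One residue identified by (chain_id, number, insertion_code)."""

    chain_id: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def one_letter(self) -> str | None:
        return AA3_TO_1.get(self.name.upper())

    @property
    def is_amino_acid(self) -> bool:
        return self.name.upper() in AA3_TO_1

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain_id}{self.number}: no atom {name!r}")

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.coords for a in atoms])

    def mean_bfactor(self) -> float:
        """Representative temperature factor: mean over heavy atoms."""
        atoms = self.heavy_atoms()
        if not atoms:
            raise ValueError(f"residue {self.chain_id}{self.number} has no heavy atoms")
        return float(np.mean([a.bfactor for a in atoms]))


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """First-model view of a macromolecular structure.

    ``source_kind`` records whether the temperature-factor channel should be
    read as a crystallographic B-factor (``experimental``) or a pLDDT
    confidence (``predicted``).
    """

    identifier: str
    chains: list[Chain] = field(default_factory=list)
    source_kind: Literal["experimental", "predicted"] = "experimental"

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues():
            if res.id in seen:
                raise ValueError(f"duplicate residue id {res.id}")
            seen.add(res.id)

    def residues(self, amino_only: bool = False) -> list[Residue]:
        out = []
        for ch in self.chains:
            for res in ch:
                if amino_only and not res.is_amino_acid:
                    continue
                out.append(res)
        return out

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r}")

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for res in self.chain(chain_id):
            if res.number == number and res.insertion_code == icode:
                return res
        raise KeyError(f"no residue {chain_id}/{number}{icode}")

    def sequence_positions(self, chain_id: str | None = None) -> dict[int, Residue]:
        """Explicit mapping 1-based sequence position -> residue.

        Amino-acid residues of the chosen chain (first chain by default) in
        author order.  Author numbering may be discontinuous; the sequence
        position is simply the ordinal rank, which matches author numbering
        for fixtures and AlphaFold models numbered 1..n.
        """
        ch = self.chains[0] if chain_id is None else self.chain(chain_id)
        amino = [r for r in ch if r.is_amino_acid]
        return {i + 1: res for i, res in enumerate(amino)}

    def heavy_atom_count(self) -> int:
        return sum(len(r.heavy_atoms()) for r in self.residues())


@dataclass(frozen=True)
class VariantRecord:
    """A protein-level single-residue substitution, e.g. R367Q."""

    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1, got {self.position}")
        for aa, role in ((self.wt, "wild-type"), (self.mut, "mutant")):
            if aa not in AA1_TO_3:
                raise ValueError(f"unknown {role} residue code {aa!r}")
        if self.wt == self.mut:
            raise ValueError(f"synonymous record {self.label} is not a variant")

    @property
    def label(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @classmethod
    def from_label(cls, label: str) -> "VariantRecord":
        label = label.strip()
        if len(label) < 3:
            raise ValueError(f"cannot parse variant label {label!r}")
        wt, pos, mut = label[0], label[1:-1], label[-1]
        if not pos.isdigit():
            raise ValueError(f"cannot parse variant label {label!r}")
        return cls(position=int(pos), wt=wt.upper(), mut=mut.upper())


# ---------------------------------------------------------------------------
# I/O via gemmi
# ---------------------------------------------------------------------------

def _looks_predicted(st: gemmi.Structure) -> bool:
    # AlphaFold-style models: all occupancies 1 and B-factors behave like
    # pLDDT (bounded by 100).  Heuristic only; callers may override.
    bvals = [a.b_iso for model in st for ch in model for r in ch for a in r]
    if not bvals:
        return False
    return max(bvals) <= 100.0 and min(bvals) >= 20.0


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    source_kind: Literal["experimental", "predicted", "auto"] = "auto",
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Keeps the first model only.  For alternate locations the
    highest-occupancy conformer is retained (ties: first seen).  Hydrogens
    and hetero records are kept but flagged; downstream geometry ignores
    them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"
    try:
        if format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path.name}: no models")
    model = st[0]

    chains: list[Chain] = []
    n_atoms = 0
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            res = Residue(
                chain_id=gchain.name,
                number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                name=gres.name,
            )
            # collapse altlocs: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            for ga in gres:  # preserve file order
                if best.get(ga.name) is not ga:
                    continue
                res.atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        bfactor=max(ga.b_iso, 0.0),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc=(ga.altloc or "").strip(),
                        is_hetero=(gres.het_flag == "H"),
                    )
                )
                n_atoms += 1
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    if n_atoms == 0:
        raise ValueError(f"{path.name}: no atoms in first model")

    if source_kind == "auto":
        source_kind = "predicted" if _looks_predicted(st) else "experimental"
    return StructureModel(identifier=st.name or path.stem, chains=chains,
                          source_kind=source_kind)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-column PDB."""
    st = _to_gemmi(model)
    st.write_pdb(str(path))


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.identifier
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gres.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.b_iso = atom.bfactor
                ga.occ = atom.occupancy
                ga.altloc = "\0" if not atom.altloc else atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_scored_structure(
    model: StructureModel,
    scores: Mapping[int, float],
    path: str | Path,
    chain_id: str | None = None,
) -> None:
    """Write a PDB whose B-factor column carries per-residue scores.

    Scores are keyed by 1-based sequence position of the scored chain;
    unscored residues get 0.00.  Values are clamped to the PDB column range
    [0, 999.99].  Useful for colouring a structure by, e.g., mean
    pathogenicity.
    """
    positions = model.sequence_positions(chain_id)
    orphans = sorted(set(scores) - set(positions))
    if orphans:
        raise KeyError(f"scores given for positions absent from the model: {orphans}")

    by_res_id = {positions[p].id: float(v) for p, v in scores.items()}
    import copy

    out = copy.deepcopy(model)
    for res in out.residues():
        value = by_res_id.get(res.id, 0.0)
        value = min(max(value, 0.0), 999.99)
        for atom in res.atoms:
            atom.bfactor = round(value, 2)
    write_pdb(out, path)


# ---------------------------------------------------------------------------
# Synthetic fixtures: ideal-geometry peptide builder
# ---------------------------------------------------------------------------

# Ideal backbone internal coordinates (Engh-Huber-like averages)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7

_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "extended": (-120.0, 120.0),
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: place atom d given chain a-b-c, |c-d|, angle(b,c,d), torsion(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ccd_template(resname: str) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Ideal heavy-atom template for a residue from the component dictionary."""
    import biotite.structure.info as _info

    arr = _info.residue(resname)
    keep = [
        i for i in range(arr.array_length())
        if arr.element[i] not in ("H", "D") and arr.atom_name[i] != "OXT"
    ]
    names = [(arr.atom_name[i], arr.element[i]) for i in keep]
    coords = np.asarray(arr.coord[keep], dtype=float)
    return names, coords


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile -> target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def _build_backbone(n_res: int, phi: float, psi: float, omega: float = 180.0) -> np.ndarray:
    """(n_res, 3, 3) array of N, CA, C coordinates."""
    coords = np.zeros((n_res, 3, 3))
    # seed the first residue in a canonical pose
    coords[0, 0] = np.array([0.0, 0.0, 0.0])                       # N
    coords[0, 1] = np.array([_B_N_CA, 0.0, 0.0])                   # CA
    ang = math.radians(_A_N_CA_C)
    coords[0, 2] = coords[0, 1] + _B_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )                                                               # C
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        coords[i] = np.stack([n_i, ca_i, c_i])
    return coords


def _build_chain(sequence: str, phi: float, psi: float, chain_id: str,
                 rng: np.random.Generator | None = None,
                 jitter: float = 0.0) -> Chain:
    n_res = len(sequence)
    backbone = _build_backbone(n_res, phi, psi)
    chain = Chain(chain_id=chain_id)
    for i, aa in enumerate(sequence):
        resname = AA1_TO_3[aa]
        names, template = _ccd_template(resname)
        t_idx = {nm: j for j, (nm, _) in enumerate(names)}
        t_bb = np.stack([template[t_idx["N"]], template[t_idx["CA"]],
                         template[t_idx["C"]]])
        rot, trans = _kabsch(t_bb, backbone[i])
        placed = template @ rot.T + trans
        # exact backbone positions for N, CA, C; template-derived for the rest
        placed[t_idx["N"]], placed[t_idx["CA"]], placed[t_idx["C"]] = backbone[i]
        if "O" in t_idx:
            # carbonyl O in the peptide plane, anti to the next N: torsion
            # ψ+180 about CA-C (the ψ default orients the final residue too)
            placed[t_idx["O"]] = _place_atom(
                backbone[i, 0], backbone[i, 1], backbone[i, 2],
                1.231, 120.5, psi + 180.0)
        if jitter > 0.0 and rng is not None:
            placed = placed + rng.normal(scale=jitter, size=placed.shape)
        res = Residue(chain_id=chain_id, number=i + 1, name=resname)
        for (nm, el), xyz in zip(names, placed):
            res.atoms.append(Atom(name=nm, element=el, coords=xyz))
        chain.residues.append(res)
    return chain


def _rotation_matrix(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def build_fixture(
    kind: Literal["helix", "extended", "tripeptide", "two_chain_dimer"],
    sequence: str,
    *,
    translation: Sequence[float] = (0.0, 0.0, 50.0),
    rotation_axis: Sequence[float] = (0.0, 0.0, 1.0),
    rotation_deg: float = 0.0,
    jitter: float = 0.0,
    seed: int | None = None,
    identifier: str | None = None,
    bfactor: float = 0.0,
) -> StructureModel:
    """Deterministic synthetic peptide structures from ideal geometry.

    ``helix`` uses (φ, ψ) = (−57°, −47°); ``extended`` (−120°, 120°).
    ``tripeptide`` builds an extended Ala-X-Ala around the given centre
    residue (``sequence`` is the one-letter code of X, or a 3-letter
    sequence whose centre is X).  ``two_chain_dimer`` builds two copies of
    the sequence as chains A and B, the second transformed by the given
    rotation and translation so the interface is caller-controlled.
    Optional Gaussian coordinate jitter is seeded and reproducible.
    """
    sequence = sequence.replace(" ", "").upper()
    if not sequence:
        raise ValueError("empty sequence")
    for aa in sequence:
        if aa not in AA1_TO_3:
            raise ValueError(f"non-standard residue code {aa!r}")

    rng = np.random.default_rng(seed) if jitter > 0.0 else None

    if kind == "tripeptide":
        if len(sequence) == 1:
            sequence = f"A{sequence}A"
        elif len(sequence) != 3:
            raise ValueError("tripeptide takes a centre residue or 3 residues")
        phi, psi = _PHI_PSI["extended"]
        chains = [_build_chain(sequence, phi, psi, "A", rng, jitter)]
    elif kind in ("helix", "extended"):
        phi, psi = _PHI_PSI[kind]
        chains = [_build_chain(sequence, phi, psi, "A", rng, jitter)]
    elif kind == "two_chain_dimer":
        phi, psi = _PHI_PSI["extended"]
        chain_a = _build_chain(sequence, phi, psi, "A", rng, jitter)
        chain_b = _build_chain(sequence, phi, psi, "B", rng, jitter)
        rot = _rotation_matrix(rotation_axis, rotation_deg)
        tvec = np.asarray(translation, dtype=float)
        for res in chain_b:
            for atom in res.atoms:
                atom.coords = rot @ atom.coords + tvec
        chains = [chain_a, chain_b]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    model = StructureModel(
        identifier=identifier or f"fixture-{kind}-{sequence}",
        chains=chains,
        source_kind="experimental",
    )
    if bfactor:
        for res in model.residues():
            for atom in res.atoms:
                atom.bfactor = bfactor
    return model
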