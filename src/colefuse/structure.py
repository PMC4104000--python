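"""Coordinate data model, PDB I/O and atom selection.

All coordinates are stored in nanometres; PDB I/O converts to/from the
Angstrom convention of the format (exact factor-10 scaling).  Author residue
numbering is preserved verbatim on read — the nuclease domain keeps its
446-576 numbering, zinc fingers keep whatever the crystallographers used.

A :class:`Structure` holds one topology (chains -> residues -> atoms) and one
or more coordinate *frames* over it.  Frame 0 lives in the atoms themselves;
additional frames (MODEL records of an ensemble) are stored as dense arrays
congruent with the atom order.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import (
    PdbFormatError,
    PdbParseError,
    SelectionError,
    TopologyError,
)

ANGSTROM_PER_NM = 10.0

#: 3-letter codes recognised as standard amino acids.
PROTEIN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE SEC PYL""".split()
)
DNA_RESIDUES = frozenset("DA DC DG DT DI DU A C G T U".split())
ION_RESIDUES = frozenset("ZN NA CL MG K CA MN FE CU NI CD CO".split())
WATER_RESIDUES = frozenset("HOH WAT SOL".split())

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Atomic masses (u) for the elements that occur in protein/DNA systems.
ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "ZN": 65.38, "NA": 22.990, "CL": 35.45, "MG": 24.305,
    "K": 39.098, "FE": 55.845, "MN": 54.938, "CA": 40.078,
}


class ResidueKind(enum.Enum):
    PROTEIN = "protein"
    DNA = "dna"
    ION = "ion"
    WATER = "water"
    OTHER = "other"


def classify_residue(res_name: str) -> ResidueKind:
    name = res_name.strip().upper()
    if name in PROTEIN_RESIDUES:
        return ResidueKind.PROTEIN
    if name in DNA_RESIDUES:
        return ResidueKind.DNA
    if name in ION_RESIDUES:
        return ResidueKind.ION
    if name in WATER_RESIDUES:
        return ResidueKind.WATER
    return ResidueKind.OTHER


def element_from_name(name: str) -> str:
    """Best-effort element symbol from an atom name (PDB conventions)."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[:2].upper() in ("ZN", "NA", "CL", "MG", "FE", "MN"):
        return stripped[:2].upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return stripped[0].upper()


@dataclasses.dataclass
class Atom:
    """A named point with element, coordinates (nm) and pass-through factors."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")

    @property
    def mass(self) -> float:
        return ELEMENT_MASS.get(self.element.upper(), 12.011)


@dataclasses.dataclass
class Residue:
    seq_id: int
    res_name: str
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    insertion_code: str = ""
    kind: ResidueKind = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind is None:
            self.kind = classify_residue(self.res_name)
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"residue {self.res_name}{self.seq_id}: duplicate atom names"
            )

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def add_atom(self, atom: Atom) -> None:
        if self.atom(atom.name) is not None:
            raise ValueError(
                f"residue {self.res_name}{self.seq_id}: duplicate atom {atom.name}"
            )
        self.atoms.append(atom)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"chain {self.chain_id}: duplicate residue ids")

    def residue(self, seq_id: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seq_id == seq_id and r.insertion_code == icode:
                return r
        return None


class Structure:
    """Chains over one topology, with >= 1 coordinate frames.

    Frame 0 is authoritative and lives in the Atom objects; frames 1..n-1
    are dense ``(n_atoms, 3)`` arrays in the same atom order.
    """

    def __init__(self, id: str, chains: Sequence[Chain] = ()):  # noqa: A002
        self.id = id
        self.chains: list[Chain] = list(chains)
        self._extra_frames: list[np.ndarray] = []

    # -- topology ---------------------------------------------------------
    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    # -- frames -----------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return 1 + len(self._extra_frames)

    def coords_array(self, frame: int = 0) -> np.ndarray:
        """Dense ``(n_atoms, 3)`` nm coordinates for one frame (copy)."""
        if frame == 0:
            return np.array([a.coords for _, _, a in self.iter_atoms()], dtype=float).reshape(-1, 3)
        return self._extra_frames[frame - 1].copy()

    def add_frame(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TopologyError(
                f"frame shape {coords.shape} does not match topology ({self.n_atoms} atoms)"
            )
        self._extra_frames.append(coords.copy())

    def set_coords(self, coords: np.ndarray, frame: int = 0) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TopologyError("coordinate array does not match topology")
        if frame == 0:
            for row, (_, _, atom) in zip(coords, self.iter_atoms()):
                atom.coords = row.copy()
        else:
            self._extra_frames[frame - 1] = coords.copy()

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply ``x -> R x + t`` to every frame in place."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        for f in range(self.n_frames):
            self.set_coords(self.coords_array(f) @ rotation.T + translation, frame=f)

    def copy(self) -> "Structure":
        new_chains = []
        for chain in self.chains:
            new_res = [
                Residue(
                    seq_id=r.seq_id,
                    res_name=r.res_name,
                    insertion_code=r.insertion_code,
                    kind=r.kind,
                    atoms=[
                        Atom(a.name, a.element, a.coords.copy(), a.occupancy, a.bfactor)
                        for a in r.atoms
                    ],
                )
                for r in chain.residues
            ]
            new_chains.append(Chain(chain.chain_id, new_res))
        out = Structure(self.id, new_chains)
        for f in self._extra_frames:
            out.add_frame(f)
        return out


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

_SELECTION_FIELDS = frozenset(
    {"chain_ids", "res_ids", "res_range", "res_names", "atom_names", "kinds"}
)


@dataclasses.dataclass(frozen=True)
class Selection:
    """Declarative atom filter; resolution is deterministic and order-stable.

    Every criterion is optional; an atom matches if it satisfies all the
    criteria that are set.  ``Selection()`` matches everything.
    """

    chain_ids: Optional[tuple[str, ...]] = None
    res_ids: Optional[tuple[int, ...]] = None
    res_range: Optional[tuple[int, int]] = None
    res_names: Optional[tuple[str, ...]] = None
    atom_names: Optional[tuple[str, ...]] = None
    kinds: Optional[tuple[ResidueKind, ...]] = None

    @classmethod
    def parse(cls, expr: str) -> "Selection":
        """Parse ``"chain=A,res=446-449,name=CA,resname=ZN,kind=protein"``."""
        kwargs: dict = {}
        for token in filter(None, (t.strip() for t in expr.split(","))):
            if "=" not in token:
                raise SelectionError(f"malformed selection token {token!r}")
            field, value = (s.strip() for s in token.split("=", 1))
            if field == "chain":
                kwargs.setdefault("chain_ids", [])
                kwargs["chain_ids"].extend(value.split("+"))
            elif field == "res":
                if "-" in value:
                    lo, hi = value.split("-", 1)
                    kwargs["res_range"] = (int(lo), int(hi))
                else:
                    kwargs.setdefault("res_ids", []).append(int(value))
            elif field == "resname":
                kwargs.setdefault("res_names", []).extend(value.split("+"))
            elif field == "name":
                kwargs.setdefault("atom_names", []).extend(value.split("+"))
            elif field == "kind":
                kwargs.setdefault("kinds", []).append(ResidueKind(value))
            else:
                raise SelectionError(f"unknown selection field {field!r}")
        return cls(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs.items()
            }
        )

    def matches(self, chain: Chain, res: Residue, atom: Atom) -> bool:
        if self.chain_ids is not None and chain.chain_id not in self.chain_ids:
            return False
        if self.res_ids is not None and res.seq_id not in self.res_ids:
            return False
        if self.res_range is not None and not (
            self.res_range[0] <= res.seq_id <= self.res_range[1]
        ):
            return False
        if self.res_names is not None and res.res_name not in self.res_names:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.kinds is not None and res.kind not in self.kinds:
            return False
        return True


@dataclasses.dataclass(frozen=True)
class AtomRef:
    """Resolved reference into a Structure: topology objects + flat index."""

    chain: Chain
    residue: Residue
    atom: Atom
    index: int


def select(structure: Structure, selection: Selection) -> list[AtomRef]:
    """Resolve a Selection to atoms in structure order (empty if no match)."""
    out = []
    for idx, (chain, res, atom) in enumerate(structure.iter_atoms()):
        if selection.matches(chain, res, atom):
            out.append(AtomRef(chain, res, atom, idx))
    return out


def selection_indices(structure: Structure, selection: Selection) -> np.ndarray:
    return np.array([ref.index for ref in select(structure, selection)], dtype=int)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def read_pdb(path: str, multi_model: bool = True) -> Structure:
    """Read a (possibly multi-MODEL) PDB file into a Structure.

    Coordinates are converted A -> nm.  MODEL records become frames; all
    models must share one topology (atom count and order).  Alternate
    locations: altloc ' ' or 'A' kept, others dropped.  HETATM metals parse
    as ion residues.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio = parser.get_structure("s", path)
    except PDBConstructionException as exc:
        raise PdbParseError(f"{path}: {exc}") from exc
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"{path}: malformed record ({exc})") from exc

    models = list(bio.get_models())
    if not models:
        raise PdbParseError(f"{path}: no coordinates found")
    if not multi_model:
        models = models[:1]

    def model_atoms(model):
        """Flatten one Bio.PDB model, resolving altlocs deterministically."""
        flat = []
        for bchain in model:
            for bres in bchain:
                seen = set()
                kept = []
                for batom in bres.get_unpacked_list():
                    if batom.get_altloc() not in (" ", "", "A"):
                        continue
                    if batom.get_name() in seen:
                        continue
                    seen.add(batom.get_name())
                    kept.append(batom)
                flat.append((bchain, bres, kept))
        return flat

    first = model_atoms(models[0])

    signature = [
        (bchain.id, bres.get_id(), tuple(a.get_name() for a in atoms))
        for bchain, bres, atoms in first
    ]

    chains: list[Chain] = []
    current: Optional[Chain] = None
    for bchain, bres, atoms in first:
        if current is None or current.chain_id != bchain.id:
            current = Chain(bchain.id)
            chains.append(current)
        het, seq_id, icode = bres.get_id()
        res = Residue(
            seq_id=seq_id,
            res_name=bres.get_resname().strip(),
            insertion_code=icode.strip(),
        )
        for batom in atoms:
            res.add_atom(
                Atom(
                    name=batom.get_name(),
                    element=(batom.element or element_from_name(batom.get_name())).strip(),
                    coords=np.asarray(batom.get_coord(), dtype=float) / ANGSTROM_PER_NM,
                    occupancy=batom.get_occupancy() if batom.get_occupancy() is not None else 1.0,
                    bfactor=batom.get_bfactor() if batom.get_bfactor() is not None else 0.0,
                )
            )
        current.residues.append(res)

    structure = Structure(id=bio.id if bio.id != "s" else path, chains=chains)

    for model in models[1:]:
        flat = model_atoms(model)
        sig = [
            (bchain.id, bres.get_id(), tuple(a.get_name() for a in atoms))
            for bchain, bres, atoms in flat
        ]
        if sig != signature:
            raise TopologyError(
                f"{path}: MODEL {model.id + 1} topology differs from MODEL 1"
            )
        coords = np.concatenate(
            [
                np.array([a.get_coord() for a in atoms], dtype=float).reshape(-1, 3)
                for _, _, atoms in flat
            ]
        ) / ANGSTROM_PER_NM
        structure.add_frame(coords)

    return structure


def _format_atom_name(name: str, element: str) -> str:
    """PDB columns 13-16: names start in column 14 unless 4 chars long or a
    two-letter element."""
    if len(name) >= 4 or (len(element) == 2 and name.upper().startswith(element.upper())):
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(structure: Structure, path: str) -> None:
    """Write a Structure as fixed-column PDB; multiple frames become MODELs.

    Round trip with :func:`read_pdb` preserves identifiers exactly and
    coordinates to 1e-4 nm (the format's 0.001 A precision).
    """
    for chain in structure.chains:
        if len(chain.chain_id) != 1:
            raise PdbFormatError(
                f"chain id {chain.chain_id!r} is not a single character"
            )

    lines: list[str] = []
    multi = structure.n_frames > 1
    for f in range(structure.n_frames):
        coords = structure.coords_array(f) * ANGSTROM_PER_NM
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        serial = 0
        idx = 0
        for chain in structure.chains:
            needs_ter = False
            for res in chain.residues:
                record = "ATOM  " if res.kind in (ResidueKind.PROTEIN, ResidueKind.DNA) else "HETATM"
                needs_ter = needs_ter or record == "ATOM  "
                for atom in res.atoms:
                    serial += 1
                    x, y, z = coords[idx]
                    idx += 1
                    lines.append(
                        f"{record}{serial % 100000:5d} "
                        f"{_format_atom_name(atom.name, atom.element)}"
                        f" {res.res_name:>3s} {chain.chain_id}"
                        f"{res.seq_id:4d}{res.insertion_code or ' ':1s}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                        f"          {atom.element:>2s}"
                    )
            if needs_ter:
                serial += 1
                lines.append(f"TER   {serial % 100000:5d}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
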