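"""Simulation-setup artifacts: Zn-site restraints, ion counts, manifest.

The zinc ions of the nuclease HNH site (three histidines) and of each
Cys2His2 finger are held by harmonic distance restraints during MD:
Zn-N(His) at r0 = 0.209 nm with k = 14,710 kJ/mol/nm^2 and Zn-S(Cys) at
r0 = 0.231 nm with k = 18,150 kJ/mol/nm^2, with the GROMOS half-k
convention E = 1/2 k (r - r0)^2.  This module emits those terms for any
structure, computes neutralization + 0.2 M NaCl ion counts, and writes a
manifest of the remaining protocol parameters.  It does not run dynamics.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import InputError
from .structure import AtomRef, ResidueKind, Selection, Structure, select

ZN_N_R0, ZN_N_K = 0.209, 14710.0  # Zn-N(His), nm / kJ mol^-1 nm^-2
ZN_S_R0, ZN_S_K = 0.231, 18150.0  # Zn-S(Cys)

#: His side-chain nitrogens and Cys sulfur eligible for Zn coordination.
HIS_N_ATOMS = ("ND1", "NE2")
CYS_S_ATOMS = ("SG",)

#: mol/L of pure water; converts a water count to a solution volume.
WATER_MOLARITY = 55.345


@dataclasses.dataclass(frozen=True)
class RestraintTerm:
    """One harmonic distance restraint between two atoms."""

    atom_i: tuple[str, int, str]  # (chain, seq_id, atom name) of the Zn
    atom_j: tuple[str, int, str]  # ligand atom
    r0: float  # nm
    k: float  # kJ mol^-1 nm^-2

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.k <= 0:
            raise InputError("restraint r0 and k must be positive")


def zn_site_restraints(
    s: Structure, capture_radius: float = 0.3
) -> list[RestraintTerm]:
    """Harmonic terms for every Zn ion's His-N and Cys-S ligands.

    Ligand atoms within ``capture_radius`` of a Zn get a term with the
    published (r0, k) for their type.  A structure without Zn, or a Zn with
    no ligands in range, produces a warning rather than an error.
    """
    zincs = select(s, Selection(res_names=("ZN",)))
    if not zincs:
        warnings.warn("no ZN ions in structure; no restraints emitted", stacklevel=2)
        return []
    terms: list[RestraintTerm] = []
    for zn in zincs:
        found = 0
        for chain, res, atom in s.iter_atoms():
            if res.kind != ResidueKind.PROTEIN:
                continue
            if res.res_name == "HIS" and atom.name in HIS_N_ATOMS:
                r0, k = ZN_N_R0, ZN_N_K
            elif res.res_name == "CYS" and atom.name in CYS_S_ATOMS:
                r0, k = ZN_S_R0, ZN_S_K
            else:
                continue
            if np.linalg.norm(atom.coords - zn.atom.coords) <= capture_radius:
                terms.append(
                    RestraintTerm(
                        atom_i=(zn.chain.chain_id, zn.residue.seq_id, zn.atom.name),
                        atom_j=(chain.chain_id, res.seq_id, atom.name),
                        r0=r0,
                        k=k,
                    )
                )
                found += 1
        if found == 0:
            warnings.warn(
                f"Zn at {zn.chain.chain_id}:{zn.residue.seq_id} has no His-N/Cys-S "
                f"ligand within {capture_radius} nm",
                stacklevel=2,
            )
    return terms


def restraint_energy(term: RestraintTerm, r: float) -> float:
    """E(r) = 1/2 k (r - r0)^2, kJ/mol (half-k GROMOS convention)."""
    if r < 0:
        raise InputError("distance must be non-negative")
    return 0.5 * term.k * (r - term.r0) ** 2


def restraint_gradient(term: RestraintTerm, r: float) -> float:
    """dE/dr = k (r - r0), kJ mol^-1 nm^-1."""
    return term.k * (r - term.r0)


def ion_counts(
    net_charge: int, n_waters: int, conc_M: float = 0.2
) -> tuple[int, int]:
    """(n_Na, n_Cl) to neutralize and reach the target NaCl concentration.

    Neutralization adds |net_charge| counter-ions; the salt concentration
    then exchanges ``round(conc * n_waters / 55.345)`` waters per ion of an
    Na/Cl pair.  Always satisfies n_Na - n_Cl = -net_charge.
    """
    if n_waters <= 0:
        raise InputError("water count must be positive")
    if conc_M < 0:
        raise InputError("concentration must be non-negative")
    pairs = round(conc_M * n_waters / WATER_MOLARITY)
    n_na = pairs + max(0, -net_charge)
    n_cl = pairs + max(0, net_charge)
    return n_na, n_cl


@dataclasses.dataclass
class MdManifest:
    """The MD protocol parameters the simulations used (documentation only)."""

    duration_ns: float = 10.0
    temperature_K: float = 298.0
    pressure_atm: float = 1.0
    nacl_M: float = 0.2
    solute_wall_nm: float = 0.9
    solute_solvent_nm: float = 0.23
    compressibility: float = 4.575e-4  # (kJ/mol/nm^3)^-1
    thermalization_steps_ps: tuple = (20, 20, 20, 20, 20, 20)  # 5 ramps + 298 K
    temperature_relaxation_ps: float = 0.1
    pressure_relaxation_ps: float = 0.5
    shake_tol: float = 1e-4
    force_field: str = "GROMOS 45A4"

    def __post_init__(self) -> None:
        for field in (
            "duration_ns", "temperature_K", "pressure_atm", "solute_wall_nm",
            "solute_solvent_nm", "compressibility", "shake_tol",
        ):
            if getattr(self, field) <= 0:
                raise InputError(f"manifest field {field} must be positive")


def emit_manifest(
    m: MdManifest,
    restraints: Sequence[RestraintTerm] = (),
    ions: Optional[tuple[int, int]] = None,
    path: str = "manifest.yaml",
) -> None:
    """Serialize manifest + restraints + ion counts as YAML (lossless)."""
    doc = dataclasses.asdict(m)
    doc["thermalization_steps_ps"] = list(m.thermalization_steps_ps)
    doc["restraints"] = [
        {
            "atom_i": list(t.atom_i),
            "atom_j": list(t.atom_j),
            "r0_nm": t.r0,
            "k_kj_mol_nm2": t.k,
        }
        for t in restraints
    ]
    if ions is not None:
        doc["ions"] = {"n_Na": int(ions[0]), "n_Cl": int(ions[1])}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_manifest(path: str) -> tuple[MdManifest, list[RestraintTerm], Optional[tuple[int, int]]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    restraints = [
        RestraintTerm(
            atom_i=tuple(t["atom_i"]),
            atom_j=tuple(t["atom_j"]),
            r0=t["r0_nm"],
            k=t["k_kj_mol_nm2"],
        )
        for t in doc.pop("restraints", [])
    ]
    ions_doc = doc.pop("ions", None)
    ions = (ions_doc["n_Na"], ions_doc["n_Cl"]) if ions_doc else None
    doc["thermalization_steps_ps"] = tuple(doc["thermalization_steps_ps"])
    return MdManifest(**doc), restraints, ions


def write_restraints_tsv(restraints: Sequence[RestraintTerm], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chain_i\tres_i\tatom_i\tchain_j\tres_j\tatom_j\tr0_nm\tk_kj_mol_nm2\n")
        for t in restraints:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (*t.atom_i, *t.atom_j, f"{t.r0:.4f}", f"{t.k:.1f}")
                )
                + "\n"
            )
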