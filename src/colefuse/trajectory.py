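"""Ensemble geometry analysis.

Implements the observables used to judge the designed nucleases over MD
coordinate ensembles: RMSD/RMSF/radius of gyration for overall stability,
hydrogen bonds, the four catalytic-geometry series (the N560-H545 contact
that keeps the general base oriented, the H545-V555 hydrogen bond, the
Zn-O coordination to the scissile phosphate, and the controlling-arginine
NE to scissile-P distance), plus pairwise protein-DNA interaction energies
and block averaging for trajectory means.

Ensembles are multi-model PDB; the residue mapping from the nuclease
numbering (R447, H545, V555, N560) onto a given model is explicit user
input, never inferred.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyInputError, InputError, MappingError, ParameterError
from .structure import (
    AtomRef,
    Residue,
    ResidueKind,
    Selection,
    Structure,
    select,
    selection_indices,
)
from .superpose import kabsch

COULOMB_CONSTANT = 138.935  # kJ mol^-1 nm e^-2


@dataclasses.dataclass
class Ensemble:
    """Ordered coordinate frames over one topology.

    ``frames`` is (n_frames, n_atoms, 3) in nm; the topology's own frames
    are the default source.  PDB files carry no time axis, so the frame
    spacing is supplied explicitly.
    """

    topology: Structure
    frames: np.ndarray
    time_step_ps: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise InputError("frames incongruent with topology")

    @classmethod
    def from_structure(cls, s: Structure, time_step_ps: float = 1.0) -> "Ensemble":
        frames = np.stack([s.coords_array(f) for f in range(s.n_frames)])
        return cls(topology=s, frames=frames, time_step_ps=time_step_ps)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.time_step_ps


# ---------------------------------------------------------------------------
# RMSD / RMSF / Rgyr
# ---------------------------------------------------------------------------


def rmsd_series(
    e: Ensemble,
    ref_frame: int = 0,
    sel: Optional[Selection] = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference frame over a selection.

    With ``fit=True`` each frame is least-squares superposed onto the
    reference over the same selection first, so rigid-body motion does not
    contribute.
    """
    sel = sel or Selection()
    idx = selection_indices(e.topology, sel)
    if idx.size == 0:
        raise EmptyInputError("selection matches no atoms")
    if fit and idx.size < 3:
        raise InputError("fitted RMSD needs >= 3 selected atoms")
    ref = e.frames[ref_frame][idx]
    out = np.empty(e.n_frames)
    for f in range(e.n_frames):
        mob = e.frames[f][idx]
        if fit:
            out[f] = kabsch(ref, mob).rmsd
        else:
            out[f] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out


def rmsf_profile(
    e: Ensemble,
    sel: Optional[Selection] = None,
    fit: bool = True,
    renumber_from: Optional[int] = None,
) -> list[tuple[tuple[str, int], float]]:
    """Per-residue RMSF (nm) about the ensemble-mean positions.

    Frames are optionally fitted to frame 0 over the selection before the
    fluctuation is taken; per-atom fluctuations are averaged within each
    residue over its selected atoms.  ``renumber_from`` relabels residues
    1..n for cross-model comparison of equivalent segments (e.g. the
    45-residue HNH motif reported as 1-45); coordinates are untouched.
    """
    sel = sel or Selection()
    refs = select(e.topology, sel)
    if not refs:
        raise EmptyInputError("selection matches no atoms")
    idx = np.array([r.index for r in refs])
    if e.n_frames == 1:
        warnings.warn("single-frame ensemble: RMSF is identically zero", stacklevel=2)

    frames = e.frames[:, idx, :].copy()
    if fit and idx.size >= 3:
        ref = frames[0]
        for f in range(e.n_frames):
            fitres = kabsch(ref, frames[f])
            frames[f] = fitres.apply(frames[f])
    mean = frames.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))

    order: list[tuple[str, int]] = []
    groups: dict[tuple[str, int], list[float]] = {}
    for ref_atom, val in zip(refs, per_atom):
        key = (ref_atom.chain.chain_id, ref_atom.residue.seq_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(float(val))
    out = [(key, float(np.mean(groups[key]))) for key in order]
    if renumber_from is not None:
        out = [
            ((key[0], renumber_from + i), val) for i, (key, val) in enumerate(out)
        ]
    return out


def radius_of_gyration(
    e_or_structure,
    frame: int = 0,
    sel: Optional[Selection] = None,
    mass_weighted: bool = True,
) -> float:
    """sqrt(sum m_i |r_i - r_com|^2 / sum m_i) over the selection, nm."""
    sel = sel or Selection()
    if isinstance(e_or_structure, Ensemble):
        topo, coords = e_or_structure.topology, e_or_structure.frames[frame]
    else:
        topo, coords = e_or_structure, e_or_structure.coords_array(frame)
    refs = select(topo, sel)
    if not refs:
        raise EmptyInputError("selection matches no atoms")
    idx = np.array([r.index for r in refs])
    x = coords[idx]
    m = (
        np.array([r.atom.mass for r in refs])
        if mass_weighted
        else np.ones(len(refs))
    )
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((x - com) ** 2, axis=1)).sum() / m.sum()))


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    With explicit hydrogens: H...A <= ha_max and D-H-A angle >= angle_min.
    Crystal structures lack hydrogens, so a heavy-atom fallback (D...A <=
    da_max) applies automatically when no H is bonded to the donor.
    """

    da_max: float = 0.35  # nm, donor-acceptor
    ha_max: float = 0.25  # nm, hydrogen-acceptor
    angle_min: float = 135.0  # degrees, donor-H-acceptor

    def __post_init__(self) -> None:
        if not (self.da_max > self.ha_max > 0):
            raise InputError("require da_max > ha_max > 0")
        if not (0 < self.angle_min <= 180):
            raise InputError("angle_min must be in (0, 180]")


def _bonded_hydrogens(topo: Structure, coords: np.ndarray, donor: AtomRef) -> list[int]:
    """Hydrogens of the donor's residue within covalent range (0.12 nm)."""
    out = []
    for idx, (chain, res, atom) in enumerate(topo.iter_atoms()):
        if res is donor.residue and atom.element.upper() == "H":
            if np.linalg.norm(coords[idx] - coords[donor.index]) <= 0.12:
                out.append(idx)
    return out


def detect_hbonds(
    topo: Structure,
    coords: np.ndarray,
    donors: Sequence[AtomRef],
    acceptors: Sequence[AtomRef],
    crit: HBondCriterion = HBondCriterion(),
) -> list[tuple[AtomRef, AtomRef]]:
    """Hydrogen bonds between donor and acceptor heavy atoms in one frame.

    Donors/acceptors are heavy-atom references; apolar atoms (anything but
    N, O, S, P) are ignored even if selected, so carbon-only groups can
    never bond.  Same-residue pairs are never reported; the output is
    deduplicated and frame-order stable.
    """
    polar = {"N", "O", "S", "P"}
    donors = [d for d in donors if d.atom.element.upper() in polar]
    acceptors = [a for a in acceptors if a.atom.element.upper() in polar]
    bonds: list[tuple[AtomRef, AtomRef]] = []
    seen: set[tuple[int, int]] = set()
    for d in donors:
        hydrogens = _bonded_hydrogens(topo, coords, d)
        for a in acceptors:
            if a.residue is d.residue:
                continue
            key = (d.index, a.index)
            if key in seen:
                continue
            da = float(np.linalg.norm(coords[a.index] - coords[d.index]))
            if da > crit.da_max:
                continue
            if hydrogens:
                ok = False
                for h in hydrogens:
                    ha = float(np.linalg.norm(coords[a.index] - coords[h]))
                    if ha > crit.ha_max:
                        continue
                    v1 = coords[d.index] - coords[h]
                    v2 = coords[a.index] - coords[h]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    if angle >= crit.angle_min:
                        ok = True
                        break
                if not ok:
                    continue
            seen.add(key)
            bonds.append((d, a))
    return bonds


def hbond_count_series(
    e: Ensemble,
    donors_sel: Selection,
    acceptors_sel: Selection,
    crit: HBondCriterion = HBondCriterion(),
    symmetric: bool = False,
) -> np.ndarray:
    """Per-frame count of H-bonds between two atom groups.

    ``symmetric=True`` also counts bonds donated by the second group to the
    first (deduplicated on unordered atom pairs).
    """
    donors = select(e.topology, donors_sel)
    acceptors = select(e.topology, acceptors_sel)
    out = np.zeros(e.n_frames, dtype=int)
    for f in range(e.n_frames):
        bonds = detect_hbonds(e.topology, e.frames[f], donors, acceptors, crit)
        pairs = {frozenset((d.index, a.index)) for d, a in bonds}
        if symmetric:
            rev = detect_hbonds(e.topology, e.frames[f], acceptors, donors, crit)
            pairs |= {frozenset((d.index, a.index)) for d, a in rev}
        out[f] = len(pairs)
    return out


# ---------------------------------------------------------------------------
# Catalytic-geometry observables
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CatalyticMapping:
    """Where the catalytic roles live in the analyzed model.

    Each entry is (chain_id, seq_id); the model numbering generally differs
    from the nuclease's native 446-576, so the mapping is explicit input.
    """

    arg447: tuple[str, int]
    his545: tuple[str, int]
    val555: tuple[str, int]
    asn560: tuple[str, int]
    zinc: tuple[str, int]
    scissile_p: tuple[str, int]  # residue carrying the scissile phosphate
    scissile_o_name: str = "OP1"  # phosphate oxygen coordinated by Zn


def _resolve_atom(topo: Structure, ref: tuple[str, int], atom_name: str, role: str) -> int:
    chain = topo.chain(ref[0])
    res = chain.residue(ref[1]) if chain else None
    atom = res.atom(atom_name) if res else None
    if atom is None:
        raise MappingError(
            f"{role}: atom {atom_name} of residue {ref[0]}:{ref[1]} not in topology"
        )
    for idx, (c, r, a) in enumerate(topo.iter_atoms()):
        if r is res and a is atom:
            return idx
    raise MappingError(f"{role}: resolution failed")  # pragma: no cover


def catalytic_observables(
    e: Ensemble,
    mapping: CatalyticMapping,
    crit: HBondCriterion = HBondCriterion(),
) -> dict[str, np.ndarray]:
    """The four catalytic series, one row per frame, distances in nm.

    - ``d_N560CG_H545CA``: CG of the conserved asparagine to CA of the
      general-base histidine (its increase flags loop rearrangement).
    - ``hb_H545_V555``: 0/1 presence of the H-bond orienting the general
      base (His ring N donor to Val backbone O).
    - ``d_Zn_O``: catalytic zinc to scissile-phosphate oxygen.
    - ``d_ArgNE_P``: controlling-arginine NE to scissile phosphorus.
    """
    i_cg = _resolve_atom(e.topology, mapping.asn560, "CG", "N560 equivalent")
    i_ca = _resolve_atom(e.topology, mapping.his545, "CA", "H545 equivalent")
    i_zn = _resolve_atom(e.topology, mapping.zinc, "ZN", "Zn ion")
    i_o = _resolve_atom(
        e.topology, mapping.scissile_p, mapping.scissile_o_name, "scissile O"
    )
    i_p = _resolve_atom(e.topology, mapping.scissile_p, "P", "scissile P")
    i_ne = _resolve_atom(e.topology, mapping.arg447, "NE", "R447 equivalent")

    his_sel = Selection(
        chain_ids=(mapping.his545[0],),
        res_ids=(mapping.his545[1],),
        atom_names=("ND1", "NE2"),
    )
    val_sel = Selection(
        chain_ids=(mapping.val555[0],),
        res_ids=(mapping.val555[1],),
        atom_names=("O",),
    )
    donors = select(e.topology, his_sel)
    acceptors = select(e.topology, val_sel)
    if not donors:
        raise MappingError("H545 equivalent: no ring nitrogens (ND1/NE2) found")
    if not acceptors:
        raise MappingError("V555 equivalent: backbone O not found")

    def dist(i: int, j: int) -> np.ndarray:
        return np.linalg.norm(e.frames[:, i] - e.frames[:, j], axis=1)

    hb = np.array(
        [
            1 if detect_hbonds(e.topology, e.frames[f], donors, acceptors, crit) else 0
            for f in range(e.n_frames)
        ],
        dtype=int,
    )
    return {
        "d_N560CG_H545CA": dist(i_cg, i_ca),
        "hb_H545_V555": hb,
        "d_Zn_O": dist(i_zn, i_o),
        "d_ArgNE_P": dist(i_ne, i_p),
    }


# ---------------------------------------------------------------------------
# Interaction energies
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class NonbondedParams:
    """Per-atom partial charges and Lennard-Jones C6/C12 coefficients.

    Keyed by (chain_id, seq_id, atom_name); a fallback keyed by atom name
    alone may be supplied for generic parameter sets.  Units: e, kJ/mol
    nm^6, kJ/mol nm^12.
    """

    by_atom: dict = dataclasses.field(default_factory=dict)
    by_name: dict = dataclasses.field(default_factory=dict)
    relative_permittivity: float = 1.0

    def lookup(self, ref: AtomRef) -> tuple[float, float, float]:
        key = (ref.chain.chain_id, ref.residue.seq_id, ref.atom.name)
        if key in self.by_atom:
            return self.by_atom[key]
        if ref.atom.name in self.by_name:
            return self.by_name[ref.atom.name]
        raise ParameterError(f"no nonbonded parameters for atom {key}")

    @classmethod
    def from_tsv(cls, path: str, relative_permittivity: float = 1.0) -> "NonbondedParams":
        """Read ``atom_key charge C6 C12`` rows; atom_key is either
        ``chain:resid:name`` or a bare atom name."""
        by_atom, by_name = {}, {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#") or line.startswith("atom_key"):
                    continue
                key, q, c6, c12 = line.split()
                params = (float(q), float(c6), float(c12))
                if ":" in key:
                    chain, resid, name = key.split(":")
                    by_atom[(chain, int(resid), name)] = params
                else:
                    by_name[key] = params
        return cls(by_atom=by_atom, by_name=by_name,
                   relative_permittivity=relative_permittivity)


def interaction_energy(
    topo: Structure,
    coords: np.ndarray,
    group_a: Selection,
    group_b: Selection,
    params: NonbondedParams,
    cutoff: Optional[float] = None,
) -> tuple[float, float, float]:
    """(vdW, electrostatic, total) kJ/mol between two atom groups.

    Plain pairwise sums over inter-group pairs: Coulomb
    f q_i q_j / (eps_r r) with f = 138.935 kJ mol^-1 nm e^-2, plus
    C12/r^12 - C6/r^6.  Atoms in both groups are counted once per
    unordered pair.  ``cutoff`` optionally drops pairs beyond a distance.
    """
    refs_a = select(topo, group_a)
    refs_b = select(topo, group_b)
    if not refs_a or not refs_b:
        raise EmptyInputError("interaction groups must be non-empty")
    pa = np.array([params.lookup(r) for r in refs_a])
    pb = np.array([params.lookup(r) for r in refs_b])
    ia = np.array([r.index for r in refs_a])
    ib = np.array([r.index for r in refs_b])

    diff = coords[ia][:, None, :] - coords[ib][None, :, :]
    r = np.linalg.norm(diff, axis=2)
    # self-pairs dropped; a pair with both atoms in A∩B is seen from both
    # orientations and gets weight 1/2, so every unordered pair counts once
    mask = np.ones_like(r, dtype=bool)
    weight = np.ones_like(r)
    set_a, set_b = set(ia.tolist()), set(ib.tolist())
    if set_a & set_b:
        for i_pos, x in enumerate(ia.tolist()):
            for j_pos, y in enumerate(ib.tolist()):
                if x == y:
                    mask[i_pos, j_pos] = False
                elif x in set_b and y in set_a:
                    weight[i_pos, j_pos] = 0.5
    if cutoff is not None:
        mask &= r <= cutoff
    r = np.where(mask, r, np.inf)

    qq = pa[:, 0:1] * pb[None, :, 0]
    elec = COULOMB_CONSTANT * np.where(
        mask, weight * qq / (params.relative_permittivity * r), 0.0
    )
    c6 = np.sqrt(pa[:, 1:2] * pb[None, :, 1])
    c12 = np.sqrt(pa[:, 2:3] * pb[None, :, 2])
    inv6 = np.where(mask, r**-6, 0.0)
    vdw = weight * (c12 * inv6**2 - c6 * inv6)
    e_vdw = float(vdw.sum())
    e_elec = float(elec.sum())
    return e_vdw, e_elec, e_vdw + e_elec


def block_average(series: Sequence[float], n_blocks: int = 5) -> tuple[float, float]:
    """(mean, standard error over block means) for a trajectory series."""
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise InputError("need at least 2 blocks")
    if x.size < n_blocks:
        raise InputError("series shorter than the number of blocks")
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(x.mean()), float(means.std(ddof=1) / np.sqrt(n_blocks))
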