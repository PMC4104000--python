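"""Seeded synthetic inputs: idealized B-DNA, toy complexes, libraries, trajectories.

Every generator is a pure function of its spec (and seed), so tests and the
command line get reproducible structures without downloading the crystal
structures.  The DNA uses a reduced per-nucleotide representation (P, C1',
glycosidic base nitrogen) on an ideal helix — enough for window
superposition and heavy-atom H-bond work, deliberately not a physical
double helix (no sugar pucker, no groove asymmetry, no sequence-dependent
geometry).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .errors import AlphabetError, InputError
from .linkers import CA_CA_MAX, CA_CA_MIN, BackboneFragment, FragmentLibrary
from .structure import Atom, Chain, Residue, Structure
from .trajectory import Ensemble

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
DNA_RES = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}

#: Purines carry N9 as the glycosidic nitrogen, pyrimidines N1.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}


@dataclasses.dataclass(frozen=True)
class BdnaSpec:
    """Ideal B-DNA helix parameters and a reduced atom representation."""

    sequence: str
    rise: float = 0.34  # nm per base pair
    twist: float = 36.0  # degrees per base pair
    p_radius: float = 0.92  # nm, backbone phosphorus
    c1_radius: float = 0.58  # nm, glycosidic carbon
    n_radius: float = 0.30  # nm, base nitrogen
    strand2_phase: float = 154.0  # degrees between the two glycosidic bonds

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise InputError("sequence must have >= 2 bases")
        if set(self.sequence.upper()) - set("ACGT"):
            raise AlphabetError(f"non-ACGT character in {self.sequence!r}")


def _helical_atom(radius: float, phase_deg: float, z: float) -> np.ndarray:
    phi = np.radians(phase_deg)
    return np.array([radius * np.cos(phi), radius * np.sin(phi), z])


def build_bdna(spec: BdnaSpec, chain_ids: tuple[str, str] = ("A", "B")) -> Structure:
    """Two antiparallel strands on an ideal helix.

    Strand 1 runs 5'->3' with base pair i at z = i*rise, twist i*36 deg;
    strand 2 carries the complement and is stored 5'->3' in its own
    direction (i.e. reversed), so pairing is positional: strand1[i] with
    strand2[n-1-i].  The ideal helix is invariant under the (rise, twist)
    screw transform, so equal-length windows anywhere along the duplex are
    exactly superposable.
    """
    seq = spec.sequence.upper()
    n = len(seq)
    strand1 = Chain(chain_ids[0])
    strand2_rev: list[Residue] = []
    for i, base in enumerate(seq):
        z = i * spec.rise
        theta = i * spec.twist
        comp = COMPLEMENT[base]
        res1 = Residue(seq_id=i + 1, res_name=DNA_RES[base])
        res1.add_atom(Atom("P", "P", _helical_atom(spec.p_radius, theta, z)))
        res1.add_atom(Atom("C1'", "C", _helical_atom(spec.c1_radius, theta + 25.0, z)))
        res1.add_atom(
            Atom(GLYCOSIDIC_N[base], "N", _helical_atom(spec.n_radius, theta + 40.0, z))
        )
        strand1.residues.append(res1)

        phase2 = theta + spec.strand2_phase
        res2 = Residue(seq_id=i + 1, res_name=DNA_RES[comp])
        res2.add_atom(Atom("P", "P", _helical_atom(spec.p_radius, phase2 + 25.0, z)))
        res2.add_atom(Atom("C1'", "C", _helical_atom(spec.c1_radius, phase2, z)))
        res2.add_atom(
            Atom(GLYCOSIDIC_N[comp], "N", _helical_atom(spec.n_radius, phase2 - 15.0, z))
        )
        strand2_rev.append(res2)

    strand2 = Chain(chain_ids[1])
    for j, res in enumerate(reversed(strand2_rev)):
        strand2.residues.append(dataclasses.replace(res, seq_id=j + 1))

    return Structure(id=f"bdna:{seq}", chains=[strand1, strand2])


# ---------------------------------------------------------------------------
# Toy protein-DNA complexes with Zn sites
# ---------------------------------------------------------------------------

HNH_SITE = ("HIS", "HIS", "HIS")
ZF_SITE = ("HIS", "HIS", "CYS", "CYS")

#: Coordination distances placed by the generator (nm).
ZN_LIGAND_DIST = {"HIS": 0.209, "CYS": 0.231}
ZN_LIGAND_ATOM = {"HIS": "NE2", "CYS": "SG"}

_TETRAHEDRAL = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def make_toy_complex(
    dna_spec: BdnaSpec,
    protein_size: int = 20,
    zn_sites: Sequence[Sequence[str]] = (HNH_SITE,),
    seed: int = 0,
    protein_chain_id: str = "P",
) -> Structure:
    """A toy protein placed alongside ideal B-DNA, with coordinated Zn ions.

    The protein is a smooth backbone trace (complete N, CA, C, O per
    residue) offset from the helix axis on the major-groove side.  Each
    requested Zn site appends its ligand residues (His with NE2, Cys with
    SG) at the generator's coordination distances around a Zn ion, plus a
    CA so the residues look like amino acids.  Seeded jitter keeps repeated
    builds identical for the same seed.
    """
    rng = np.random.default_rng(seed)
    s = build_bdna(dna_spec)

    chain = Chain(protein_chain_id)
    axis_offset = np.array([1.6, 0.0, 0.0])
    for i in range(protein_size):
        t = i * 0.35
        ca = axis_offset + np.array(
            [0.25 * np.cos(1.3 * t), 0.25 * np.sin(1.3 * t), t * 0.6]
        )
        res = Residue(seq_id=i + 1, res_name="ALA")
        res.add_atom(Atom("N", "N", ca + np.array([-0.12, 0.05, -0.04])))
        res.add_atom(Atom("CA", "C", ca))
        res.add_atom(Atom("C", "C", ca + np.array([0.12, 0.05, 0.04])))
        res.add_atom(Atom("O", "O", ca + np.array([0.16, 0.16, 0.02])))
        chain.residues.append(res)
    s.chains.append(chain)

    zchain = Chain("Z")
    lchain = Chain("L")
    next_res = 1
    for site_idx, site in enumerate(zn_sites):
        for lig in site:
            if lig not in ZN_LIGAND_DIST:
                raise InputError(f"unsupported Zn ligand {lig!r}")
        center = np.array([2.6 + 1.5 * site_idx, 1.5, 0.5]) + rng.normal(0, 0.02, 3)
        zres = Residue(seq_id=site_idx + 1, res_name="ZN")
        zres.add_atom(Atom("ZN", "ZN", center))
        zchain.residues.append(zres)
        for k, lig in enumerate(site):
            direction = _TETRAHEDRAL[k % 4]
            pos = center + ZN_LIGAND_DIST[lig] * direction
            res = Residue(seq_id=next_res, res_name=lig)
            next_res += 1
            atom_name = ZN_LIGAND_ATOM[lig]
            res.add_atom(Atom(atom_name, atom_name[0], pos))
            res.add_atom(Atom("CA", "C", center + 0.55 * direction))
            lchain.residues.append(res)
    if zchain.residues:
        s.chains.append(lchain)
        s.chains.append(zchain)
    s.id = f"toy:{dna_spec.sequence}:{seed}"
    return s


# ---------------------------------------------------------------------------
# Toy trajectories
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ToyTrajectorySpec:
    """Frames = drift^t(base) + iid Gaussian noise, seeded."""

    base: Structure
    n_frames: int = 10
    noise_sigma: float = 0.0  # nm
    drift_rotation: Optional[np.ndarray] = None  # 3x3 per-frame rotation
    drift_translation: Optional[np.ndarray] = None  # nm per frame
    seed: int = 0
    time_step_ps: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise InputError("need >= 1 frame")
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be non-negative")


def make_toy_trajectory(spec: ToyTrajectorySpec) -> Ensemble:
    """Seeded ensemble: frame t applies the rigid drift t times, then noise."""
    rng = np.random.default_rng(spec.seed)
    base = spec.base.coords_array(0)
    rot = np.eye(3) if spec.drift_rotation is None else np.asarray(spec.drift_rotation)
    trans = (
        np.zeros(3)
        if spec.drift_translation is None
        else np.asarray(spec.drift_translation)
    )
    frames = np.empty((spec.n_frames, base.shape[0], 3))
    current_r, current_t = np.eye(3), np.zeros(3)
    for f in range(spec.n_frames):
        coords = base @ current_r.T + current_t
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        frames[f] = coords
        current_r = rot @ current_r
        current_t = rot @ current_t + trans
    return Ensemble(topology=spec.base, frames=frames, time_step_ps=spec.time_step_ps)


# ---------------------------------------------------------------------------
# Synthetic fragment libraries
# ---------------------------------------------------------------------------

#: Ideal alpha-helix backbone parameters (radius nm, rise nm, twist deg).
_HELIX = dict(radius=0.23, rise=0.15, twist=100.0)


def _helix_backbone(length: int, phase: float = 0.0) -> np.ndarray:
    """(L, 4, 3) ideal-helical backbone; CA on the helix, N/C/O offset."""
    out = np.empty((length, 4, 3))
    for i in range(length):
        theta = np.radians(phase + i * _HELIX["twist"])
        z = i * _HELIX["rise"]
        ca = np.array(
            [_HELIX["radius"] * np.cos(theta), _HELIX["radius"] * np.sin(theta), z]
        )
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.6])
        tangent /= np.linalg.norm(tangent)
        out[i, 0] = ca - 0.145 * tangent  # N
        out[i, 1] = ca
        out[i, 2] = ca + 0.152 * tangent  # C
        out[i, 3] = ca + 0.152 * tangent + np.array([0.0, 0.0, 0.123])  # O
    return out


def _extended_backbone(length: int, wobble: float = 0.05) -> np.ndarray:
    out = np.empty((length, 4, 3))
    for i in range(length):
        ca = np.array([0.36 * i, wobble * (-1) ** i, 0.0])
        out[i, 0] = ca + np.array([-0.13, 0.05, 0.0])
        out[i, 1] = ca
        out[i, 2] = ca + np.array([0.13, 0.05, 0.0])
        out[i, 3] = ca + np.array([0.13, 0.05, 0.123])
    return out


def make_fragment_library(
    n_fragments: int = 100,
    length_range: tuple[int, int] = (3, 8),
    geometry: str = "mixed",
    seed: int = 0,
    jitter: float = 0.01,
) -> FragmentLibrary:
    """Seeded decoy library of helical/extended backbone fragments.

    Each fragment gets a random length in ``length_range``, a random phase,
    a random rigid placement and small coordinate jitter; chain-continuity
    invariants always hold.  Deterministic under the seed.
    """
    if geometry not in ("helix", "extended", "mixed"):
        raise InputError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)
    lib = FragmentLibrary(
        metadata={"generator": "synthetic", "geometry": geometry, "seed": seed}
    )
    for i in range(n_fragments):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        kind = geometry if geometry != "mixed" else ("helix", "extended")[i % 2]
        if kind == "helix":
            bb = _helix_backbone(length, phase=float(rng.uniform(0, 360)))
        else:
            bb = _extended_backbone(length, wobble=float(rng.uniform(0.02, 0.08)))
        if jitter > 0:
            # re-draw jitter (seeded) until chain continuity survives it
            for attempt in range(10):
                trial = bb + rng.normal(0.0, jitter, bb.shape)
                d = np.linalg.norm(np.diff(trial[:, 1], axis=0), axis=1)
                if np.all((d >= CA_CA_MIN) & (d <= CA_CA_MAX)):
                    bb = trial
                    break
        # random proper rotation + translation
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        bb = bb @ rot.T + rng.uniform(-2, 2, 3)
        lib.fragments.append(BackboneFragment(bb, source_id=f"syn{i:05d}"))
    return lib


def bridge_interior(anchors, n_interior: int) -> np.ndarray:
    """(n_interior, 4, 3) backbone interpolated between two anchors.

    Linear interpolation of each backbone atom between the anchor residues
    — geometrically naive but chain-continuous whenever the anchor gap fits
    the residue count, which is all the planted-solution fixtures need.
    """
    ts = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    return np.stack(
        [anchors.n_anchor + t * (anchors.c_anchor - anchors.n_anchor) for t in ts]
    )


def plant_fragment(
    lib: FragmentLibrary, anchors, interior: np.ndarray, source_id: str = "planted"
) -> BackboneFragment:
    """Insert a fragment whose termini are copies of the anchors themselves.

    Such a fragment fits the anchors with RMSD ~ 0 and must come back at
    rank 1 from a linker search — the planted-solution check.
    """
    coords = np.concatenate(
        [anchors.n_anchor[None], np.asarray(interior), anchors.c_anchor[None]]
    )
    frag = BackboneFragment(coords, source_id=source_id)
    lib.fragments.append(frag)
    return frag
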