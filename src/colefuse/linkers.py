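"""Backbone-fragment linker design.

A fragment library is produced by in-silico digestion of protein chains
into every contiguous backbone window (N, C-alpha, C, O per residue).
Candidate linkers for a fusion joint are fragments whose length falls in
the requested range, whose end-to-end distance matches the anchor gap, and
whose terminal residues superpose onto the two anchor residues within an
RMSD tolerance.  Accepted candidates are grafted into the model as
polyalanine; a position scan then proposes side chains per linker position
with a pluggable stability scorer (cysteine and proline are never
proposed: the thiol is too reactive and proline's backbone constraint is
over-rewarded by simple scoring).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .errors import EmptyInputError, GraftError, InputError, SelectionError
from .structure import (
    AA1_TO_3,
    AA3_TO_1,
    Atom,
    Chain,
    Residue,
    ResidueKind,
    Selection,
    Structure,
    select,
)
from .superpose import clash_score, kabsch, relieve_clashes

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Chain-continuity bounds on consecutive C-alpha distances (nm).
CA_CA_MIN, CA_CA_MAX = 0.2, 0.5


@dataclasses.dataclass
class BackboneFragment:
    """Contiguous backbone piece: per-residue (N, CA, C, O) coordinates, nm."""

    coords: np.ndarray  # (length, 4, 3)
    source_id: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise InputError("fragment coords must be (L, 4, 3)")
        if self.length < 2:
            raise InputError("fragments need >= 2 residues")
        ca = self.coords[:, 1]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        if np.any(d < CA_CA_MIN) or np.any(d > CA_CA_MAX):
            raise InputError(
                f"fragment {self.source_id}: CA-CA distance outside "
                f"[{CA_CA_MIN}, {CA_CA_MAX}] nm"
            )

    @property
    def length(self) -> int:
        return self.coords.shape[0]

    @property
    def end_to_end(self) -> float:
        """C-alpha(first) to C-alpha(last) distance, nm."""
        return float(np.linalg.norm(self.coords[-1, 1] - self.coords[0, 1]))

    @property
    def terminal_backbone(self) -> np.ndarray:
        """The 8 backbone atoms of the two terminal residues, (8, 3)."""
        return np.concatenate([self.coords[0], self.coords[-1]])


@dataclasses.dataclass
class FragmentLibrary:
    fragments: list[BackboneFragment] = dataclasses.field(default_factory=list)
    metadata: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def by_length(self, length: int) -> list[BackboneFragment]:
        return [f for f in self.fragments if f.length == length]

    # -- TSV serialization -------------------------------------------------
    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(self.metadata.items()):
                fh.write(f"# {key}={value}\n")
            fh.write("source_id\tlength\tcoords_nm\n")
            for frag in self.fragments:
                flat = "\t".join(f"{v:.6f}" for v in frag.coords.ravel())
                fh.write(f"{frag.source_id}\t{frag.length}\t{flat}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "FragmentLibrary":
        metadata: dict = {}
        fragments = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    metadata[key] = value
                    continue
                if not line or line.startswith("source_id"):
                    continue
                fields = line.split("\t")
                source_id, length = fields[0], int(fields[1])
                coords = np.array(fields[2:], dtype=float).reshape(length, 4, 3)
                fragments.append(BackboneFragment(coords, source_id))
        return cls(fragments, metadata)


@dataclasses.dataclass
class AnchorPair:
    """Backbone geometry of the two residues a linker must bridge.

    ``n_ref``/``c_ref`` optionally locate those residues in a model as
    (chain_id, seq_id), which grafting needs.
    """

    n_anchor: np.ndarray  # (4, 3) N, CA, C, O
    c_anchor: np.ndarray  # (4, 3)
    n_ref: Optional[tuple[str, int]] = None
    c_ref: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        self.n_anchor = np.asarray(self.n_anchor, dtype=float)
        self.c_anchor = np.asarray(self.c_anchor, dtype=float)
        if self.n_anchor.shape != (4, 3) or self.c_anchor.shape != (4, 3):
            raise InputError("anchors must each be (4, 3) backbone coordinates")
        if self.gap_distance <= 0:
            raise InputError("anchor gap distance must be positive")

    @property
    def gap_distance(self) -> float:
        return float(np.linalg.norm(self.c_anchor[1] - self.n_anchor[1]))

    @property
    def backbone(self) -> np.ndarray:
        return np.concatenate([self.n_anchor, self.c_anchor])

    @classmethod
    def from_model(
        cls, model: Structure, n_ref: tuple[str, int], c_ref: tuple[str, int]
    ) -> "AnchorPair":
        def backbone_of(ref):
            chain = model.chain(ref[0])
            res = chain.residue(ref[1]) if chain else None
            if res is None:
                raise SelectionError(f"anchor residue {ref[0]}:{ref[1]} not found")
            rows = []
            for name in BACKBONE_ATOMS:
                atom = res.atom(name)
                if atom is None:
                    raise SelectionError(
                        f"anchor residue {ref[0]}:{ref[1]} lacks backbone atom {name}"
                    )
                rows.append(atom.coords)
            return np.asarray(rows)

        return cls(backbone_of(n_ref), backbone_of(c_ref), n_ref=n_ref, c_ref=c_ref)


@dataclasses.dataclass
class LinkerCandidate:
    fragment: BackboneFragment
    anchor_rmsd: float
    end_to_end: float
    grafted_sequence: str
    transform: tuple[np.ndarray, np.ndarray]  # rotation, translation onto anchors


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------


def _backbone_runs(chain: Chain) -> list[np.ndarray]:
    """Maximal contiguous backbone stretches of one protein chain.

    A residue participates only with a complete (N, CA, C, O) set; runs are
    broken where a residue is incomplete or consecutive C-alphas violate
    the continuity bounds.
    """
    runs: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    prev_ca: Optional[np.ndarray] = None
    for res in chain.residues:
        if res.kind != ResidueKind.PROTEIN:
            continue
        atoms = [res.atom(n) for n in BACKBONE_ATOMS]
        if any(a is None for a in atoms):
            if current:
                runs.append(current)
            current, prev_ca = [], None
            continue
        bb = np.array([a.coords for a in atoms])
        if prev_ca is not None:
            d = float(np.linalg.norm(bb[1] - prev_ca))
            if not (CA_CA_MIN <= d <= CA_CA_MAX):
                runs.append(current)
                current = []
        current.append(bb)
        prev_ca = bb[1]
    if current:
        runs.append(current)
    return [np.asarray(r) for r in runs if len(r) >= 2]


def digest_structures(
    structures: Iterable[Structure], min_len: int = 3, max_len: int = 12
) -> FragmentLibrary:
    """Cut every contiguous backbone window of length [min_len, max_len].

    A chain of L complete residues yields ``sum_w max(0, L - w + 1)``
    fragments.  Structures without protein chains contribute nothing.
    """
    if min_len < 2:
        raise InputError("min_len must be >= 2")
    if max_len < min_len:
        raise InputError("max_len must be >= min_len")
    lib = FragmentLibrary(metadata={"min_len": min_len, "max_len": max_len})
    n_sources = 0
    for s in structures:
        n_sources += 1
        for chain in s.chains:
            for run_idx, run in enumerate(_backbone_runs(chain)):
                L = run.shape[0]
                for w in range(min_len, max_len + 1):
                    for start in range(L - w + 1):
                        lib.fragments.append(
                            BackboneFragment(
                                run[start : start + w],
                                source_id=f"{s.id}:{chain.chain_id}:{run_idx}:{start}+{w}",
                            )
                        )
    lib.metadata["source_count"] = n_sources
    return lib


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


def anchor_fit(fragment: BackboneFragment, anchors: AnchorPair):
    """Superpose the fragment's terminal backbone onto the anchors.

    Returns (rmsd, rotation, translation) over the 8 terminal backbone
    atoms (N, CA, C, O of both ends).
    """
    fit = kabsch(anchors.backbone, fragment.terminal_backbone)
    return fit.rmsd, fit.rotation, fit.translation


def search_linkers(
    lib: FragmentLibrary,
    anchors: AnchorPair,
    length_range: tuple[int, int],
    dist_tol: float = 0.05,
    rmsd_max: float = 0.05,
) -> list[LinkerCandidate]:
    """Filter and rank the library against one anchor pair.

    A fragment passes iff its length is in ``length_range``, its
    end-to-end distance is within ``dist_tol`` of the anchor gap, and its
    terminal residues fit the anchors within ``rmsd_max``.  Results are
    ranked by anchor RMSD ascending, ties by source_id.  The grafted
    sequence starts as polyalanine over the fragment interior.
    """
    if dist_tol <= 0 or rmsd_max <= 0:
        raise InputError("tolerances must be positive")
    lo, hi = length_range
    out: list[LinkerCandidate] = []
    for frag in lib.fragments:
        if not (lo <= frag.length <= hi):
            continue
        if abs(frag.end_to_end - anchors.gap_distance) > dist_tol:
            continue
        rmsd, rot, trans = anchor_fit(frag, anchors)
        if rmsd > rmsd_max:
            continue
        out.append(
            LinkerCandidate(
                fragment=frag,
                anchor_rmsd=rmsd,
                end_to_end=frag.end_to_end,
                grafted_sequence="A" * (frag.length - 2),
                transform=(rot, trans),
            )
        )
    out.sort(key=lambda c: (c.anchor_rmsd, c.fragment.source_id))
    return out


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------

# Ideal CB direction coefficients (applied to A-scale vectors b = CA - N,
# c = C - CA, a = b x c); standard tetrahedral reconstruction.
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta position from backbone N, CA, C (inputs/outputs in nm)."""
    nA, caA, cA = 10.0 * np.asarray(n), 10.0 * np.asarray(ca), 10.0 * np.asarray(c)
    b = caA - nA
    c_ = cA - caA
    a = np.cross(b, c_)
    cb = _CB_COEFF[0] * a + _CB_COEFF[1] * b + _CB_COEFF[2] * c_ + caA
    return cb / 10.0


def graft_linker(
    model: Structure,
    cand: LinkerCandidate,
    anchors: AnchorPair,
    clash_threshold: float = 0.05,
    relief_steps: int = 30,
    relief_step_size: float = 0.005,
) -> Structure:
    """Insert the candidate's interior residues between the anchors as ALA.

    The fragment is placed with its anchor-fit transform; interior residues
    get the fragment backbone plus an ideal C-beta.  If the anchors sit on
    two different chains the chains are fused into one, renumbered
    contiguously.  Clash relief (steepest descent, linker atoms mobile) is
    applied; a residual clash score above ``clash_threshold`` raises
    :class:`GraftError`.
    """
    if anchors.n_ref is None or anchors.c_ref is None:
        raise InputError("anchors must carry model references for grafting")
    rot, trans = cand.transform
    placed = cand.fragment.coords @ rot.T + trans  # (L, 4, 3)
    interior = placed[1:-1]

    out = model.copy()
    n_chain = out.chain(anchors.n_ref[0])
    c_chain = out.chain(anchors.c_ref[0])
    if n_chain is None or c_chain is None:
        raise SelectionError("anchor chains not found in model")
    n_idx = next(
        i for i, r in enumerate(n_chain.residues) if r.seq_id == anchors.n_ref[1]
    )
    c_idx = next(
        i for i, r in enumerate(c_chain.residues) if r.seq_id == anchors.c_ref[1]
    )

    linker_residues = []
    for bb in interior:
        res = Residue(seq_id=0, res_name="ALA")
        for name, xyz in zip(BACKBONE_ATOMS, bb):
            res.add_atom(Atom(name, name[0], xyz))
        res.add_atom(Atom("CB", "C", ideal_cb(bb[0], bb[1], bb[2])))
        linker_residues.append(res)

    if n_chain is c_chain:
        if c_idx <= n_idx:
            raise InputError("c-anchor must follow n-anchor within one chain")
        merged_residues = (
            n_chain.residues[: n_idx + 1]
            + linker_residues
            + c_chain.residues[c_idx:]
        )
        fused = Chain(n_chain.chain_id, [])
        out.chains[out.chains.index(n_chain)] = fused
    else:
        merged_residues = (
            n_chain.residues[: n_idx + 1]
            + linker_residues
            + c_chain.residues[c_idx:]
        )
        fused = Chain(n_chain.chain_id, [])
        out.chains[out.chains.index(n_chain)] = fused
        out.chains.remove(c_chain)

    start = merged_residues[0].seq_id
    fused.residues = [
        dataclasses.replace(r, seq_id=start + i, insertion_code="")
        for i, r in enumerate(merged_residues)
    ]

    linker_ids = tuple(
        start + n_idx + 1 + i for i in range(len(linker_residues))
    )
    mobile = Selection(chain_ids=(fused.chain_id,), res_ids=linker_ids)
    if linker_ids:
        out = relieve_clashes(
            out, mobile, max_steps=relief_steps, step_size=relief_step_size
        )
    _, residual = clash_score(out)
    if residual > clash_threshold:
        raise GraftError(
            f"grafting {cand.fragment.source_id} left clash score {residual:.4f} "
            f"> {clash_threshold}"
        )
    return out


# ---------------------------------------------------------------------------
# Position scan
# ---------------------------------------------------------------------------

#: Side-chain bulk proxy (nm): effective radius beyond the ideal C-beta.
SIDECHAIN_RADIUS = {
    "GLY": 0.00, "ALA": 0.05, "SER": 0.07, "THR": 0.09, "ASP": 0.10,
    "VAL": 0.10, "ASN": 0.11, "ILE": 0.12, "LEU": 0.12, "GLU": 0.12,
    "GLN": 0.13, "MET": 0.13, "HIS": 0.13, "PHE": 0.14, "LYS": 0.14,
    "ARG": 0.15, "TYR": 0.15, "TRP": 0.17,
    # excluded from scans but present for completeness
    "CYS": 0.08, "PRO": 0.09,
}

DEFAULT_EXCLUDED = frozenset({"CYS", "PRO"})

# scorer contract: (model, (chain_id, seq_id), candidate res_name) -> score
PositionScorer = Callable[[Structure, tuple[str, int], str], float]


def steric_scorer(
    model: Structure, site: tuple[str, int], res_name: str, env_radius: float = 0.1
) -> float:
    """Reference scorer: squared overlap of a side-chain probe with its
    surroundings (lower is better; strictly non-decreasing in bulk).

    The probe sits at the residue's ideal C-beta; its radius is the
    side-chain bulk proxy.  Atoms of the scanned residue itself are
    ignored.
    """
    chain = model.chain(site[0])
    res = chain.residue(site[1]) if chain else None
    if res is None:
        raise SelectionError(f"scan position {site[0]}:{site[1]} not in model")
    bb = [res.atom(n) for n in ("N", "CA", "C")]
    if any(a is None for a in bb):
        raise SelectionError(f"scan position {site[0]}:{site[1]} lacks backbone")
    probe = ideal_cb(bb[0].coords, bb[1].coords, bb[2].coords)
    radius = SIDECHAIN_RADIUS[res_name]
    score = 0.0
    for ch, other, atom in model.iter_atoms():
        if ch is chain and other is res:
            continue
        d = float(np.linalg.norm(atom.coords - probe))
        overlap = radius + env_radius - d
        if overlap > 0:
            score += overlap**2
    return score


def position_scan(
    model: Structure,
    positions: Sequence[tuple[str, int]],
    scorer: PositionScorer = steric_scorer,
    excluded: frozenset[str] = DEFAULT_EXCLUDED,
) -> dict[tuple[str, int], dict]:
    """Score every standard residue except ``excluded`` at each position.

    Returns ``{position: {"scores": {res: score}, "best": res}}``; the best
    residue is the minimum score, ties broken alphabetically.  Cysteine and
    proline never appear in the output under the default exclusion.
    """
    candidates = sorted(set(AA3_TO_1) - set(excluded))
    out: dict[tuple[str, int], dict] = {}
    for site in positions:
        chain = model.chain(site[0])
        if chain is None or chain.residue(site[1]) is None:
            raise SelectionError(f"scan position {site[0]}:{site[1]} not in model")
        scores = {res: float(scorer(model, site, res)) for res in candidates}
        best = min(candidates, key=lambda r: (scores[r], r))
        out[site] = {"scores": scores, "best": best}
    return out
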