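"""Chimera construction by exhaustive DNA-window superposition.

The fusion models are built by sliding equal-length base-pair windows over
the DNA of two protein-DNA complexes (the nuclease complex and the zinc
finger complex), rigid-body superposing the donor complex onto each window
of the acceptor, deleting the donor DNA, and ranking the merged models.
The acceptor DNA — the zinc fingers' specific site — is the one retained.

Superposition uses the Kabsch algorithm (SVD with reflection exclusion).
The model score is a steric clash proxy (the full force-field energy used
to rank models originally is pluggable via the ``scorer`` argument).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    InsufficientPointsError,
    SuperpositionAtomsError,
)
from .structure import (
    Atom,
    Chain,
    Residue,
    ResidueKind,
    Selection,
    Structure,
    select,
)

#: DNA atoms used to define a window superposition: backbone phosphorus and
#: the glycosidic sugar carbon, present in every nucleotide of both donors.
DEFAULT_SUPERPOSITION_ATOMS = ("P", "C1'")

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform mapping a mobile set onto a reference."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # nm
    rmsd: float  # nm
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> SuperpositionResult:
    """Optimal rotation/translation mapping ``coords_b`` onto ``coords_a``.

    Minimises the (weighted) RMSD; reflections are excluded so the returned
    rotation is always proper (det = +1).

    Raises
    ------
    InsufficientPointsError
        fewer than 3 points.
    DegenerateGeometryError
        collinear points (rotation about the common axis undetermined).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    cen_a = w @ a
    cen_b = w @ b
    a0 = a - cen_a
    b0 = b - cen_b

    # second singular value ~ 0 <=> points collinear
    if min(np.linalg.svd(a0 * w[:, None] ** 0.5, compute_uv=False)[1],
           np.linalg.svd(b0 * w[:, None] ** 0.5, compute_uv=False)[1]) < 1e-10:
        raise DegenerateGeometryError("point set is collinear; rotation undetermined")

    cov = (b0 * w[:, None]).T @ a0
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cen_a - rotation @ cen_b

    moved = b @ rotation.T + translation
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - a) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n)


# ---------------------------------------------------------------------------
# Duplex model and window enumeration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DnaDuplex:
    """Two antiparallel DNA chains with an explicit Watson-Crick pairing.

    ``pairing[i]`` is the (strand1 residue, strand2 residue) base pair at
    position i, ordered 5'->3' along strand1.
    """

    strand1: Chain
    strand2: Chain
    pairing: list[tuple[Residue, Residue]]

    def __len__(self) -> int:
        return len(self.pairing)

    @classmethod
    def from_structure(
        cls, s: Structure, chain1_id: str, chain2_id: str
    ) -> "DnaDuplex":
        """Infer pairing positionally: strand2 reversed against strand1.

        Mismatched lengths fall back to geometric pairing by C1'-C1'
        proximity (< 1.2 nm) with a warning.
        """
        import warnings as _warnings

        c1, c2 = s.chain(chain1_id), s.chain(chain2_id)
        if c1 is None or c2 is None:
            raise EmptyInputError(f"chains {chain1_id}/{chain2_id} not found")
        r1 = [r for r in c1.residues if r.kind == ResidueKind.DNA]
        r2 = [r for r in c2.residues if r.kind == ResidueKind.DNA]
        if len(r1) == len(r2):
            pairing = list(zip(r1, reversed(r2)))
        else:
            _warnings.warn(
                "strand lengths differ; pairing geometrically by C1' proximity",
                stacklevel=2,
            )
            pairing = []
            for res in r1:
                a = res.atom("C1'")
                if a is None:
                    continue
                best, best_d = None, 1.2
                for other in r2:
                    b = other.atom("C1'")
                    if b is None:
                        continue
                    d = float(np.linalg.norm(a.coords - b.coords))
                    if d < best_d:
                        best, best_d = other, d
                if best is not None:
                    pairing.append((res, best))
        return cls(strand1=c1, strand2=c2, pairing=pairing)


@dataclasses.dataclass(frozen=True)
class WindowPairing:
    """A candidate superposition: equal-length windows on two duplexes."""

    window_len: int
    start_a: int
    start_b: int
    orientation: str  # PARALLEL or ANTIPARALLEL

    def __post_init__(self) -> None:
        if self.orientation not in (PARALLEL, ANTIPARALLEL):
            raise ValueError(f"bad orientation {self.orientation!r}")


def enumerate_window_pairings(
    dup_a: DnaDuplex, dup_b: DnaDuplex, window_len: int
) -> list[WindowPairing]:
    """All window placements, both orientations; 2(La-w+1)(Lb-w+1) entries.

    Deterministic order: a-offset, then b-offset, then orientation.
    Returns an empty list (not an error) if a duplex is shorter than the
    window.
    """
    la, lb = len(dup_a), len(dup_b)
    if window_len > la or window_len > lb:
        return []
    return [
        WindowPairing(window_len, sa, sb, orient)
        for sa in range(la - window_len + 1)
        for sb in range(lb - window_len + 1)
        for orient in (PARALLEL, ANTIPARALLEL)
    ]


# ---------------------------------------------------------------------------
# Window superposition and model merge
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MergedModel:
    """Acceptor complex plus the transformed donor protein (donor DNA removed)."""

    structure: Structure
    pairing_used: WindowPairing
    score: float
    window_rmsd: float = 0.0
    clash_count: int = 0


def _window_coords(
    duplex: DnaDuplex,
    start: int,
    window_len: int,
    atom_names: Sequence[str],
    reverse: bool,
    swap_strands: bool,
) -> np.ndarray:
    """Superposition-atom coordinates of one window, in pairing order.

    ``reverse``/``swap_strands`` implement the antiparallel matching: base
    pair i of window A meets base pair (w-1-i) of window B with the strands
    exchanged.
    """
    rows = []
    indices = range(start + window_len - 1, start - 1, -1) if reverse else range(
        start, start + window_len
    )
    for i in indices:
        res1, res2 = duplex.pairing[i]
        if swap_strands:
            res1, res2 = res2, res1
        for res in (res1, res2):
            for name in atom_names:
                atom = res.atom(name)
                if atom is None:
                    raise SuperpositionAtomsError(
                        f"residue {res.res_name}{res.seq_id} lacks atom {name}"
                    )
                rows.append(atom.coords)
    return np.asarray(rows)


def _unique_chain_ids(taken: set[str]) -> Iterable[str]:
    for cid in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789":
        if cid not in taken:
            yield cid


def superpose_on_window(
    complex_a: Structure,
    complex_b: Structure,
    duplex_a: DnaDuplex,
    duplex_b: DnaDuplex,
    wp: WindowPairing,
    atom_names: Sequence[str] = DEFAULT_SUPERPOSITION_ATOMS,
) -> tuple[SuperpositionResult, MergedModel]:
    """Fit the donor complex (b) onto one window of the acceptor (a).

    The donor's DNA chains are removed from the merged model; the acceptor
    DNA (the zinc fingers' specific site) is kept.  Donor protein chains
    are renamed to avoid id collisions.
    """
    ref = _window_coords(duplex_a, wp.start_a, wp.window_len, atom_names,
                         reverse=False, swap_strands=False)
    antival = wp.orientation == ANTIPARALLEL
    mob = _window_coords(duplex_b, wp.start_b, wp.window_len, atom_names,
                         reverse=antival, swap_strands=antival)
    fit = kabsch(ref, mob)

    donor = complex_b.copy()
    donor.transform(fit.rotation, fit.translation)

    merged = complex_a.copy()
    merged.id = f"{complex_a.id}+{complex_b.id}:w{wp.window_len}a{wp.start_a}b{wp.start_b}{wp.orientation[0]}"
    donor_dna_ids = {duplex_b.strand1.chain_id, duplex_b.strand2.chain_id}
    taken = {c.chain_id for c in merged.chains}
    fresh = _unique_chain_ids(taken)
    for chain in donor.chains:
        if chain.chain_id in donor_dna_ids:
            continue  # donor DNA removed
        new_id = chain.chain_id if chain.chain_id not in taken else next(fresh)
        taken.add(new_id)
        merged.chains.append(Chain(new_id, chain.residues))

    model = MergedModel(
        structure=merged, pairing_used=wp, score=0.0, window_rmsd=fit.rmsd
    )
    return fit, model


# ---------------------------------------------------------------------------
# Clash scoring / relief
# ---------------------------------------------------------------------------


def _bonded_exclusion(structure: Structure) -> Callable[[int, int], bool]:
    """Default exclusion rule: same residue or sequence-adjacent residues
    within one chain count as bonded."""
    res_key = []
    for ci, chain in enumerate(structure.chains):
        for ri, res in enumerate(chain.residues):
            for _ in res.atoms:
                res_key.append((ci, ri))

    def excluded(i: int, j: int) -> bool:
        ci, ri = res_key[i]
        cj, rj = res_key[j]
        return ci == cj and abs(ri - rj) <= 1

    return excluded


def clash_score(
    s: Structure,
    cutoff: float = 0.25,
    exclusions: Optional[Callable[[int, int], bool]] = None,
    frame: int = 0,
) -> tuple[int, float]:
    """Count non-bonded atom pairs closer than ``cutoff`` (strict ``<``).

    Returns ``(count, sum((cutoff - d)^2))``.  Pairs excluded by the bonded
    rule (default: same or adjacent residue in a chain) are skipped.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = s.coords_array(frame)
    if coords.shape[0] == 0:
        return 0, 0.0
    if exclusions is None:
        exclusions = _bonded_exclusion(s)
    tree = cKDTree(coords)
    count, score = 0, 0.0
    for i, j in tree.query_pairs(cutoff):
        if exclusions(i, j):
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < cutoff:
            count += 1
            score += (cutoff - d) ** 2
    return count, score


def relieve_clashes(
    s: Structure,
    mobile: Selection,
    cutoff: float = 0.25,
    max_steps: int = 50,
    step_size: float = 0.01,
) -> Structure:
    """Steepest descent on the clash score, moving only ``mobile`` atoms.

    The score is non-increasing over accepted steps; the routine stops at
    ``max_steps``, at zero gradient, or when backtracking cannot find a
    downhill step.  Atom displacement is bounded by ``max_steps*step_size``.
    """
    out = s.copy()
    mobile_idx = np.array([r.index for r in select(out, mobile)], dtype=int)
    if mobile_idx.size == 0:
        raise EmptyInputError("mobile selection is empty")
    exclusions = _bonded_exclusion(out)
    coords = out.coords_array(0)

    def score_and_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        tree = cKDTree(x)
        grad = np.zeros_like(x)
        total = 0.0
        for i, j in tree.query_pairs(cutoff):
            if exclusions(i, j):
                continue
            dv = x[i] - x[j]
            d = float(np.linalg.norm(dv))
            if d >= cutoff or d == 0.0:
                continue
            total += (cutoff - d) ** 2
            g = -2.0 * (cutoff - d) * dv / d
            grad[i] += g
            grad[j] -= g
        return total, grad

    current, grad = score_and_grad(coords)
    for _ in range(max_steps):
        if current == 0.0:
            break
        g = np.zeros_like(coords)
        g[mobile_idx] = grad[mobile_idx]
        gnorm = float(np.linalg.norm(g))
        if gnorm < 1e-12:
            break
        step = step_size
        accepted = False
        while step > step_size * 1e-4:
            trial = coords - (step / gnorm) * g
            trial_score, trial_grad = score_and_grad(trial)
            if trial_score < current:
                coords, current, grad = trial, trial_score, trial_grad
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    out.set_coords(coords, frame=0)
    return out


# ---------------------------------------------------------------------------
# Model ranking
# ---------------------------------------------------------------------------

Scorer = Callable[[Structure], float]


def default_scorer(s: Structure, cutoff: float = 0.25) -> float:
    """Reference scorer: clash score at the default cutoff (lower is better)."""
    return clash_score(s, cutoff=cutoff)[1]


def score_models(models: Sequence[MergedModel], scorer: Scorer = default_scorer) -> None:
    for m in models:
        m.score = float(scorer(m.structure))
        m.clash_count = clash_score(m.structure)[0]


def select_best_model(models: Sequence[MergedModel]) -> MergedModel:
    """Lowest-score model; ties broken by enumeration order."""
    if not models:
        raise EmptyInputError("no models to select from")
    best = models[0]
    for m in models[1:]:
        if m.score < best.score:
            best = m
    return best


def build_models(
    acceptor: Structure,
    donor: Structure,
    acceptor_chains: tuple[str, str],
    donor_chains: tuple[str, str],
    window_lens: Sequence[int] = (5, 8),
    atom_names: Sequence[str] = DEFAULT_SUPERPOSITION_ATOMS,
    scorer: Scorer = default_scorer,
) -> list[MergedModel]:
    """Full enumeration: every window length, offset and orientation, scored.

    Models from all window lengths are pooled and ranked jointly.
    """
    dup_a = DnaDuplex.from_structure(acceptor, *acceptor_chains)
    dup_b = DnaDuplex.from_structure(donor, *donor_chains)
    models: list[MergedModel] = []
    for w in window_lens:
        for wp in enumerate_window_pairings(dup_a, dup_b, w):
            _, model = superpose_on_window(acceptor, donor, dup_a, dup_b, wp, atom_names)
            models.append(model)
    score_models(models, scorer)
    return models
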