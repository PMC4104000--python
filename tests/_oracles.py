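"""Independent reference implementations used only to cross-check the package.

Each oracle deliberately uses a different algorithm or a naive exhaustive
formulation than the code under test.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method.

    Independent of the SVD route: builds the 4x4 key matrix from the
    correlation tensor and takes its largest eigenvalue.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    m = b0.T @ a0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    n = a.shape[0]
    msd = (np.sum(a0**2) + np.sum(b0**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def brute_clash(coords: np.ndarray, cutoff: float, excluded) -> tuple[int, float]:
    """O(N^2) double loop over all atom pairs (strict < at the cutoff)."""
    n = coords.shape[0]
    count, score = 0, 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if excluded(i, j):
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < cutoff:
                count += 1
                score += (cutoff - d) ** 2
    return count, score


def brute_hbonds_heavy(coords, donor_idx, acceptor_idx, same_residue, da_max):
    """Triple... well, double loop heavy-atom H-bond finder."""
    bonds = []
    for d in donor_idx:
        for a in acceptor_idx:
            if same_residue(d, a):
                continue
            if np.linalg.norm(coords[d] - coords[a]) <= da_max:
                bonds.append((d, a))
    return bonds


def brute_interaction_energy(coords, idx_a, idx_b, params_of, eps_r=1.0, f=138.935):
    """Naive pairwise sum; geometric-mean LJ combination, unordered pairs."""
    seen = set()
    vdw = elec = 0.0
    for i in idx_a:
        for j in idx_b:
            if i == j:
                continue
            key = frozenset((i, j))
            if key in seen:
                continue
            seen.add(key)
            qi, c6i, c12i = params_of(i)
            qj, c6j, c12j = params_of(j)
            r = float(np.linalg.norm(coords[i] - coords[j]))
            elec += f * qi * qj / (eps_r * r)
            c6 = np.sqrt(c6i * c6j)
            c12 = np.sqrt(c12i * c12j)
            vdw += c12 / r**12 - c6 / r**6
    return vdw, elec, vdw + elec


def brute_linker_filter(fragments, anchors, length_range, dist_tol, rmsd_max,
                        fit_rmsd):
    """Exhaustive filter over a fragment list; returns passing source ids."""
    passing = []
    for frag in fragments:
        if not (length_range[0] <= frag.length <= length_range[1]):
            continue
        if abs(frag.end_to_end - anchors.gap_distance) > dist_tol:
            continue
        rmsd = fit_rmsd(frag)
        if rmsd <= rmsd_max:
            passing.append((rmsd, frag.source_id))
    passing.sort()
    return [sid for _, sid in passing]
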