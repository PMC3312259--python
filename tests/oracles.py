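"""Independent reference implementations used only as test oracles.

Everything here deliberately avoids the package's own algorithms:
alignment optima come from exhaustive enumeration of the move tree,
contacts and energies from literal double loops, UPGMA from direct
leaf-pair averaging over the original matrix, and the alanine Cβ from
internal-coordinate (NeRF) construction with textbook geometry.
"""

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# geometry

def nerf(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom d bonded to c (angle b-c-d, dihedral a-b-c-d)."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([-np.cos(ang),
                          np.sin(ang) * np.cos(dih),
                          np.sin(ang) * np.sin(dih)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def ideal_alanine():
    """Idealized alanine: backbone from textbook bond geometry, Cβ by NeRF.

    N–CA 1.458 Å, CA–C 1.525 Å, N–CA–C 111°; CB placed with CA–CB
    1.53 Å, C–CA–CB 110.1° and improper dihedral N–C–CA–CB +122.6°
    (L-configuration).
    """
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    ang = np.deg2rad(111.0)
    c = 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    cb = nerf(n, c, ca, 1.53, 110.1, 122.6)
    return {"N": n, "CA": ca, "C": c, "CB": cb}


# ---------------------------------------------------------------------------
# alignment optima by exhaustive enumeration

def brute_global(S, gap):
    """Maximum global alignment score by enumerating every move path."""
    n, m = S.shape

    def walk(i, j):
        if i == n and j == m:
            return 0.0
        vals = []
        if i < n and j < m:
            vals.append(S[i, j] + walk(i + 1, j + 1))
        if i < n:
            vals.append(walk(i + 1, j) - gap)
        if j < m:
            vals.append(walk(i, j + 1) - gap)
        return max(vals)

    return walk(0, 0)


def brute_local(S, gap):
    """Best score over all substring pairs (empty alignment scores 0)."""
    n, m = S.shape
    best = 0.0
    for i0 in range(n):
        for i1 in range(i0 + 1, n + 1):
            for j0 in range(m):
                for j1 in range(j0 + 1, m + 1):
                    best = max(best, brute_global(S[i0:i1, j0:j1], gap))
    return best


# ---------------------------------------------------------------------------
# contacts and energies by literal double loop

def naive_contacts(structure, i, cutoff):
    out = set()
    for j, r in enumerate(structure.residues):
        if j == i:
            continue
        if np.linalg.norm(structure.residues[i].ca - r.ca) <= cutoff:
            out.add(j)
    return out


def naive_profile(structure, table, cutoff):
    energies = []
    for i, ri in enumerate(structure.residues):
        total = 0.0
        for j, rj in enumerate(structure.residues):
            if j == i:
                continue
            if np.linalg.norm(ri.ca - rj.ca) <= cutoff:
                total += table[ri.aa] + table[rj.aa]
        energies.append(total)
    return energies


# ---------------------------------------------------------------------------
# UPGMA by direct leaf-pair averaging

def reference_upgma(labels, matrix):
    """Merge list [(leavesA, leavesB, height), ...] from first principles.

    Cluster-to-cluster distance is recomputed every round as the plain
    mean of all leaf-pair distances in the input matrix (no incremental
    update); ties break on the lexicographically smallest pair of sorted
    leaf tuples.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    clusters = [frozenset([lab]) for lab in labels]
    merges = []

    def cdist(a, b):
        vals = [matrix[index[x], index[y]] for x in a for y in b]
        return sum(vals) / len(vals)

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            ka, kb = sorted((tuple(sorted(a)), tuple(sorted(b))))
            cand = (cdist(a, b), ka, kb, a, b)
            if best is None or cand[:3] < best[:3]:
                best = cand
        dmin, ka, kb, a, b = best
        merges.append((list(ka), list(kb), dmin / 2.0))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges
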