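"""Multiple energy profile alignment (MEPAL).

The pipeline mirrors classic progressive sequence alignment, but on
energy profiles: (1) every pair of profiles is aligned and its dScore
entered into a distance matrix, (2) the matrix is clustered with UPGMA
and the merge order recorded as a guide tree, (3) profiles are merged
into a growing multiple alignment following that order, scoring a column
against a column by the mean pairwise energy score over the non-gap
members ("once a gap, always a gap").  Each final column carries a
consensus energy — the member energy with the highest summed pairwise
score to the others — and a conservation value, the summed pairwise
scores normalized by the best possible sum, so 1.0 means the column is
energetically invariant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import (AlignConfig, EnergyBinner, align_profiles, build_binner,
                    _nw_matrix)
from .errors import EprofilerError
from .profile import EnergyProfile


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, bans

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


@dataclass
class GuideTree:
    """Rooted binary UPGMA tree; internal heights are merge distances / 2."""

    label: str | None = None  # leaf name
    left: "GuideTree | None" = None
    right: "GuideTree | None" = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            return self.label
        parts = []
        for child in (self.left, self.right):
            branch = self.height - child.height
            parts.append(f"{child._newick_node()}:{branch:.6g}")
        return "(" + ",".join(parts) + ")"

    def merge_order(self) -> list[tuple[list[str], list[str], float]]:
        """Chronological clustering steps as (left, right, merge height).

        Average linkage is reducible, so merge heights never decrease
        over time; sorting the tree's internal nodes by height (stable)
        therefore reconstructs the recorded agglomeration order.
        """
        def collect(node):
            if node.is_leaf:
                return []
            return collect(node.left) + collect(node.right) + [
                (node.left.leaves(), node.right.leaves(), node.height)
            ]

        return sorted(collect(self), key=lambda m: m[2])


def unique_labels(profiles: Sequence[EnergyProfile]) -> list[str]:
    """Profile ids, disambiguated with ``~k`` suffixes on repeats."""
    seen: dict[str, int] = {}
    labels = []
    for p in profiles:
        k = seen.get(p.id, 0)
        seen[p.id] = k + 1
        labels.append(p.id if k == 0 else f"{p.id}~{k + 1}")
    return labels


def distance_matrix(profiles: Sequence[EnergyProfile],
                    config: AlignConfig = AlignConfig()) -> DistanceMatrix:
    """All-vs-all dScores; each pair aligned once, diagonal forced to 0."""
    if len(profiles) < 2:
        raise EprofilerError("need at least 2 profiles")
    labels = unique_labels(profiles)
    n = len(profiles)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            res = align_profiles(profiles[i], profiles[j], config)
        except EprofilerError as exc:
            raise EprofilerError(
                f"pairwise alignment failed for ({labels[i]}, {labels[j]}): {exc}"
            ) from exc
        m[i, j] = m[j, i] = res.dscore
    return DistanceMatrix(labels=labels, matrix=m)


def upgma(dm: DistanceMatrix) -> GuideTree:
    """UPGMA agglomeration with lexicographic tie-breaking.

    Cluster-to-cluster distances follow the size-weighted average update;
    among equally close pairs the one whose sorted leaf-label tuples come
    first lexicographically is merged.  Merge heights are half the merge
    distance, so leaf-to-root path lengths reproduce the matrix under
    perfect ultrametricity.
    """
    if len(dm.labels) < 2:
        raise EprofilerError("UPGMA needs at least 2 labels")
    if np.isnan(dm.matrix).any():
        raise EprofilerError("distance matrix contains NaN")
    nodes: dict[int, GuideTree] = {
        i: GuideTree(label=lab) for i, lab in enumerate(dm.labels)
    }
    sizes = {i: 1 for i in nodes}
    keys = {i: tuple(sorted(nodes[i].leaves())) for i in nodes}
    dist: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(len(dm.labels)), 2):
        dist[(i, j)] = float(dm.matrix[i, j])
    next_id = len(dm.labels)

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(nodes) > 1:
        best = None
        for a, b in itertools.combinations(sorted(nodes), 2):
            ka, kb = sorted((keys[a], keys[b]))
            cand = (d(a, b), ka, kb, a, b)
            if best is None or cand < best:
                best = cand
        dmin, _, _, a, b = best
        merged = GuideTree(left=nodes[a], right=nodes[b], height=dmin / 2.0)
        for other in nodes:
            if other in (a, b):
                continue
            new = (sizes[a] * d(a, other) + sizes[b] * d(b, other)) / (
                sizes[a] + sizes[b]
            )
            dist[(min(other, next_id), max(other, next_id))] = new
        nodes.pop(a), nodes.pop(b)
        nodes[next_id] = merged
        sizes[next_id] = sizes.get(a, 1) + sizes.get(b, 1)
        keys[next_id] = tuple(sorted(merged.leaves()))
        next_id += 1
    return nodes.popitem()[1]


# ---------------------------------------------------------------------------
# progressive alignment

@dataclass
class MultipleAlignment:
    """Aligned columns over >= 2 profiles plus consensus and conservation.

    ``rows[label]`` maps each alignment column to an entry index of that
    profile or ``None`` for a gap; non-gap indices appear in original
    order.
    """

    labels: list[str]
    profiles: dict[str, EnergyProfile]
    rows: dict[str, list[int | None]]
    binner: EnergyBinner
    s_max: float
    consensus: list[float] = field(default_factory=list)
    conservation: list[float] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def column_energies(self, col: int) -> list[float]:
        """Non-gap member energies of a column, in label order."""
        out = []
        for lab in self.labels:
            idx = self.rows[lab][col]
            if idx is not None:
                out.append(float(self.profiles[lab].entries[idx].energy))
        return out


def consensus_energy(energies: Sequence[float], binner: EnergyBinner,
                     s_max: float) -> float:
    """Member energy with the highest summed pairwise score; ties -> lower."""
    if len(energies) == 0:
        raise EprofilerError("all-gap column has no consensus")
    bins = binner.bin_of(energies)
    best_e, best_sum = None, None
    for e, b in sorted(zip(energies, bins)):
        total = float(np.sum(s_max - np.abs(bins - b))) - s_max  # minus self
        if best_sum is None or total > best_sum:
            best_e, best_sum = float(e), total
    return best_e


def conservation(energies: Sequence[float], binner: EnergyBinner,
                 s_max: float) -> float:
    """Summed pairwise scores over the best possible sum, in [0, 1].

    Columns with a single member report 1.0 by convention (nothing can
    diverge); negative pair scores (possible only when s_max is set
    below the bin range) clamp at 0.
    """
    if len(energies) < 2:
        return 1.0
    bins = binner.bin_of(energies)
    total = 0.0
    n_pairs = 0
    for x, y in itertools.combinations(bins, 2):
        total += s_max - abs(int(x) - int(y))
        n_pairs += 1
    return max(0.0, min(1.0, total / (n_pairs * s_max)))


def _column_bins(profile_bins: dict[str, np.ndarray],
                 labels: list[str], rows: dict[str, list[int | None]]
                 ) -> list[np.ndarray]:
    cols = []
    n_cols = len(rows[labels[0]])
    for c in range(n_cols):
        members = [profile_bins[lab][rows[lab][c]] for lab in labels
                   if rows[lab][c] is not None]
        cols.append(np.asarray(members, dtype=float))
    return cols


def _merge_groups(rows_a: dict[str, list[int | None]],
                  rows_b: dict[str, list[int | None]],
                  labels_a: list[str], labels_b: list[str],
                  profile_bins: dict[str, np.ndarray],
                  s_max: float, gap: float):
    cols_a = _column_bins(profile_bins, labels_a, rows_a)
    cols_b = _column_bins(profile_bins, labels_b, rows_b)
    S = np.empty((len(cols_a), len(cols_b)))
    for i, u in enumerate(cols_a):
        for j, v in enumerate(cols_b):
            S[i, j] = s_max - float(np.mean(np.abs(u[:, None] - v[None, :])))
    H = _nw_matrix(S, gap)
    # traceback, prefer diagonal, then up, then left
    i, j = S.shape
    steps: list[tuple[int | None, int | None]] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) < eps:
            steps.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and abs(H[i, j] - (H[i - 1, j] - gap)) < eps:
            steps.append((i - 1, None))
            i -= 1
        else:
            steps.append((None, j - 1))
            j -= 1
    steps.reverse()
    merged: dict[str, list[int | None]] = {lab: [] for lab in
                                           labels_a + labels_b}
    for ca, cb in steps:
        for lab in labels_a:
            merged[lab].append(rows_a[lab][ca] if ca is not None else None)
        for lab in labels_b:
            merged[lab].append(rows_b[lab][cb] if cb is not None else None)
    return merged


def progressive_align(profiles: Sequence[EnergyProfile], tree: GuideTree,
                      config: AlignConfig = AlignConfig()) -> MultipleAlignment:
    """Merge profiles following the guide tree into one multiple alignment.

    A single binner is fitted once on the pooled energies of all profiles
    so column scores are comparable across merges.
    """
    labels = unique_labels(profiles)
    by_label = dict(zip(labels, profiles))
    if set(tree.leaves()) != set(labels):
        raise EprofilerError("guide tree leaves do not match profile labels")
    if config.reference_energies is not None:
        sample = np.asarray(config.reference_energies, dtype=float)
    else:
        # sorted pooling: the fit is invariant to profile input order
        sample = np.sort(np.concatenate([p.energies for p in profiles]))
    binner = build_binner(sample, n_bins=config.n_bins)
    s_max = config.effective_s_max
    gap = config.effective_gap
    profile_bins = {lab: binner.bin_of(by_label[lab].energies)
                    for lab in labels}

    def build(node: GuideTree) -> tuple[dict[str, list[int | None]], list[str]]:
        if node.is_leaf:
            lab = node.label
            return {lab: list(range(len(by_label[lab])))}, [lab]
        rows_a, labs_a = build(node.left)
        rows_b, labs_b = build(node.right)
        merged = _merge_groups(rows_a, rows_b, labs_a, labs_b, profile_bins,
                               s_max, gap)
        return merged, labs_a + labs_b

    rows, _ = build(tree)
    msa = MultipleAlignment(labels=labels, profiles=by_label, rows=rows,
                            binner=binner, s_max=s_max)
    for c in range(msa.n_columns):
        members = msa.column_energies(c)
        msa.consensus.append(consensus_energy(members, binner, s_max))
        msa.conservation.append(conservation(members, binner, s_max))
    return msa


@dataclass
class MepalResult:
    distances: DistanceMatrix
    tree: GuideTree
    alignment: MultipleAlignment


def mepal(profiles: Sequence[EnergyProfile],
          config: AlignConfig = AlignConfig()) -> MepalResult:
    """Full pipeline: distance matrix -> UPGMA guide tree -> alignment."""
    dm = distance_matrix(profiles, config)
    tree = upgma(dm)
    msa = progressive_align(profiles, tree, config)
    return MepalResult(distances=dm, tree=tree, alignment=msa)


# ---------------------------------------------------------------------------
# text rendering

_BIN_GLYPHS = "0123456789abcdefghijklmnopqrstuvwxyz"
_CONS_GLYPHS = " .:-=+*#%@"  # low -> high conservation


def _bin_glyph(b: int) -> str:
    return _BIN_GLYPHS[min(b, len(_BIN_GLYPHS) - 1)]


def render_mepal(msa: MultipleAlignment, width: int = 60) -> str:
    """Three-part text report: profiles, consensus, conservation.

    Per profile two rows per block: amino-acid one-letter codes (gaps as
    ``-``) and the energy-bin glyph of each residue (base-36 digit, low
    bin = low energy).  The consensus row shows the consensus energy's
    bin; the conservation row maps [0, 1] to ``' .:-=+*#%@'`` (``@`` =
    fully conserved).
    """
    n = msa.n_columns
    aa_rows = {}
    bin_rows = {}
    for lab in msa.labels:
        prof = msa.profiles[lab]
        bins = msa.binner.bin_of(prof.energies)
        aa, bg = [], []
        for idx in msa.rows[lab]:
            if idx is None:
                aa.append("-")
                bg.append("-")
            else:
                aa.append(prof.entries[idx].aa)
                bg.append(_bin_glyph(int(bins[idx])))
        aa_rows[lab] = "".join(aa)
        bin_rows[lab] = "".join(bg)
    cons_bins = msa.binner.bin_of(msa.consensus)
    cons_row = "".join(_bin_glyph(int(b)) for b in cons_bins)
    conserv_row = "".join(
        _CONS_GLYPHS[min(int(v * len(_CONS_GLYPHS)), len(_CONS_GLYPHS) - 1)]
        for v in msa.conservation
    )
    name_w = max(len(lab) for lab in msa.labels) + 2
    name_w = max(name_w, len("conservation") + 2)

    lines = [f"# MEPAL  profiles={len(msa.labels)}  columns={n}"]
    for start in range(0, n, width):
        stop = min(start + width, n)
        lines.append(f"== columns {start + 1}-{stop} ==")
        for lab in msa.labels:
            lines.append(f"{lab:<{name_w}}{aa_rows[lab][start:stop]}")
            lines.append(f"{'':<{name_w}}{bin_rows[lab][start:stop]}")
        lines.append(f"{'consensus':<{name_w}}{cons_row[start:stop]}")
        lines.append(f"{'conservation':<{name_w}}{conserv_row[start:stop]}")
    return "\n".join(lines) + "\n"
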