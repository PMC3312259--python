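"""Inside/outside classification and inverse-Boltzmann pseudoenergies.

A residue is classified as buried ("inside") or exposed ("outside") from
purely geometric information: the centroid c of the Cα atoms within a
sphere around its own Cα, the distance to that centroid, and the
orientation of the Cα→Cβ side-chain vector relative to it.  Counting how
often each amino-acid type ends up inside versus outside over a set of
structures, and inverting the resulting odds with the Boltzmann relation,

    e*_i = -ln(n_in,i / n_out,i),

yields a per-amino-acid pseudoenergy in arbitrary units: types that
prefer burial get negative e*, exposure-biased types positive e*.  The
Boltzmann factor k_B·T is a constant scale and is omitted.

Note on the classification rule: the centroid of Cα atoms that all lie
within `radius` of Cα_i itself lies within `radius` of Cα_i, so the
distance criterion fires whenever any neighbor exists and the rule
degenerates to "has a neighbor within the sphere".  The rule is kept in
its literal disjunctive form here — distance OR side-chain orientation —
with `radius` and `orientation_sign` exposed so users can explore
non-degenerate variants; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import EprofilerError, FormatError
from .structure_io import AMINO_ACIDS, Structure

DEFAULT_RADIUS = 5.0  # Å, neighbor sphere for the local centroid
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class BuriednessCounts:
    """Per-amino-acid inside/outside frequencies over a structure set."""

    n_in: dict[str, int]
    n_out: dict[str, int]
    source_set: str = ""
    radius: float = DEFAULT_RADIUS

    @classmethod
    def zeros(cls, source_set: str = "", radius: float = DEFAULT_RADIUS):
        return cls(
            n_in={aa: 0 for aa in AMINO_ACIDS},
            n_out={aa: 0 for aa in AMINO_ACIDS},
            source_set=source_set,
            radius=radius,
        )

    def total(self, aa: str) -> int:
        return self.n_in[aa] + self.n_out[aa]

    def __add__(self, other: "BuriednessCounts") -> "BuriednessCounts":
        return BuriednessCounts(
            n_in={aa: self.n_in[aa] + other.n_in[aa] for aa in AMINO_ACIDS},
            n_out={aa: self.n_out[aa] + other.n_out[aa] for aa in AMINO_ACIDS},
            source_set=self.source_set or other.source_set,
            radius=self.radius,
        )


@dataclass
class PseudoEnergyTable:
    """Per-amino-acid pseudoenergies e* in arbitrary units [a.u.]."""

    e_star: dict[str, float]
    source_set: str = ""
    radius: float = DEFAULT_RADIUS
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    counts: BuriednessCounts | None = None

    def __getitem__(self, aa: str) -> float:
        return self.e_star[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self.e_star

    def scaled(self, factor: float) -> "PseudoEnergyTable":
        return PseudoEnergyTable(
            e_star={aa: factor * e for aa, e in self.e_star.items()},
            source_set=self.source_set,
            radius=self.radius,
            pseudocount=self.pseudocount,
        )


def local_center(
    structure: Structure, i: int, radius: float = DEFAULT_RADIUS
) -> np.ndarray | None:
    """Centroid of all Cα atoms within `radius` of residue i's Cα.

    Residue i itself is excluded by default design (including it pulls
    the centroid toward Cα_i and weakens the classification); pass
    ``include_self=True`` on :func:`classify_inside` for the literal
    all-atoms variant.  Returns ``None`` when no neighbor is in range.
    """
    coords = structure.ca_coords()
    d = np.linalg.norm(coords - coords[i], axis=1)
    mask = d <= radius
    mask[i] = False
    if not mask.any():
        return None
    return coords[mask].mean(axis=0)


def inside_rule(
    ca: np.ndarray,
    cb: np.ndarray | None,
    c: np.ndarray | None,
    radius: float = DEFAULT_RADIUS,
    orientation_sign: int = 1,
) -> bool:
    """The bare inside/outside disjunction for given Cα, Cβ and centroid c.

    Inside iff  ‖Cα − c‖ < radius  OR
    orientation_sign · (Cα − Cβ)·(Cα − c) < 0.  With no centroid
    (isolated residue) the result is outside; with no Cβ only the
    distance criterion is evaluated.
    """
    if c is None:
        return False
    if np.linalg.norm(ca - c) < radius:
        return True
    if cb is None:
        return False
    return orientation_sign * float(np.dot(ca - cb, ca - c)) < 0.0


def classify_inside(
    structure: Structure,
    i: int,
    radius: float = DEFAULT_RADIUS,
    orientation_sign: int = 1,
    include_self: bool = False,
) -> bool:
    """Inside/outside decision for residue i (see :func:`inside_rule`)."""
    res = structure.residues[i]
    coords = structure.ca_coords()
    d = np.linalg.norm(coords - coords[i], axis=1)
    mask = d <= radius
    if not include_self:
        mask[i] = False
    c = coords[mask].mean(axis=0) if mask.any() else None
    return inside_rule(res.ca, res.effective_cb(), c, radius=radius,
                       orientation_sign=orientation_sign)


def classify_all(
    structure: Structure,
    radius: float = DEFAULT_RADIUS,
    orientation_sign: int = 1,
    include_self: bool = False,
) -> np.ndarray:
    """Inside/outside decision for every residue at once.

    Identical to calling :func:`classify_inside` per residue, but with a
    single KD-tree neighbor query, so large structure sets tally in
    linear expected time.
    """
    from scipy.spatial import cKDTree

    coords = structure.ca_coords()
    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, r=radius)
    out = np.zeros(len(coords), dtype=bool)
    for i, res in enumerate(structure.residues):
        nb = neighbor_lists[i] if include_self else \
            [j for j in neighbor_lists[i] if j != i]
        if not nb:
            continue
        c = coords[nb].mean(axis=0)
        if np.linalg.norm(coords[i] - c) < radius:
            out[i] = True
            continue
        cb = res.effective_cb()
        if cb is None:
            continue
        out[i] = orientation_sign * float(
            np.dot(coords[i] - cb, coords[i] - c)
        ) < 0.0
    return out


def accumulate_counts(
    structures: Iterable[Structure],
    radius: float = DEFAULT_RADIUS,
    orientation_sign: int = 1,
    source_set: str = "",
    include_self: bool = False,
) -> BuriednessCounts:
    """Classify every residue of every structure and tally by type."""
    counts = BuriednessCounts.zeros(source_set=source_set, radius=radius)
    n_structures = 0
    for s in structures:
        n_structures += 1
        inside = classify_all(s, radius=radius,
                              orientation_sign=orientation_sign,
                              include_self=include_self)
        for res, flag in zip(s.residues, inside):
            if flag:
                counts.n_in[res.aa] += 1
            else:
                counts.n_out[res.aa] += 1
    if n_structures == 0:
        raise EprofilerError("accumulate_counts requires at least one structure")
    return counts


def pseudoenergy(n_in: int, n_out: int,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Scalar Boltzmann inversion, e* = -ln((n_in + q)/(n_out + q))."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    num = n_in + pseudocount
    den = n_out + pseudocount
    if num == 0 or den == 0:
        raise EprofilerError("undefined in/out ratio with pseudocount 0")
    return -math.log(num / den)


def pseudoenergies(
    counts: BuriednessCounts, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> PseudoEnergyTable:
    """Boltzmann inversion of the buriedness odds for all 20 amino acids.

    A pseudocount (default 1.0) keeps e* finite for amino acids never
    seen in one of the two classes.
    """
    e_star: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        try:
            e_star[aa] = pseudoenergy(counts.n_in[aa], counts.n_out[aa],
                                      pseudocount)
        except EprofilerError as exc:
            raise EprofilerError(f"{exc} (amino acid {aa})") from exc
    return PseudoEnergyTable(
        e_star=e_star,
        source_set=counts.source_set,
        radius=counts.radius,
        pseudocount=pseudocount,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# stats TSV round trip

def write_stats(table: PseudoEnergyTable, fh: TextIO) -> None:
    """Write counts + pseudoenergies as a commented TSV (20 data rows)."""
    counts = table.counts or BuriednessCounts.zeros(
        source_set=table.source_set, radius=table.radius
    )
    fh.write(f"# source_set: {table.source_set}\n")
    fh.write(f"# radius: {table.radius}\n")
    fh.write(f"# pseudocount: {table.pseudocount}\n")
    fh.write("aa\tn_in\tn_out\te_star\n")
    for aa in AMINO_ACIDS:
        fh.write(f"{aa}\t{counts.n_in[aa]}\t{counts.n_out[aa]}"
                 f"\t{table.e_star[aa]:.10g}\n")


def read_stats(fh: TextIO) -> PseudoEnergyTable:
    """Read a stats TSV written by :func:`write_stats`."""
    meta: dict[str, str] = {}
    rows: dict[str, tuple[int, int, float]] = {}
    header_seen = False
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields[0] != "aa":
                raise FormatError(f"line {lineno}: expected header row")
            header_seen = True
            continue
        if len(fields) != 4:
            raise FormatError(f"line {lineno}: expected 4 columns")
        aa = fields[0]
        if aa not in AMINO_ACIDS:
            raise FormatError(f"line {lineno}: unknown amino acid {aa!r}")
        try:
            rows[aa] = (int(fields[1]), int(fields[2]), float(fields[3]))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    missing = set(AMINO_ACIDS) - set(rows)
    if missing:
        raise FormatError(f"missing amino acid rows: {sorted(missing)}")
    counts = BuriednessCounts(
        n_in={aa: rows[aa][0] for aa in AMINO_ACIDS},
        n_out={aa: rows[aa][1] for aa in AMINO_ACIDS},
        source_set=meta.get("source_set", ""),
        radius=float(meta.get("radius", DEFAULT_RADIUS)),
    )
    return PseudoEnergyTable(
        e_star={aa: rows[aa][2] for aa in AMINO_ACIDS},
        source_set=counts.source_set,
        radius=counts.radius,
        pseudocount=float(meta.get("pseudocount", DEFAULT_PSEUDOCOUNT)),
        counts=counts,
    )


def write_stats_file(table: PseudoEnergyTable, path) -> None:
    with open(path, "w") as fh:
        write_stats(table, fh)


def read_stats_file(path) -> PseudoEnergyTable:
    with open(path) as fh:
        return read_stats(fh)


def default_table() -> PseudoEnergyTable:
    """The bundled pseudoenergy table.

    Computed from a seeded synthetic structure set whose per-amino-acid
    burial probabilities follow a logistic transform of the Kyte–
    Doolittle hydropathy scale.  It is a synthetic stand-in: for any
    biological analysis, derive statistics from a structure set matching
    the proteins under study (statistics from an inappropriate set give
    misleading energies).
    """
    import importlib.resources as resources

    ref = resources.files("eprofiler.data").joinpath("default_stats.tsv")
    with ref.open("r") as fh:
        return read_stats(fh)
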