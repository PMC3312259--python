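"""Synthetic structures and profiles with controlled properties.

Generators here stand in for downloaded coordinate sets so every stage
of the pipeline — classification, statistics, profiles, alignment — can
be exercised deterministically.  All generators are pure functions of
their parameters and seed.  The geometries are idealized (exact helix
parameters, lattice globules); they emulate packing densities and
burial tendencies, not real folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .buriedness_stats import (BuriednessCounts, PseudoEnergyTable,
                               accumulate_counts, pseudoenergies)
from .errors import EprofilerError
from .profile import EnergyProfile, ProfileEntry
from .structure_io import AMINO_ACIDS, Residue, Structure

# ideal alpha-helix Calpha-trace parameters
HELIX_RISE = 1.5        # Å per residue along the axis
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # Å, Calpha distance from the axis
LATTICE_SPACING = 3.8   # Å, consecutive-Calpha distance


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic structure.

    ``composition`` maps one-letter codes to sampling probabilities
    (uniform over the 20 amino acids when empty); ``jitter_sd`` is the
    per-coordinate Gaussian noise in Å.
    """

    n_residues: int = 60
    geometry: Literal["helix", "globule", "extended"] = "helix"
    composition: dict[str, float] = field(default_factory=dict)
    jitter_sd: float = 0.0
    seed: int = 0

    def probabilities(self) -> tuple[tuple[str, ...], np.ndarray]:
        if not self.composition:
            aas = AMINO_ACIDS
            p = np.full(len(aas), 1.0 / len(aas))
            return aas, p
        aas = tuple(sorted(self.composition))
        p = np.array([self.composition[a] for a in aas], dtype=float)
        if not math.isclose(float(p.sum()), 1.0, rel_tol=1e-6):
            raise EprofilerError("composition probabilities must sum to 1")
        return aas, p


def _sample_sequence(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    aas, p = spec.probabilities()
    return [str(a) for a in rng.choice(aas, size=spec.n_residues, p=p)]


def _jitter(coords: np.ndarray, sd: float, rng: np.random.Generator
            ) -> np.ndarray:
    if sd <= 0:
        return coords
    return coords + rng.normal(0.0, sd, size=coords.shape)


def make_helix(spec: SyntheticSpec, structure_id: str = "helix") -> Structure:
    """Ideal α-helix Cα trace with Cβ atoms pointing radially outward."""
    if spec.n_residues < 1:
        raise EprofilerError("need at least 1 residue")
    rng = np.random.default_rng(spec.seed)
    seq = _sample_sequence(spec, rng)
    idx = np.arange(spec.n_residues)
    theta = np.deg2rad(HELIX_TWIST) * idx
    ca = np.stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * idx,
    ], axis=1)
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)],
                      axis=1)
    cb = ca + 1.53 * radial
    ca = _jitter(ca, spec.jitter_sd, rng)
    cb = _jitter(cb, spec.jitter_sd, rng)
    residues = [
        Residue(chain_id="A", seq_index=i + 1, aa=seq[i], ca=ca[i],
                cb=None if seq[i] == "G" else cb[i])
        for i in range(spec.n_residues)
    ]
    return Structure(id=structure_id, residues=residues)


def make_extended(spec: SyntheticSpec, structure_id: str = "extended"
                  ) -> Structure:
    """Straight Cα trace at 3.8 Å spacing (no compact environment)."""
    rng = np.random.default_rng(spec.seed)
    seq = _sample_sequence(spec, rng)
    ca = np.zeros((spec.n_residues, 3))
    ca[:, 0] = LATTICE_SPACING * np.arange(spec.n_residues)
    cb = ca + np.array([0.0, 1.53, 0.0])
    ca = _jitter(ca, spec.jitter_sd, rng)
    cb = _jitter(cb, spec.jitter_sd, rng)
    residues = [
        Residue(chain_id="A", seq_index=i + 1, aa=seq[i], ca=ca[i],
                cb=None if seq[i] == "G" else cb[i])
        for i in range(spec.n_residues)
    ]
    return Structure(id=structure_id, residues=residues)


_LATTICE_STEPS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]
])


def make_globule(
    spec: SyntheticSpec,
    structure_id: str = "globule",
    orientations: Sequence[str] | None = None,
    max_restarts: int = 50,
) -> Structure:
    """Compact self-avoiding Cα walk on a 3.8 Å cubic lattice.

    The walk grows by stepping to the free neighbor site closest to the
    current centroid (random tie-break), which keeps the chain globular.
    ``orientations`` marks residues ``"in"`` (Cβ toward the centroid) or
    ``"out"`` (away), enabling burial-controlled fixtures.
    """
    if spec.n_residues < 1:
        raise EprofilerError("need at least 1 residue")
    rng = np.random.default_rng(spec.seed)
    seq = _sample_sequence(spec, rng)
    if orientations is not None and len(orientations) != spec.n_residues:
        raise EprofilerError("orientations length mismatch")

    sites = None
    for _ in range(max_restarts):
        pos = np.zeros(3, dtype=int)
        visited = {tuple(pos)}
        path = [pos.copy()]
        ok = True
        for _step in range(spec.n_residues - 1):
            centroid = np.mean(path, axis=0)
            candidates = [pos + s for s in _LATTICE_STEPS
                          if tuple(pos + s) not in visited]
            if not candidates:
                ok = False
                break
            dists = [np.linalg.norm(c - centroid) for c in candidates]
            best = min(dists)
            pool = [c for c, d in zip(candidates, dists) if d <= best + 1e-9]
            pos = pool[rng.integers(len(pool))]
            visited.add(tuple(pos))
            path.append(pos.copy())
        if ok:
            sites = np.array(path, dtype=float) * LATTICE_SPACING
            break
    if sites is None:
        raise EprofilerError("self-avoiding walk failed after restarts")

    centroid = sites.mean(axis=0)
    residues = []
    for i in range(spec.n_residues):
        direction = sites[i] - centroid
        nrm = np.linalg.norm(direction)
        if nrm < 1e-9:
            direction = np.array([1.0, 0.0, 0.0])
        else:
            direction = direction / nrm
        if orientations is not None and orientations[i] == "in":
            direction = -direction
        ca = sites[i]
        cb = ca + 1.53 * direction
        residues.append(
            Residue(chain_id="A", seq_index=i + 1, aa=seq[i], ca=ca,
                    cb=None if seq[i] == "G" else cb)
        )
    if spec.jitter_sd > 0:
        ca_j = _jitter(np.array([r.ca for r in residues]), spec.jitter_sd, rng)
        cb_j = _jitter(np.array([r.cb if r.cb is not None else r.ca
                                 for r in residues]), spec.jitter_sd, rng)
        residues = [
            replace(r, ca=ca_j[i], cb=None if r.cb is None else cb_j[i])
            for i, r in enumerate(residues)
        ]
    return Structure(id=structure_id, residues=residues)


def make_structure(spec: SyntheticSpec, structure_id: str | None = None
                   ) -> Structure:
    maker = {"helix": make_helix, "globule": make_globule,
             "extended": make_extended}[spec.geometry]
    return maker(spec, structure_id or spec.geometry)


def perturb_structure(structure: Structure, sd: float, seed: int = 0
                      ) -> Structure:
    """Gaussian coordinate jitter (sd in Å) on every stored atom."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)

    def tx(v):
        return None if v is None else v + rng.normal(0.0, sd, size=3)

    return Structure(
        id=structure.id,
        residues=[replace(r, ca=tx(r.ca), cb=tx(r.cb), n=tx(r.n), c=tx(r.c))
                  for r in structure.residues],
    )


def perturb_profile(profile: EnergyProfile, sd: float, seed: int = 0
                    ) -> EnergyProfile:
    """Seeded Gaussian noise on each energy; sd 0 is the identity."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return profile
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, size=len(profile))
    return profile.with_energies(profile.energies + noise)


# ---------------------------------------------------------------------------
# burial-controlled structure sets for statistics recovery

def make_burial_set(
    aa: str,
    p_inside: float,
    n_residues: int,
    seed: int = 0,
    site_spacing: float = 20.0,
    companion_aa: str = "G",
) -> Structure:
    """Residues of type ``aa`` buried (neighbored) with probability p.

    Each residue of interest sits on an isolated grid site; with
    probability ``p_inside`` a companion residue is placed 3.8 Å away so
    the residue acquires a local Cα environment and classifies as
    inside, otherwise it stays isolated and classifies as outside.
    Sites are spaced far apart so they never interact.  Companions use a
    different amino-acid type so they do not contaminate the counts of
    ``aa``.
    """
    if not 0.0 <= p_inside <= 1.0:
        raise ValueError("p_inside must be in [0, 1]")
    if aa == companion_aa:
        raise EprofilerError("companion type must differ from the target type")
    rng = np.random.default_rng(seed)
    side = int(math.ceil(n_residues ** (1.0 / 3.0)))
    residues: list[Residue] = []
    seq_index = 1
    placed = 0
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                if placed >= n_residues:
                    break
                base = np.array([ix, iy, iz], dtype=float) * site_spacing
                cb = base + np.array([0.0, 0.0, 1.53])
                residues.append(Residue("A", seq_index, aa, ca=base, cb=cb))
                seq_index += 1
                if rng.random() < p_inside:
                    comp = base + np.array([LATTICE_SPACING, 0.0, 0.0])
                    residues.append(
                        Residue("A", seq_index, companion_aa, ca=comp, cb=None)
                    )
                    seq_index += 1
                placed += 1
    return Structure(id=f"burial_{aa}_{p_inside:g}", residues=residues)


#: Kyte–Doolittle hydropathy; the synthetic default statistics bury each
#: amino acid with probability logistic(KD / 2.25), i.e. log-odds KD/2.25.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

DEFAULT_STATS_SEED = 20260923
DEFAULT_STATS_N = 2000


def burial_probability(aa: str, scale: float = 2.25) -> float:
    return 1.0 / (1.0 + math.exp(-KYTE_DOOLITTLE[aa] / scale))


def make_default_stats(
    n_per_aa: int = DEFAULT_STATS_N, seed: int = DEFAULT_STATS_SEED
) -> PseudoEnergyTable:
    """Regenerate the bundled synthetic pseudoenergy table.

    Burial probabilities follow a logistic transform of Kyte–Doolittle
    hydropathy, so hydrophobic types get negative e* (burial-favoring)
    and polar types positive e*, with magnitudes up to ~2 a.u.  The
    result is a synthetic stand-in, not membrane-protein statistics.
    """
    source = f"synthetic-hydropathy-n{n_per_aa}-seed{seed}"
    # each amino acid gets its own structure; only its own rows are kept,
    # so companion placements never contaminate another type's tally
    clean = BuriednessCounts.zeros(source_set=source)
    for k, aa in enumerate(AMINO_ACIDS):
        companion = "G" if aa != "G" else "A"
        s = make_burial_set(aa, burial_probability(aa), n_per_aa,
                            seed=seed + k, companion_aa=companion)
        own = accumulate_counts([s], source_set=source)
        clean.n_in[aa] = own.n_in[aa]
        clean.n_out[aa] = own.n_out[aa]
    return pseudoenergies(clean)
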