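"""Per-residue energy profiles.

The environment Env(i) of residue i is every other residue whose Cα lies
within a contact cutoff (8 Å, boundary inclusive) of Cα_i.  The total
energy of residue i sums the pairwise pseudoenergy contributions over
that environment:

    E*_i = Σ_{j in Env(i)} (e*_i + e*_j)
         = |Env(i)|·e*_i + Σ_{j in Env(i)} e*_j,

with e* the per-amino-acid buriedness pseudoenergies.  The energy
profile of a structure is the ordered tuple of all E*_i, in residue
order — a one-dimensional, alignable fingerprint of the 3D fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
from scipy.spatial import cKDTree

from .buriedness_stats import PseudoEnergyTable
from .errors import FormatError, TableLookupError
from .structure_io import AMINO_ACIDS, Structure

DEFAULT_CUTOFF = 8.0  # Å, Cα–Cα contact distance, inclusive


@dataclass
class ProfileEntry:
    chain_id: str
    seq_index: int
    aa: str
    energy: float


@dataclass
class EnergyProfile:
    """Ordered per-residue energies with provenance metadata."""

    id: str
    entries: list[ProfileEntry] = field(default_factory=list)
    stats_provenance: str = ""
    contact_radius: float = DEFAULT_CUTOFF

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def energies(self) -> np.ndarray:
        return np.array([e.energy for e in self.entries], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(e.aa for e in self.entries)

    def with_energies(self, energies: Sequence[float], id: str | None = None
                      ) -> "EnergyProfile":
        if len(energies) != len(self.entries):
            raise ValueError("energy vector length mismatch")
        return EnergyProfile(
            id=id if id is not None else self.id,
            entries=[
                ProfileEntry(e.chain_id, e.seq_index, e.aa, float(v))
                for e, v in zip(self.entries, energies)
            ],
            stats_provenance=self.stats_provenance,
            contact_radius=self.contact_radius,
        )


def contact_sets(structure: Structure, cutoff: float = DEFAULT_CUTOFF
                 ) -> list[set[int]]:
    """Contact sets for all residues at once (KD-tree, boundary inclusive)."""
    coords = structure.ca_coords()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff)  # inclusive upper bound
    sets: list[set[int]] = [set() for _ in range(len(coords))]
    for i, j in pairs:
        sets[i].add(j)
        sets[j].add(i)
    return sets


def contacts(structure: Structure, i: int, cutoff: float = DEFAULT_CUTOFF
             ) -> set[int]:
    """Indices j ≠ i with ‖Cα_i − Cα_j‖ ≤ cutoff."""
    coords = structure.ca_coords()
    d = np.linalg.norm(coords - coords[i], axis=1)
    hit = np.flatnonzero(d <= cutoff)
    return {int(j) for j in hit if j != i}


def residue_energy(
    structure: Structure,
    i: int,
    table: PseudoEnergyTable,
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Total energy E*_i of residue i; 0 for a contact-free residue."""
    res = structure.residues[i]
    if res.aa not in table:
        raise TableLookupError(f"no pseudoenergy for amino acid {res.aa!r}")
    total = 0.0
    for j in contacts(structure, i, cutoff=cutoff):
        aa_j = structure.residues[j].aa
        if aa_j not in table:
            raise TableLookupError(f"no pseudoenergy for amino acid {aa_j!r}")
        total += table[res.aa] + table[aa_j]
    return total


def compute_profile(
    structure: Structure,
    table: PseudoEnergyTable,
    cutoff: float = DEFAULT_CUTOFF,
) -> EnergyProfile:
    """Energy profile of a structure (one entry per residue, file order)."""
    for aa in set(structure.sequence()):
        if aa not in table:
            raise TableLookupError(f"no pseudoenergy for amino acid {aa!r}")
    e_self = np.array([table[r.aa] for r in structure.residues], dtype=float)
    sets = contact_sets(structure, cutoff=cutoff)
    entries = []
    for i, res in enumerate(structure.residues):
        env = sets[i]
        energy = len(env) * e_self[i] + float(sum(e_self[j] for j in env))
        entries.append(ProfileEntry(res.chain_id, res.seq_index, res.aa, energy))
    return EnergyProfile(
        id=structure.id,
        entries=entries,
        stats_provenance=table.source_set,
        contact_radius=cutoff,
    )


def compute_profiles_per_chain(
    structure: Structure, table: PseudoEnergyTable, cutoff: float = DEFAULT_CUTOFF
) -> list[EnergyProfile]:
    """One profile per chain (contacts never cross chain boundaries)."""
    return [compute_profile(c, table, cutoff=cutoff)
            for c in structure.split_chains()]


# ---------------------------------------------------------------------------
# profile text format

def write_profile(profile: EnergyProfile, fh: TextIO) -> None:
    fh.write(f"# id: {profile.id}\n")
    fh.write(f"# stats: {profile.stats_provenance}\n")
    fh.write(f"# cutoff: {profile.contact_radius}\n")
    for e in profile.entries:
        fh.write(f"{e.chain_id}\t{e.seq_index}\t{e.aa}\t{e.energy:.10g}\n")


def read_profile(fh: TextIO) -> EnergyProfile:
    meta: dict[str, str] = {}
    entries: list[ProfileEntry] = []
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"line {lineno}: expected 4 tab-separated fields")
        chain, seq, aa, energy = fields
        if aa not in AMINO_ACIDS:
            raise FormatError(f"line {lineno}: unknown amino acid {aa!r}")
        try:
            entries.append(ProfileEntry(chain, int(seq), aa, float(energy)))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    if not entries:
        raise FormatError("profile has no entries")
    return EnergyProfile(
        id=meta.get("id", "profile"),
        entries=entries,
        stats_provenance=meta.get("stats", ""),
        contact_radius=float(meta.get("cutoff", DEFAULT_CUTOFF)),
    )


def write_profile_file(profile: EnergyProfile, path) -> None:
    with open(path, "w") as fh:
        write_profile(profile, fh)


def read_profile_file(path) -> EnergyProfile:
    with open(path) as fh:
        return read_profile(fh)
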