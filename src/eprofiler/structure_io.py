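"""Reading and writing the minimal per-residue structure representation.

The energy model only needs, for every residue, the chain it belongs to,
its author numbering, its amino-acid type and the coordinates of the
Cα atom (plus Cβ, or the backbone N/C atoms from which a virtual Cβ can
be reconstructed).  This module extracts exactly that from PDB coordinate
files via Biopython and writes it back out as minimal PDB for fixtures.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .errors import EmptyStructureError, FormatError, GeometryError

log = logging.getLogger(__name__)

#: canonical three-letter -> one-letter codes; MSE (selenomethionine) is
#: treated as methionine, the only HETATM retained.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

AMINO_ACIDS = tuple(sorted(ONE_TO_THREE))  # 20 one-letter codes

#: ideal Cα–Cβ bond length in Å
CBETA_BOND_LENGTH = 1.53


@dataclass
class Residue:
    """One residue reduced to the coordinates the energy model uses.

    ``seq_index`` is the author residue number; ``icode`` preserves
    insertion-code ordering.  ``cb`` is ``None`` for glycine or when the
    Cβ atom is missing from the file; ``n``/``c`` backbone coordinates are
    kept so a virtual Cβ can be built on demand.
    """

    chain_id: str
    seq_index: int
    aa: str
    ca: np.ndarray
    cb: np.ndarray | None = None
    n: np.ndarray | None = None
    c: np.ndarray | None = None
    icode: str = " "

    def effective_cb(self) -> np.ndarray | None:
        """Real Cβ if present, otherwise a virtual one from N/Cα/C.

        Returns ``None`` when neither route is available; the buriedness
        classifier then falls back to the distance criterion alone.
        """
        if self.cb is not None:
            return self.cb
        if self.n is not None and self.c is not None:
            try:
                return virtual_cbeta(self.n, self.ca, self.c)
            except GeometryError:
                return None
        return None


@dataclass
class Structure:
    """An ordered list of residues, in file order within each chain."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> "Structure":
        res = [r for r in self.residues if r.chain_id == chain_id]
        return Structure(id=f"{self.id}_{chain_id}", residues=res)

    def split_chains(self) -> list["Structure"]:
        return [self.chain(c) for c in self.chain_ids()]

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy: x -> R @ x + t for every stored coordinate."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)

        def tx(v):
            return None if v is None else R @ v + t

        return Structure(
            id=self.id,
            residues=[
                replace(r, ca=tx(r.ca), cb=tx(r.cb), n=tx(r.n), c=tx(r.c))
                for r in self.residues
            ],
        )


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral Cβ position from the backbone N, Cα, C atoms.

    The Cβ direction is a fixed linear combination of the two backbone
    bond vectors and their cross product, rescaled to the ideal 1.53 Å
    Cα–Cβ bond length.  Deterministic; equivariant under rigid motion.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    b1 = ca - n
    b2 = c - ca
    b3 = np.cross(b1, b2)
    if np.linalg.norm(b3) < 1e-8:
        raise GeometryError("backbone N, CA, C are collinear or coincident")
    v = -0.58273431 * b3 + 0.56802827 * b1 - 0.54067466 * b2
    norm = np.linalg.norm(v)
    if norm < 1e-8:
        raise GeometryError("degenerate backbone geometry")
    return ca + CBETA_BOND_LENGTH * v / norm


def _first_altloc(residue, name: str):
    """Return the coordinate of atom `name`, first altloc, or None."""
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        atom = atom.disordered_get_list()[0]
    return np.array(atom.get_coord(), dtype=float)


def read_structure(
    pdb_text: str,
    structure_id: str = "structure",
    model_index: int = 0,
    chains: Sequence[str] | None = None,
) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Keeps the first altloc of each atom, preserves insertion-code order,
    drops HETATM records except MSE (mapped to methionine) and drops
    residues without a Cα or with a non-canonical type (logged).
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            bio = parser.get_structure(structure_id, io.StringIO(pdb_text))
        except Exception as exc:  # Biopython raises bare exceptions on bad input
            raise FormatError(f"cannot parse PDB input: {exc}") from exc

    models = list(bio)
    if not models:
        raise FormatError("PDB input contains no model")
    if model_index >= len(models):
        raise FormatError(
            f"model index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]

    residues: list[Residue] = []
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            resname = res.get_resname().strip()
            if hetflag != " " and resname != "MSE":
                continue
            if resname not in THREE_TO_ONE:
                log.warning("dropping non-canonical residue %s %s%s", resname,
                            chain.id, resseq)
                continue
            ca = _first_altloc(res, "CA")
            if ca is None:
                log.warning("dropping residue without CA: %s %s%s", resname,
                            chain.id, resseq)
                continue
            residues.append(
                Residue(
                    chain_id=chain.id,
                    seq_index=resseq,
                    aa=THREE_TO_ONE[resname],
                    ca=ca,
                    cb=_first_altloc(res, "CB"),
                    n=_first_altloc(res, "N"),
                    c=_first_altloc(res, "C"),
                    icode=icode,
                )
            )
    if not residues:
        raise EmptyStructureError("no canonical residues with Cα found")
    return Structure(id=structure_id, residues=residues)


def read_structure_file(path, **kwargs) -> Structure:
    with open(path) as fh:
        text = fh.read()
    sid = kwargs.pop("structure_id", None)
    if sid is None:
        import os

        sid = os.path.splitext(os.path.basename(str(path)))[0]
    return read_structure(text, structure_id=sid, **kwargs)


def write_structure(structure: Structure) -> str:
    """Serialize to minimal PDB (N, CA, C, CB atoms only; 3 decimals)."""
    lines: list[str] = []
    serial = 1
    three = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}
    for r in structure.residues:
        for name, coord in (("N", r.n), ("CA", r.ca), ("C", r.c), ("CB", r.cb)):
            if coord is None:
                continue
            lines.append(
                "ATOM  {serial:5d} {name:^4s}{alt}{res:>3s} {chain}{seq:4d}{icode}"
                "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                    serial=serial,
                    name=name,
                    alt=" ",
                    res=three[r.aa],
                    chain=r.chain_id,
                    seq=r.seq_index,
                    icode=r.icode,
                    x=coord[0],
                    y=coord[1],
                    z=coord[2],
                    occ=1.0,
                    b=0.0,
                    el=name[0],
                )
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
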