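"""Shared fixtures: a synthetic PDB snippet and the bundled energy table.

The alanine in the PDB fixture is idealized, not deposited: its backbone
uses textbook bond lengths/angles and its Cβ was placed independently by
internal-coordinate construction (see oracles.ideal_alanine), so it can
serve as a reference for virtual-Cβ reconstruction.
"""

import numpy as np
import pytest

from eprofiler.buriedness_stats import default_table as _default_table
from eprofiler.profile import compute_profile
from eprofiler.synthetic import SyntheticSpec, make_helix

from oracles import ideal_alanine


def _pdb_line(record, serial, name, altloc, resname, chain, resseq, icode,
              xyz, occ=1.0):
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {name[0]:>2s}"
    )


@pytest.fixture(scope="session")
def ala_backbone():
    """Idealized alanine N/CA/C/CB coordinates (synthetic, see oracles)."""
    return ideal_alanine()


@pytest.fixture(scope="session")
def pdb_fixture(ala_backbone):
    """Hand-built synthetic PDB exercising the parser's corner cases.

    Chain A: idealized ALA (with altloc on CA), GLY without CB, MSE as
    HETATM; chain B: one VAL; plus a water HETATM that must be dropped.
    """
    n, ca, c, cb = (ala_backbone[k] for k in ("N", "CA", "C", "CB"))
    shift = np.array([10.0, 10.0, 10.0])
    lines = [
        _pdb_line("ATOM", 1, "N", " ", "ALA", "A", 1, " ", n + shift),
        _pdb_line("ATOM", 2, "CA", "A", "ALA", "A", 1, " ", ca + shift, 0.6),
        _pdb_line("ATOM", 3, "CA", "B", "ALA", "A", 1, " ",
                  ca + shift + 0.5, 0.4),
        _pdb_line("ATOM", 4, "C", " ", "ALA", "A", 1, " ", c + shift),
        _pdb_line("ATOM", 5, "CB", " ", "ALA", "A", 1, " ", cb + shift),
        _pdb_line("ATOM", 6, "N", " ", "GLY", "A", 2, " ",
                  np.array([13.8, 10.0, 10.0])),
        _pdb_line("ATOM", 7, "CA", " ", "GLY", "A", 2, " ",
                  np.array([14.8, 11.0, 10.0])),
        _pdb_line("ATOM", 8, "C", " ", "GLY", "A", 2, " ",
                  np.array([15.8, 10.5, 9.0])),
        _pdb_line("HETATM", 9, "CA", " ", "MSE", "A", 3, " ",
                  np.array([18.0, 10.0, 10.0])),
        _pdb_line("HETATM", 10, "CB", " ", "MSE", "A", 3, " ",
                  np.array([18.5, 11.3, 10.2])),
        _pdb_line("HETATM", 11, "O", " ", "HOH", "A", 101, " ",
                  np.array([25.0, 25.0, 25.0])),
        "TER",
        _pdb_line("ATOM", 12, "CA", " ", "VAL", "B", 1, " ",
                  np.array([0.0, 0.0, 0.0])),
        _pdb_line("ATOM", 13, "CB", " ", "VAL", "B", 1, " ",
                  np.array([0.0, 0.0, 1.53])),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def table():
    return _default_table()


@pytest.fixture(scope="session")
def helix60_profile(table):
    s = make_helix(SyntheticSpec(n_residues=60, seed=1), structure_id="h60")
    return compute_profile(s, table)
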