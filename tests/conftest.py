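import numpy as np
import pytest

from rnagauss import writhe_matrix
from rnagauss.synthetic import random_walk


def pdb_atom_line(serial, x, y, z, resnum, name=" P  ", alt=" ", resname="  U",
                  chain="A", element=" P"):
    """One fixed-column ATOM record for hand-written fixtures."""
    return (
        f"ATOM  {serial:>5d} {name:<4s}{alt:1s}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def write_pdb_text(tmp_path):
    """Write raw PDB record lines to a temp file and return the path."""

    def _write(lines, name="fixture.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def walk_curve():
    return random_walk(10, seed=1)


@pytest.fixture
def walk_W(walk_curve):
    return writhe_matrix(walk_curve)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
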