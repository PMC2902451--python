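"""Extraction of RNA phosphorus-atom backbone traces from PDB files.

An RNA chain is reduced to the ordered polygonal space curve through its
phosphorus (P) atoms, one per nucleotide.  That curve is the sole input to
the Gauss-integral descriptor: bases, sugars and everything else in the
coordinate file are ignored.

Parsing goes through :mod:`gemmi`.  Selection rules mirror the behaviour a
scanning tool needs to be deterministic on arbitrary deposited files:

* first model unless ``model_index`` says otherwise;
* first chain containing at least one P atom unless ``chain_id`` is given;
* residues are taken in file order within the chain;
* altloc '' or 'A' only; modified nucleotides (HETATM) with a P atom are
  part of the backbone and kept; waters, free phosphate and other
  non-backbone heteroatoms are dropped;
* a nucleotide lacking a P atom is skipped and the two neighbouring P atoms
  are joined by a single straight segment, so the curve stays one connected
  polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "ChainSelector",
    "BackboneCurve",
    "StructureError",
    "ChainNotFoundError",
    "CurveTooShortError",
    "parse_structure",
    "validate_curve",
]

#: Residues never part of a nucleic-acid backbone even when they contain P.
_NON_BACKBONE = {"HOH", "WAT", "DOD", "PO4", "PO3", "2HP", "PI", "SO4"}

#: Minimum points for the descriptor: the order-3 integral superposes six
#: segments, so chains of 7 or fewer nucleotides are rejected.
MIN_POINTS = 8

_MIN_SEGMENT = 1e-6  # Angstrom; consecutive P atoms closer than this are degenerate


class StructureError(ValueError):
    """A PDB file could not be parsed or contains no usable chain."""


class ChainNotFoundError(StructureError):
    """The requested chain/model is absent or has no P atoms."""


class CurveTooShortError(StructureError):
    """Chain has <= 7 nucleotides; the descriptor is undefined."""


@dataclass(frozen=True)
class ChainSelector:
    """Which chain of which model of which file to extract.

    ``model_index`` is 1-based, matching PDB MODEL numbering; ``None`` means
    the first model.  ``chain_id`` of ``None`` means the first chain that
    contains a P atom.
    """

    pdb_path: str | Path
    chain_id: str | None = None
    model_index: int | None = None

    def __post_init__(self) -> None:
        if self.model_index is not None and self.model_index < 1:
            raise ValueError("model_index must be >= 1")


@dataclass
class BackboneCurve:
    """Ordered P-atom positions of one RNA chain (the polygonal curve).

    ``points`` is an (N, 3) float array in Angstrom; ``residue_labels`` is a
    parallel sequence of human-readable residue identifiers.
    """

    entry_id: str
    points: np.ndarray
    residue_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if not self.residue_labels:
            self.residue_labels = [str(i + 1) for i in range(len(self.points))]
        if len(self.points) != len(self.residue_labels):
            raise ValueError("points and residue_labels must be parallel")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if len(self.points) >= 2:
            steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(steps < _MIN_SEGMENT):
                raise ValueError("consecutive points coincide (zero-length segment)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_segments(self) -> int:
        return max(len(self.points) - 1, 0)


def _p_position(residue: gemmi.Residue) -> gemmi.Position | None:
    for atom in residue:
        if atom.name.strip() == "P" and atom.altloc in ("\0", "", "A"):
            return atom.pos
    return None


def _chain_trace(chain: gemmi.Chain) -> tuple[list[list[float]], list[str]]:
    points: list[list[float]] = []
    labels: list[str] = []
    for residue in chain:
        if residue.name.strip().upper() in _NON_BACKBONE:
            continue
        pos = _p_position(residue)
        if pos is None:
            continue  # missing P: bridge to the next observed one
        points.append([pos.x, pos.y, pos.z])
        labels.append(f"{residue.name.strip()}{residue.seqid.num}")
    return points, labels


def parse_structure(sel: ChainSelector) -> BackboneCurve:
    """Read a PDB file and return the P-atom trace of the selected chain.

    Raises :class:`FileNotFoundError` for a missing file,
    :class:`ChainNotFoundError` when the requested model/chain does not
    exist or no chain carries P atoms, :class:`StructureError` for files
    gemmi cannot parse.
    """
    path = Path(sel.pdb_path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureError(f"{path} contains no coordinate models")

    model_index = sel.model_index or 1
    if model_index > len(structure):
        raise ChainNotFoundError(
            f"{path} has {len(structure)} model(s), model {model_index} requested"
        )
    model = structure[model_index - 1]

    candidates = list(model)
    if sel.chain_id is not None:
        candidates = [c for c in model if c.name == sel.chain_id]
        if not candidates:
            raise ChainNotFoundError(f"chain {sel.chain_id!r} not found in {path}")

    for chain in candidates:
        points, labels = _chain_trace(chain)
        if points:
            entry_id = f"{path.stem}_{chain.name}" if chain.name else path.stem
            return BackboneCurve(entry_id, np.array(points), labels)

    which = f"chain {sel.chain_id!r}" if sel.chain_id else "any chain"
    raise ChainNotFoundError(f"no P atoms found in {which} of {path}")


def validate_curve(curve: BackboneCurve) -> BackboneCurve:
    """Pass the curve through iff it is long enough for the descriptor.

    The order-3 Gauss integral needs six distinct segments, so molecules
    with more than 7 nucleotides are required; shorter chains raise
    :class:`CurveTooShortError`.
    """
    if len(curve) < MIN_POINTS:
        raise CurveTooShortError(
            f"{curve.entry_id}: {len(curve)} P atoms; descriptor requires more "
            f"than 7 nucleotides"
        )
    return curve
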