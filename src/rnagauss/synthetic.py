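"""Synthetic backbone curves with known topological properties.

Every other part of the package is testable without downloading deposited
structures: a planar zigzag has identically vanishing Gauss integrals, a
helix is chiral (its mirror image flips the sign of every odd invariant), a
seeded random walk gives reproducible generic curves, and jittered copies
of a curve emulate independently determined structures of the same fold.

Geometry defaults mimic RNA backbone scale -- consecutive P atoms ~6 A
apart, A-form-like helix radius and rise -- but no attempt is made at real
stereochemistry: each residue is a single P atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .structure_io import BackboneCurve

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "planar_zigzag",
    "helix",
    "random_walk",
    "perturbed_copy",
    "mirrored",
    "transformed",
    "scaled",
    "random_rotation",
    "write_fixture_pdb",
]

#: canonical synthetic P-P spacing in Angstrom (typical RNA backbone step)
STEP_LENGTH = 6.0

_KINDS = ("planar_zigzag", "helix", "random_walk", "mirror_pair", "perturbed_copy")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic curve (or curve pair)."""

    kind: str
    n_points: int
    seed: int = 0
    helix_radius: float = 9.4
    helix_rise: float = 2.81
    jitter_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")
        if self.helix_radius <= 0:
            raise ValueError("helix radius must be > 0")


def planar_zigzag(n_points: int, entry_id: str | None = None) -> BackboneCurve:
    """Zigzag in the z=0 plane, step length exactly 6 A; all integrals 0."""
    k = np.arange(n_points)
    dx = np.sqrt(STEP_LENGTH**2 - 3.0**2)
    pts = np.stack([k * dx, 3.0 * (k % 2), np.zeros(n_points)], axis=1)
    return BackboneCurve(entry_id or f"ZIGZAG{n_points}_A", pts)


def helix(
    n_points: int,
    radius: float = 9.4,
    rise: float = 2.81,
    points_per_turn: float = 11.0,
    entry_id: str | None = None,
) -> BackboneCurve:
    """Right-handed circular helix at roughly A-form RNA dimensions."""
    k = np.arange(n_points)
    theta = 2.0 * np.pi * k / points_per_turn
    pts = np.stack([radius * np.cos(theta), radius * np.sin(theta), rise * k], axis=1)
    return BackboneCurve(entry_id or f"HELIX{n_points}_A", pts)


def random_walk(
    n_points: int, seed: int = 0, step: float = STEP_LENGTH,
    entry_id: str | None = None,
) -> BackboneCurve:
    """Seeded random walk with fixed step length (not self-avoiding)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_points - 1, 3))
    steps *= step / np.linalg.norm(steps, axis=1, keepdims=True)
    pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return BackboneCurve(entry_id or f"WALK{n_points}S{seed}_A", pts)


def perturbed_copy(
    curve: BackboneCurve, sigma: float = 0.3, seed: int = 0,
    entry_id: str | None = None,
) -> BackboneCurve:
    """Gaussian coordinate jitter, emulating an independent determination
    of the same fold (sigma in Angstrom)."""
    rng = np.random.default_rng(seed)
    pts = curve.points + rng.normal(scale=sigma, size=curve.points.shape)
    return BackboneCurve(
        entry_id or f"{curve.entry_id}~J{seed}", pts, list(curve.residue_labels)
    )


def mirrored(curve: BackboneCurve, entry_id: str | None = None) -> BackboneCurve:
    """Reflection through the z=0 plane (chirality flip)."""
    pts = curve.points * np.array([1.0, 1.0, -1.0])
    return BackboneCurve(
        entry_id or f"{curve.entry_id}~M", pts, list(curve.residue_labels)
    )


def transformed(
    curve: BackboneCurve, rotation: np.ndarray, translation=0.0,
    entry_id: str | None = None,
) -> BackboneCurve:
    """Rigid motion: ``R x + t`` applied to every point."""
    pts = curve.points @ np.asarray(rotation).T + translation
    return BackboneCurve(
        entry_id or f"{curve.entry_id}~T", pts, list(curve.residue_labels)
    )


def scaled(curve: BackboneCurve, factor: float,
           entry_id: str | None = None) -> BackboneCurve:
    """Uniform scaling about the origin."""
    return BackboneCurve(
        entry_id or f"{curve.entry_id}~S", curve.points * factor,
        list(curve.residue_labels),
    )


def random_rotation(rng=None) -> np.ndarray:
    """Haar-uniform 3x3 rotation matrix (QR of a Gaussian matrix)."""
    rng = np.random.default_rng(rng)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_fixture(spec: FixtureSpec):
    """Build the curve (or ``(curve, mirror)`` pair for ``mirror_pair``)
    described by a :class:`FixtureSpec`; deterministic given the seed."""
    if spec.kind == "planar_zigzag":
        return planar_zigzag(spec.n_points)
    if spec.kind == "helix":
        return helix(spec.n_points, radius=spec.helix_radius, rise=spec.helix_rise)
    if spec.kind == "random_walk":
        return random_walk(spec.n_points, seed=spec.seed)
    if spec.kind == "perturbed_copy":
        base = helix(spec.n_points, radius=spec.helix_radius, rise=spec.helix_rise)
        return perturbed_copy(base, sigma=spec.jitter_sigma, seed=spec.seed)
    base = helix(spec.n_points, radius=spec.helix_radius, rise=spec.helix_rise)
    return base, mirrored(base)


def write_fixture_pdb(curves, path: str | Path) -> Path:
    """Write one curve (or several, as successive MODELs) to a minimal PDB.

    One uridine residue with a single P atom per backbone point; coordinates
    keep the format's 3-decimal precision, so a write/parse round trip
    agrees to 1e-3 A.
    """
    if isinstance(curves, BackboneCurve):
        curves = [curves]
    structure = gemmi.Structure()
    structure.name = curves[0].entry_id
    for curve in curves:
        model = gemmi.Model(len(structure) + 1)
        chain = gemmi.Chain("A")
        for i, (x, y, z) in enumerate(curve.points):
            residue = gemmi.Residue()
            residue.name = "U"
            residue.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "P"
            atom.element = gemmi.Element("P")
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 0.0
            residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    path = Path(path)
    structure.write_pdb(str(path))
    return path
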