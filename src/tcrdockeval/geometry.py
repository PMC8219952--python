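"""Least-squares rigid superposition (Kabsch) and fixed-frame RMSD.

This is the numerical kernel behind every RMSD reported by the pipeline:
ligand RMSD and interface RMSD of docked models, bound/unbound difficulty
I-RMSD, and the framework-superposed CDR loop RMSDs.  The superposition is
the classic SVD solution of the orthogonal Procrustes problem with the
reflection correction, unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .errors import CorrespondenceError, DegenerateInputError


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t`` in Angstroms.

    ``rotation`` is orthonormal with determinant +1 (checked on
    construction to 1e-8); improper (reflecting) matrices are rejected.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise ValueError("rotation is not proper (det != +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class CoordSet:
    """An ordered, labelled set of atomic coordinates.

    ``labels`` identify atoms (typically ``(ResidueKey, atom_name)`` tuples)
    and define the correspondence between two sets being compared; ``coords``
    is the matching (N, 3) array in Angstroms.
    """

    labels: Sequence[Hashable]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coords must have equal length")
        if len(self.coords) < 1:
            raise ValueError("CoordSet must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)


def _check_labels(a: CoordSet, b: CoordSet) -> None:
    if len(a) != len(b) or list(a.labels) != list(b.labels):
        raise CorrespondenceError(
            f"coordinate sets do not correspond ({len(a)} vs {len(b)} atoms)"
        )


def kabsch(mobile: CoordSet, target: CoordSet) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``target``.

    Returns the rigid transform minimising the RMSD between the transformed
    mobile set and the target, together with that minimised RMSD.  If the
    smallest singular value direction would require a reflection its sign is
    flipped, so the result is always a proper rotation.

    Raises
    ------
    DegenerateInputError
        Fewer than three atom pairs.
    CorrespondenceError
        Label sequences differ.
    """
    _check_labels(mobile, target)
    if len(mobile) < 3:
        raise DegenerateInputError("superposition needs at least 3 atom pairs")

    x = mobile.coords
    y = target.coords
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc

    # rank < 2 means the points are collinear and the rotation about the
    # line is undetermined; the minimised RMSD is still well defined
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        warnings.warn("all points are collinear; rotation is not unique", stacklevel=2)

    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T

    residual = x0 @ rotation.T - y0
    rmsd = float(np.sqrt((residual**2).sum() / len(x)))
    translation = yc - rotation @ xc
    return RigidTransform(rotation, translation), rmsd


def rmsd_fixed(a: CoordSet, b: CoordSet) -> float:
    """Root-mean-square deviation between two sets without re-fitting.

    Used for ligand RMSD and loop RMSD, where the superposition frame is
    defined by a different atom subset (receptor, framework) than the one
    being measured.
    """
    _check_labels(a, b)
    d = a.coords - b.coords
    return float(np.sqrt((d**2).sum() / len(a)))
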