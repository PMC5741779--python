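"""Rigid-body least-squares superposition (Kabsch) over an atom subset.

The transition-state structure is aligned onto the substrate frame over
a chosen pairing of atoms — typically the conserved reactant skeleton,
since the geometries differ most near the reacting bond.  Rotations are
always proper (det +1); the reflection branch of the underlying SVD is
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, UsageError
from .structures_io import Molecule

__all__ = ["RigidTransform", "AtomPairing", "kabsch_superpose", "apply_transform", "rmsd"]


@dataclass(frozen=True)
class RigidTransform:
    """x → R·x + t with R a proper rotation and t in Å."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise UsageError("rotation matrix must have determinant +1")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise UsageError("rotation matrix must be orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class AtomPairing:
    """(mobile index, reference index) pairs, 1-based, defining the subset."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(m), int(r)) for m, r in self.pairs)
        if len({m for m, _ in pairs}) != len(pairs) or len({r for _, r in pairs}) != len(pairs):
            raise UsageError("duplicate atom index in pairing")
        if any(m < 1 or r < 1 for m, r in pairs):
            raise UsageError("atom indices are 1-based and must be ≥ 1")
        object.__setattr__(self, "pairs", pairs)

    @classmethod
    def identity(cls, n: int) -> "AtomPairing":
        return cls(tuple((i, i) for i in range(1, n + 1)))

    def __len__(self) -> int:
        return len(self.pairs)

    def check_bounds(self, n_mobile: int, n_reference: int) -> None:
        for m, r in self.pairs:
            if m > n_mobile or r > n_reference:
                raise UsageError(
                    f"pair ({m}, {r}) out of bounds for molecules of size "
                    f"{n_mobile} and {n_reference}"
                )

    def select(self, mobile: Molecule, reference: Molecule) -> tuple[np.ndarray, np.ndarray]:
        self.check_bounds(len(mobile), len(reference))
        mpos = mobile.positions
        rpos = reference.positions
        mi = np.array([m - 1 for m, _ in self.pairs])
        ri = np.array([r - 1 for _, r in self.pairs])
        return mpos[mi], rpos[ri]


def _require_noncollinear(ref: np.ndarray) -> None:
    centered = ref - ref.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(1.0, s[0]):
        raise DegenerateGeometryError(
            "reference subset is collinear; the rotation is not unique"
        )


def kabsch_superpose(
    mobile: Molecule, reference: Molecule, pairing: AtomPairing
) -> tuple[RigidTransform, float]:
    """Best-fit rigid transform taking *mobile* onto *reference*.

    Returns the transform minimizing the RMSD over the paired atoms and
    that minimal RMSD (Å).  Requires ≥ 3 non-collinear reference atoms.
    """
    if len(pairing) < 3:
        raise DegenerateGeometryError(
            f"need ≥ 3 atom pairs for a unique rotation, got {len(pairing)}"
        )
    mob, ref = pairing.select(mobile, reference)
    _require_noncollinear(ref)
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    # recompute the residual from coordinates: the solver's reported rssd
    # loses ~1e-7 absolute precision to cancellation at zero residual
    moved = mob @ R.T + t
    best = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return RigidTransform(R, t), best


def apply_transform(mol: Molecule, t: RigidTransform) -> Molecule:
    """Map every atom position x → R·x + t; order, elements, labels unchanged."""
    return mol.with_positions(t.apply(mol.positions))


def rmsd(a: Molecule, b: Molecule, pairing: AtomPairing) -> float:
    """Root-mean-square of paired inter-atom distances (Å); no alignment."""
    if len(pairing) == 0:
        raise UsageError("rmsd of an empty pairing is undefined")
    pa, pb = pairing.select(a, b)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
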