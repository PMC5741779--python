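"""Molecular electrostatic potential from atom-centered multipoles.

The potential at a point r generated by atom a at r_a, with monopole
q_a (e), dipole μ_a (e·bohr) and traceless quadrupole Θ_a (e·bohr²), is
the truncated multipole series in atomic units

    V(r) = Σ_a [ q_a/R + (μ_a·R)/R³ + Σ_ij Θ_a,ij (3 R_i R_j − R² δ_ij) / (2 R⁵) ]

with R = r − r_a converted to bohr.  The result is reported in
kcal mol⁻¹ e⁻¹.  This is a vacuum point-multipole model: no dielectric
screening, no periodicity, no penetration correction.  Points closer
than 0.3 bohr to any center are rejected, because the series diverges
at the expansion centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM_TO_BOHR, HARTREE_TO_KCAL_PER_MOL, PROXIMITY_GUARD_BOHR
from .errors import ProximityError
from .structures_io import AtomicMultipoleSet, Molecule, _detrace

__all__ = [
    "PotentialValue",
    "MolecularMoments",
    "potential_at_point",
    "potential_on_grid",
    "molecular_moments",
]


@dataclass(frozen=True)
class PotentialValue:
    """The MEP at one point: position in Å, V in kcal mol⁻¹ e⁻¹."""

    point: np.ndarray
    V: float


@dataclass(frozen=True)
class MolecularMoments:
    """Whole-molecule moments about an origin — a sanity diagnostic.

    Q in e, D in e·bohr, T traceless in e·bohr².
    """

    origin: np.ndarray  # Å
    Q: float
    D: np.ndarray  # (3,)
    T: np.ndarray  # (3, 3)


def _check_pair(mol: Molecule, mps: AtomicMultipoleSet) -> None:
    if len(mps) != len(mol):
        raise ValueError(
            f"multipole set has {len(mps)} entries but molecule "
            f"{mol.name!r} has {len(mol)} atoms"
        )


def _potential_hartree(
    pos_bohr: np.ndarray, mps: AtomicMultipoleSet, point_bohr: np.ndarray, order: int
) -> float:
    d = point_bohr - pos_bohr  # atom → point, (N, 3)
    r2 = np.einsum("ai,ai->a", d, d)
    r = np.sqrt(r2)
    k = int(np.argmin(r))
    if r[k] <= PROXIMITY_GUARD_BOHR:
        raise ProximityError(
            f"evaluation point is {r[k]:.3f} bohr from atom {k + 1} "
            f"(guard radius {PROXIMITY_GUARD_BOHR} bohr)"
        )
    v = np.sum(mps.q / r)
    if order >= 1:
        v += np.sum(np.einsum("ai,ai->a", mps.mu, d) / r**3)
    if order >= 2:
        dtd = np.einsum("aij,ai,aj->a", mps.theta, d, d)
        tr = np.trace(mps.theta, axis1=-2, axis2=-1)
        v += np.sum((3.0 * dtd - r2 * tr) / (2.0 * r2**2 * r))
    return float(v)


def potential_at_point(
    mol: Molecule,
    mps: AtomicMultipoleSet,
    point: np.ndarray,
    order: int | None = None,
) -> PotentialValue:
    """Evaluate the MEP of (*mol*, *mps*) at *point* (Å).

    *order* truncates the expansion below the set's own order; by
    default the set's full order is used.  Raises
    :class:`~catfield.errors.ProximityError` inside the 0.3 bohr guard.
    """
    _check_pair(mol, mps)
    point = np.asarray(point, dtype=float).reshape(3)
    if order is None:
        order = mps.order
    v_h = _potential_hartree(
        mol.positions * ANGSTROM_TO_BOHR, mps, point * ANGSTROM_TO_BOHR, order
    )
    return PotentialValue(point=point, V=v_h * HARTREE_TO_KCAL_PER_MOL)


def potential_on_grid(
    mol: Molecule,
    mps: AtomicMultipoleSet,
    points,
    order: int | None = None,
) -> list[PotentialValue]:
    """Batched :func:`potential_at_point`; element-wise identical to it.

    Proximity errors are re-raised with the offending point index.
    """
    out: list[PotentialValue] = []
    for i, p in enumerate(points):
        try:
            out.append(potential_at_point(mol, mps, p, order=order))
        except ProximityError as exc:
            raise ProximityError(f"point {i}: {exc}") from None
    return out


def molecular_moments(
    mol: Molecule, mps: AtomicMultipoleSet, origin: np.ndarray
) -> MolecularMoments:
    """Total charge, dipole and traceless quadrupole about *origin* (Å).

    Atom-centered moments are translated to the common origin with the
    standard shift formulas; the quadrupole uses the Buckingham
    (traceless) convention and is detraced against numerical drift.
    """
    _check_pair(mol, mps)
    origin = np.asarray(origin, dtype=float).reshape(3)
    d = (mol.positions - origin) * ANGSTROM_TO_BOHR  # (N, 3), bohr
    q = mps.q
    mu = mps.mu
    Q = float(np.sum(q))
    D = np.sum(mu + q[:, None] * d, axis=0)
    d2 = np.einsum("ai,ai->a", d, d)
    eye = np.eye(3)
    # traceless second-moment convention, Θ = Σ q (x_i x_j − r²δ_ij/3):
    # shift terms are dμᵀ + μdᵀ − (2/3)(μ·d)I and q(ddᵀ − d²I/3)
    T = (
        np.sum(mps.theta, axis=0)
        + np.einsum("ai,aj->ij", d, mu)
        + np.einsum("ai,aj->ij", mu, d)
        - (2.0 / 3.0) * np.einsum("ai,ai->", mu, d) * eye
        + np.einsum("a,ai,aj->ij", q, d, d)
        - (1.0 / 3.0) * np.sum(q * d2) * eye
    )
    return MolecularMoments(origin=origin, Q=Q, D=D, T=_detrace(T))
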