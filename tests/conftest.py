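"""Shared fixtures and independent oracles.

The oracle functions here deliberately avoid the code paths they check:
potentials are direct Coulomb loops over explicit point charges, and the
minimum-RMSD oracle searches rotation space by sampling instead of
solving the Kabsch SVD.
"""

from __future__ import annotations

import numpy as np
import pytest

from catfield.constants import ANGSTROM_TO_BOHR, HARTREE_TO_KCAL_PER_MOL
from catfield.structures_io import Atom, Molecule


# ---------------------------------------------------------------- fixtures


def random_molecule(rng: np.random.Generator, n: int = 10, spread: float = 4.0) -> Molecule:
    """n well-separated atoms in a box; used as generic geometry."""
    elements = rng.choice(["C", "N", "O", "H"], size=n)
    positions: list[np.ndarray] = []
    while len(positions) < n:
        cand = rng.uniform(-spread, spread, size=3)
        if all(np.linalg.norm(cand - p) > 0.8 for p in positions):
            positions.append(cand)
    atoms = tuple(
        Atom(index=i + 1, element=el, position=p)
        for i, (el, p) in enumerate(zip(elements, positions))
    )
    return Molecule(name="random", atoms=atoms)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def methane_like() -> Molecule:
    """A tetrahedral CH4-like geometry with 1.09 Å C–H bonds."""
    d = 1.09 / np.sqrt(3.0)
    hs = np.array([[d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]])
    atoms = [Atom(index=1, element="C", position=np.zeros(3))]
    atoms += [Atom(index=i + 2, element="H", position=h) for i, h in enumerate(hs)]
    return Molecule(name="methane-like", atoms=tuple(atoms))


# ------------------------------------------------------- potential oracles


def direct_coulomb_kcal(charges, point) -> float:
    """Plain-loop Coulomb sum over (position_Å, q_e) pairs, in kcal/mol/e."""
    point = np.asarray(point, float)
    total = 0.0
    for pos, q in charges:
        r_bohr = float(np.linalg.norm(point - np.asarray(pos, float))) * ANGSTROM_TO_BOHR
        total += q / r_bohr
    return total * HARTREE_TO_KCAL_PER_MOL


def multipole_site_as_charges(pos_ang, q, mu, theta, delta_bohr=0.01):
    """Realize one atom's (q, μ, Θ) as an explicit finite charge cluster.

    The dipole becomes ±|μ|/δ at ±δ/2 along μ̂; the traceless quadrupole
    (detraced second moment, Θ = Σ q (x_i x_j − r²δ_ij/3)) is
    eigendecomposed and each eigendirection v with eigenvalue λ becomes
    a symmetric linear quadruplet (+λ/(2δ²) at ±δ·v, −λ/δ² at the
    center).  Odd multipole contaminants vanish by symmetry, so the
    cluster's moments match (q, μ, Θ) with O(δ²) relative error in the
    far field.  Positions returned in Å.
    """
    pos = np.asarray(pos_ang, float)
    delta_ang = delta_bohr / ANGSTROM_TO_BOHR
    charges = []
    center_q = float(q)
    mu = np.asarray(mu, float)
    m = np.linalg.norm(mu)
    if m > 0:
        u = mu / m
        qd = m / delta_bohr
        charges.append((pos + 0.5 * delta_ang * u, qd))
        charges.append((pos - 0.5 * delta_ang * u, -qd))
    theta = np.asarray(theta, float)
    if np.any(theta != 0.0):
        lam, vecs = np.linalg.eigh(theta)
        for k in range(3):
            qk = lam[k] / (2.0 * delta_bohr**2)
            v = vecs[:, k]
            charges.append((pos + delta_ang * v, qk))
            charges.append((pos - delta_ang * v, qk))
            center_q -= 2.0 * qk
    charges.append((pos, center_q))
    return charges


# ----------------------------------------------------- rotation-search oracle


def _rodrigues(v: np.ndarray) -> np.ndarray:
    """Rotation matrix for rotation vector v (axis × angle)."""
    angle = np.linalg.norm(v)
    if angle < 1e-15:
        return np.eye(3)
    k = v / angle
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def brute_force_min_rmsd(mobile: np.ndarray, reference: np.ndarray, seed: int = 0) -> float:
    """Minimum RMSD over rigid motions, by sampled rotation search.

    For each candidate rotation the optimal translation is the centroid
    match; the rotation itself is found by coarse random sampling
    followed by shrinking random perturbations (no SVD anywhere).
    """
    rng = np.random.default_rng(seed)
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)

    def score(R: np.ndarray) -> float:
        moved = mobile @ R.T
        moved = moved + (reference.mean(axis=0) - moved.mean(axis=0))
        return float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))

    best_R = np.eye(3)
    best = score(best_R)
    for _ in range(400):  # coarse global sweep
        R = _rodrigues(rng.normal(size=3) * rng.uniform(0.0, np.pi))
        s = score(R)
        if s < best:
            best, best_R = s, R
    scale = 0.5
    for _ in range(80):  # local refinement with shrinking steps
        for _ in range(40):
            v = rng.normal(size=3)
            v *= rng.uniform(0.0, scale) / (np.linalg.norm(v) + 1e-300)
            R = _rodrigues(v) @ best_R
            s = score(R)
            if s < best:
                best, best_R = s, R
        scale *= 0.75
    return best
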