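"""Static catalytic fields: probe placement, Δs, and environment Δ.

The static catalytic field at a point is

    Δs = −(V^TS − V^S)

the activation-barrier lowering (kcal mol⁻¹) produced by a unit
positive point charge at that point: positive Δs means a +1 e charge
there stabilizes the transition state more than the substrate.  An
explicit environment of point charges {q_i} changes the barrier by

    Δ = Σ_i q_i (V^TS(r_i) − V^S(r_i)) = −Σ_i q_i Δs(r_i)

(negative Δ = catalysis).  Both rest on the electrostatic leading term
of differential transition-state stabilization, which is exactly
additive over environment charges.

Probes are defined in the substrate frame after the transition state
has been superposed onto it, so one probe set serves both potentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import vdw_radius
from .electrostatics import potential_at_point
from .errors import ConfigurationError, ProximityError, SiteGeometryError, UsageError
from .structures_io import AtomicMultipoleSet, Molecule
from .superposition import RigidTransform

__all__ = [
    "ProbePoint",
    "ReactantPair",
    "CatalyticFieldValue",
    "EnvironmentCharge",
    "place_bond_probes",
    "place_surface_probes",
    "compute_catalytic_field",
    "environment_barrier_change",
]

#: H is considered bonded to a heavy atom within this distance (Å)
BOND_CUTOFF = 1.3

#: default probe offset beyond the substitution hydrogen (Å)
DEFAULT_PROBE_DISTANCE = 1.5

#: default solvent probe radius (water) for the accessible surface (Å)
DEFAULT_PROBE_RADIUS = 1.4


@dataclass(frozen=True)
class ProbePoint:
    """A point where Δs is evaluated, in the substrate frame (Å).

    ``bond_directed`` probes sit on the extension of a heavy-atom→H bond
    and carry the 1-based index of their hydrogen; ``surface`` probes
    sample the solvent-accessible surface and carry no site.
    """

    position: np.ndarray
    kind: str  # "bond_directed" | "surface"
    site_index: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.kind not in ("bond_directed", "surface"):
            raise UsageError(f"unknown probe kind {self.kind!r}")
        if self.kind == "surface" and self.site_index is not None:
            raise UsageError("surface probes carry no site index")
        if self.kind == "bond_directed" and self.site_index is None:
            raise UsageError("bond-directed probes must reference an H atom")


@dataclass(frozen=True)
class ReactantPair:
    """Aligned substrate / transition-state structures with their multipoles.

    The transition state must already be superposed into the substrate
    frame; the transform used is recorded when available.
    """

    substrate: tuple[Molecule, AtomicMultipoleSet]
    transition: tuple[Molecule, AtomicMultipoleSet]
    direction_label: str = "forward"
    transform: RigidTransform | None = None

    def __post_init__(self) -> None:
        for mol, mps in (self.substrate, self.transition):
            if len(mps) != len(mol):
                raise UsageError(
                    f"{mol.name!r}: multipole set size {len(mps)} does not "
                    f"match atom count {len(mol)}"
                )

    def swapped(self) -> "ReactantPair":
        """The pair with substrate and transition-state roles exchanged."""
        return ReactantPair(
            substrate=self.transition,
            transition=self.substrate,
            direction_label=f"{self.direction_label}-swapped",
            transform=self.transform,
        )


@dataclass(frozen=True)
class CatalyticFieldValue:
    """V^S, V^TS and Δs = −(V^TS − V^S) at one probe, kcal mol⁻¹ e⁻¹."""

    probe: ProbePoint
    V_S: float
    V_TS: float
    delta_s: float


@dataclass(frozen=True)
class EnvironmentCharge:
    """One point charge of the molecular environment: position (Å), q (e)."""

    position: np.ndarray
    q: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not (np.all(np.isfinite(pos)) and np.isfinite(self.q)):
            raise UsageError("environment charge must be finite")
        object.__setattr__(self, "position", pos)


def place_bond_probes(
    mol: Molecule,
    site_indices,
    distance: float = DEFAULT_PROBE_DISTANCE,
) -> list[ProbePoint]:
    """One probe per substitution hydrogen, *distance* Å beyond the H.

    The probe sits at ``r_H + distance·û`` where û points from the
    bonded heavy atom through the H — roughly where the charge center of
    a substituent replacing that H would sit.  Each site must be an H
    with exactly one heavy-atom neighbor within 1.3 Å.
    """
    pos = mol.positions
    probes = []
    for idx in site_indices:
        if not 1 <= idx <= len(mol):
            raise SiteGeometryError(f"site index {idx} out of range 1..{len(mol)}")
        atom = mol.atoms[idx - 1]
        if atom.element != "H":
            raise SiteGeometryError(
                f"site {idx} is {atom.element}, not a hydrogen"
            )
        dist = np.linalg.norm(pos - atom.position, axis=1)
        heavy = [
            j
            for j in range(len(mol))
            if j != idx - 1 and mol.atoms[j].element != "H" and dist[j] <= BOND_CUTOFF
        ]
        if len(heavy) != 1:
            raise SiteGeometryError(
                f"site {idx}: expected exactly one heavy-atom neighbor within "
                f"{BOND_CUTOFF} Å, found {len(heavy)}"
            )
        bond = atom.position - pos[heavy[0]]
        u = bond / np.linalg.norm(bond)
        probes.append(
            ProbePoint(
                position=atom.position + distance * u,
                kind="bond_directed",
                site_index=idx,
            )
        )
    return probes


def _fibonacci_sphere(n: int) -> np.ndarray:
    """*n* near-uniform unit vectors on the sphere (deterministic lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def place_surface_probes(
    mol: Molecule,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    density: float = 1.0,
) -> list[ProbePoint]:
    """Sample the solvent-accessible surface with ~*density* points per Å².

    Each atom's sphere of radius (r_vdW + probe_radius) is covered with a
    deterministic Fibonacci lattice; points inside any other atom's
    enlarged sphere are discarded, so buried atoms contribute nothing.
    """
    try:
        radii = np.array([vdw_radius(el) + probe_radius for el in mol.elements])
    except KeyError as exc:
        raise ConfigurationError(f"no vdW radius for element {exc}") from None
    pos = mol.positions
    probes: list[ProbePoint] = []
    for i in range(len(mol)):
        r = radii[i]
        n_pts = max(1, int(round(density * 4.0 * np.pi * r * r)))
        candidates = pos[i] + r * _fibonacci_sphere(n_pts)
        keep = np.ones(len(candidates), dtype=bool)
        for j in range(len(mol)):
            if j == i:
                continue
            dj = np.linalg.norm(candidates - pos[j], axis=1)
            keep &= dj > radii[j] - 1e-6
        probes.extend(
            ProbePoint(position=p, kind="surface") for p in candidates[keep]
        )
    return probes


def compute_catalytic_field(
    pair: ReactantPair, probes, order: int | None = None
) -> list[CatalyticFieldValue]:
    """Δs = −(V^TS − V^S) at every probe, kcal mol⁻¹ e⁻¹.

    *order* truncates the multipole expansion for both states (defaults
    to each set's own order).  Proximity failures name the probe.
    """
    s_mol, s_mps = pair.substrate
    t_mol, t_mps = pair.transition
    values = []
    for k, probe in enumerate(probes):
        try:
            v_s = potential_at_point(s_mol, s_mps, probe.position, order=order).V
            v_ts = potential_at_point(t_mol, t_mps, probe.position, order=order).V
        except ProximityError as exc:
            raise ProximityError(f"probe {k} (site {probe.site_index}): {exc}") from None
        values.append(
            CatalyticFieldValue(probe=probe, V_S=v_s, V_TS=v_ts, delta_s=-(v_ts - v_s))
        )
    return values


def environment_barrier_change(
    pair: ReactantPair, env, order: int | None = None
) -> float:
    """Barrier change Δ = Σ_i q_i (V^TS(r_i) − V^S(r_i)), kcal mol⁻¹.

    Negative Δ means the environment lowers the barrier (catalysis).
    The sum is exactly additive over charges.
    """
    s_mol, s_mps = pair.substrate
    t_mol, t_mps = pair.transition
    delta = 0.0
    for k, charge in enumerate(env):
        try:
            v_s = potential_at_point(s_mol, s_mps, charge.position, order=order).V
            v_ts = potential_at_point(t_mol, t_mps, charge.position, order=order).V
        except ProximityError as exc:
            raise ProximityError(f"environment charge {k}: {exc}") from None
        delta += charge.q * (v_ts - v_s)
    return delta
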