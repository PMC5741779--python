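"""Self-contained synthetic test systems.

Point-charge-only pairs have exactly summable Coulomb potentials, which
makes them the primary oracle for the field logic; random multipole
clouds exercise the order-1/2 code paths separately; the linear dataset
emulates a set of substitution sites whose barrier changes respond
linearly to the local catalytic field with Gaussian noise.

Every generator is a deterministic function of its arguments and seed;
randomness flows through one explicitly passed numpy Generator, never
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalytic_field import ReactantPair
from .errors import UsageError
from .structures_io import Atom, AtomicMultipoleSet, Molecule
from .substituent_analysis import SubstitutionRecord

__all__ = [
    "FixtureSpec",
    "make_proton_shift_pair",
    "make_random_multipole_cloud",
    "make_linear_dataset",
]

_CLOUD_BOX = 6.0  # Å
_CLOUD_MIN_SEP = 1.2  # Å
_CLOUD_ELEMENTS = ("C", "N", "O", "H")


@dataclass(frozen=True)
class FixtureSpec:
    """A named, seeded fixture request; same spec + seed ⇒ identical output."""

    kind: str  # "proton_shift" | "random_cloud" | "linear_dataset"
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("proton_shift", "random_cloud", "linear_dataset"):
            raise UsageError(f"unknown fixture kind {self.kind!r}")

    def build(self):
        if self.kind == "proton_shift":
            return make_proton_shift_pair(seed=self.seed, **self.params)
        if self.kind == "random_cloud":
            return make_random_multipole_cloud(seed=self.seed, **self.params)
        return make_linear_dataset(seed=self.seed, **self.params)


def _point_charge_molecule(name: str, elements, positions) -> Molecule:
    atoms = tuple(
        Atom(index=i + 1, element=el, position=p)
        for i, (el, p) in enumerate(zip(elements, positions))
    )
    return Molecule(name=name, atoms=atoms, net_charge=0)


def make_proton_shift_pair(
    separation: float = 2.5, shift: float = 1.25, seed: int = 0
) -> ReactantPair:
    """An abstract intramolecular proton transfer as a 3-charge system.

    Two anchor centers carrying −0.5 e sit *separation* Å apart on the x
    axis; a +1 e proton starts at a quarter of the way from donor to
    acceptor and moves *shift* Å toward the acceptor in the transition
    state.  With shift = separation/2 the substrate and transition state
    are mirror images through the perpendicular bisector plane, so Δs
    vanishes on that plane by symmetry.  Both states are neutral,
    monopole-only, and deterministic (the seed is accepted for API
    uniformity).
    """
    if not 0.0 <= shift < separation:
        raise UsageError(f"need 0 ≤ shift < separation, got shift={shift}, separation={separation}")
    donor = np.array([0.0, 0.0, 0.0])
    acceptor = np.array([separation, 0.0, 0.0])
    proton_s = np.array([separation / 4.0, 0.0, 0.0])
    proton_ts = proton_s + np.array([shift, 0.0, 0.0])
    if np.linalg.norm(proton_ts - acceptor) < 0.1:
        raise UsageError("shift places the proton on top of the acceptor anchor")
    q = np.array([-0.5, -0.5, 1.0])
    elements = ("O", "N", "H")
    sub = _point_charge_molecule("proton-shift substrate", elements, [donor, acceptor, proton_s])
    ts = _point_charge_molecule("proton-shift transition state", elements, [donor, acceptor, proton_ts])
    mps = AtomicMultipoleSet(order=0, q=q)
    return ReactantPair(substrate=(sub, mps), transition=(ts, mps), direction_label="forward")


def make_random_multipole_cloud(
    n_atoms: int = 8, order: int = 2, seed: int = 0
) -> tuple[Molecule, AtomicMultipoleSet]:
    """A random neutral cluster with multipoles up to *order*.

    Atoms are placed uniformly in a 6 Å box at least 1.2 Å apart
    (rejection sampling); charges are N(0, 0.3 e) shifted to exact
    neutrality; dipoles are N(0, 0.1 e·bohr) and quadrupoles small
    random symmetric traceless tensors.
    """
    if n_atoms < 1:
        raise UsageError("need at least one atom")
    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n_atoms:
        attempts += 1
        if attempts > 10000 * n_atoms:
            raise UsageError(
                f"could not pack {n_atoms} atoms ≥ {_CLOUD_MIN_SEP} Å apart "
                f"in a {_CLOUD_BOX} Å box"
            )
        cand = rng.uniform(0.0, _CLOUD_BOX, size=3)
        if all(np.linalg.norm(cand - p) >= _CLOUD_MIN_SEP for p in positions):
            positions.append(cand)
    elements = rng.choice(_CLOUD_ELEMENTS, size=n_atoms)
    mol = _point_charge_molecule(f"random multipole cloud (seed {seed})", elements, positions)

    q = rng.normal(0.0, 0.3, size=n_atoms)
    q -= q.mean()  # exact neutrality
    mu = theta = None
    if order >= 1:
        mu = rng.normal(0.0, 0.1, size=(n_atoms, 3))
    if order >= 2:
        raw = rng.normal(0.0, 0.05, size=(n_atoms, 3, 3))
        theta = 0.5 * (raw + np.swapaxes(raw, -1, -2))
        tr = np.trace(theta, axis1=-2, axis2=-1)
        for k in range(3):
            theta[:, k, k] -= tr / 3.0
    return mol, AtomicMultipoleSet(order=order, q=q, mu=mu, theta=theta)


def make_linear_dataset(
    n_sites: int = 50,
    slope: float = 0.15,
    intercept: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> list[SubstitutionRecord]:
    """Substitution records with Δ linear in Δs plus Gaussian noise.

    Δs ~ Uniform(−10, 10) kcal mol⁻¹ e⁻¹ and
    observed Δ = slope·Δs + intercept + N(0, noise_sd); labels "1".."n".
    """
    if n_sites < 2:
        raise UsageError("need at least two sites")
    rng = np.random.default_rng(seed)
    delta_s = rng.uniform(-10.0, 10.0, size=n_sites)
    noise = rng.normal(0.0, noise_sd, size=n_sites) if noise_sd > 0 else np.zeros(n_sites)
    observed = slope * delta_s + intercept + noise
    return [
        SubstitutionRecord(
            site_label=str(i + 1),
            site_index=i + 1,
            delta_s=float(delta_s[i]),
            observed_delta=float(observed[i]),
        )
        for i in range(n_sites)
    ]
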