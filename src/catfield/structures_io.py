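"""Molecular geometries, atomic multipole tables, and field-map output.

Geometry lives in Å.  Multipole moments follow the quantum-chemistry
convention: monopole charge in e, dipole in e·bohr, quadrupole in
e·bohr² as a symmetric *traceless* tensor (the detraced Cartesian
second moment, Θ_ij = Σ q (x_i x_j − r²δ_ij/3)).  Tables whose
quadrupole carries a trace are detraced on load rather than rejected,
because different QM codes disagree about the convention.

Atom identity is file order, 1-based, everywhere; no reader reorders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import BONDI_VDW_RADII
from .errors import FormatError, UsageError

__all__ = [
    "Atom",
    "Molecule",
    "AtomicMultipoleSet",
    "GridSpec",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "read_multipole_table",
    "write_multipole_table",
    "write_field_outputs",
]

_MIN_ATOM_SEPARATION = 0.1  # Å; closer pairs indicate a corrupt file

#: B-factor column of the PDB format is fixed width: clamp |Δs| here
PDB_BFACTOR_CLAMP = 999.99


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, Cartesian position (Å), optional site tag."""

    index: int  # 1-based position in file order
    element: str
    position: np.ndarray  # shape (3,), Å
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.element not in BONDI_VDW_RADII:
            raise FormatError(
                f"atom {self.index}: unknown element symbol {self.element!r}"
            )
        if not np.all(np.isfinite(self.position)):
            raise FormatError(f"atom {self.index}: non-finite coordinates")


@dataclass(frozen=True)
class Molecule:
    """An ordered collection of atoms; the geometric substrate of everything."""

    name: str
    atoms: tuple[Atom, ...]
    net_charge: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        for want, atom in enumerate(self.atoms, start=1):
            if atom.index != want:
                raise FormatError(
                    f"atom indices must be contiguous 1..N; found {atom.index} "
                    f"at position {want}"
                )
        if len(self.atoms) >= 2:
            pos = self.positions
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if d[i, j] < _MIN_ATOM_SEPARATION:
                raise FormatError(
                    f"atoms {i + 1} and {j + 1} are {d[i, j]:.4f} Å apart "
                    f"(< {_MIN_ATOM_SEPARATION} Å): corrupt geometry?"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of coordinates in Å."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    def with_positions(self, positions: np.ndarray, name: str | None = None) -> "Molecule":
        """Copy of the molecule with new coordinates, same atoms/order."""
        positions = np.asarray(positions, dtype=float).reshape(len(self.atoms), 3)
        atoms = tuple(
            replace(a, position=p) for a, p in zip(self.atoms, positions)
        )
        return Molecule(name if name is not None else self.name, atoms, self.net_charge)


def _detrace(theta: np.ndarray) -> np.ndarray:
    """Subtract trace/3 from the diagonal of each (3,3) block."""
    theta = np.asarray(theta, dtype=float)
    tr = np.trace(theta, axis1=-2, axis2=-1)
    out = theta.copy()
    for k in range(3):
        out[..., k, k] -= tr / 3.0
    return out


@dataclass(frozen=True)
class AtomicMultipoleSet:
    """Per-atom multipole moments that generate the electrostatic potential.

    ``order`` truncates the expansion: 0 = monopoles only, 1 = + dipoles,
    2 = + traceless quadrupoles.  Arrays are indexed like the paired
    :class:`Molecule`'s atoms (row i ↔ atom i+1).
    """

    order: int
    q: np.ndarray  # (N,) e
    mu: np.ndarray = field(default=None)  # (N, 3) e·bohr
    theta: np.ndarray = field(default=None)  # (N, 3, 3) e·bohr², traceless

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise UsageError(f"multipole order must be 0, 1 or 2, got {self.order}")
        q = np.asarray(self.q, dtype=float).reshape(-1)
        n = q.shape[0]
        mu = self.mu
        theta = self.theta
        mu = np.zeros((n, 3)) if mu is None else np.asarray(mu, float).reshape(n, 3)
        theta = (
            np.zeros((n, 3, 3))
            if theta is None
            else np.asarray(theta, float).reshape(n, 3, 3)
        )
        if self.order < 1 and np.any(mu != 0.0):
            raise UsageError("order-0 set carries nonzero dipoles")
        if self.order < 2 and np.any(theta != 0.0):
            raise UsageError(f"order-{self.order} set carries nonzero quadrupoles")
        tr = np.trace(theta, axis1=-2, axis2=-1)
        if np.any(np.abs(tr) > 1e-10):
            raise UsageError("quadrupoles must be traceless (|trace| ≤ 1e-10)")
        if not np.allclose(theta, np.swapaxes(theta, -1, -2), atol=1e-12):
            raise UsageError("quadrupoles must be symmetric")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "theta", theta)

    def __len__(self) -> int:
        return self.q.shape[0]


def read_xyz(path) -> Molecule:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` rows).

    Coordinates are Å; the comment line becomes the molecule name; atoms
    keep file order with 1-based indices.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}, line 1: expected an atom count") from None
    body = lines[2 : 2 + count]
    if len(body) < count:
        raise FormatError(
            f"{path}: count line declares {count} atoms but only "
            f"{len(body)} atom rows follow"
        )
    name = lines[1].strip() if len(lines) > 1 else ""
    atoms = []
    for i, line in enumerate(body, start=1):
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}, line {i + 2}: unparseable atom row {line!r}")
        el = parts[0].capitalize()
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise FormatError(
                f"{path}, line {i + 2}: non-numeric coordinate in {line!r}"
            ) from None
        if el not in BONDI_VDW_RADII:
            raise FormatError(f"{path}, line {i + 2}: unknown element {parts[0]!r}")
        atoms.append(Atom(index=i, element=el, position=np.array(xyz)))
    return Molecule(name=name, atoms=tuple(atoms))


def write_xyz(mol: Molecule, path) -> None:
    """Write a standard XYZ file; coordinates to 8 decimals."""
    with open(path, "w") as fh:
        fh.write(f"{len(mol)}\n{mol.name}\n")
        for a in mol.atoms:
            x, y, z = a.position
            fh.write(f"{a.element:<3s} {x:18.8f} {y:18.8f} {z:18.8f}\n")


def read_pdb(path) -> Molecule:
    """Minimal PDB coordinate reader (ATOM/HETATM records only), via gemmi."""
    import gemmi

    st = gemmi.read_structure(str(path))
    atoms = []
    i = 0
    for chain in st[0]:
        for residue in chain:
            for atom in residue:
                i += 1
                el = atom.element.name.capitalize()
                atoms.append(
                    Atom(
                        index=i,
                        element=el,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        label=atom.name,
                    )
                )
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return Molecule(name=st.name or str(path), atoms=tuple(atoms))


_DIPOLE_COLS = ["mux", "muy", "muz"]
_QUAD_COLS = ["qxx", "qxy", "qxz", "qyy", "qyz", "qzz"]


def read_multipole_table(path, mol: Molecule) -> AtomicMultipoleSet:
    """Read a per-atom multipole CSV matching *mol*'s atom order.

    Required column ``q`` (e); optional ``mux,muy,muz`` (e·bohr) and
    ``qxx,qxy,qxz,qyy,qyz,qzz`` (e·bohr²).  The expansion order is
    inferred from the columns present.  Quadrupoles are detraced on load;
    a warning is emitted when the input trace exceeds 1e-8.
    """
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    if "q" not in df.columns:
        raise FormatError(f"{path}: required column 'q' missing")
    if len(df) != len(mol):
        raise FormatError(
            f"{path}: table has {len(df)} rows but molecule "
            f"{mol.name!r} has {len(mol)} atoms"
        )
    have_mu = all(c in df.columns for c in _DIPOLE_COLS)
    have_quad = all(c in df.columns for c in _QUAD_COLS)
    order = 2 if have_quad else (1 if have_mu else 0)

    def _numeric(cols: list[str]) -> np.ndarray:
        sub = df[cols].apply(pd.to_numeric, errors="coerce")
        bad = sub.isna().any(axis=1)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(f"{path}: non-numeric cell in data row {row}")
        return sub.to_numpy(dtype=float)

    q = _numeric(["q"]).reshape(-1)
    mu = _numeric(_DIPOLE_COLS) if have_mu else None
    theta = None
    if have_quad:
        c = _numeric(_QUAD_COLS)
        theta = np.empty((len(df), 3, 3))
        theta[:, 0, 0] = c[:, 0]
        theta[:, 0, 1] = theta[:, 1, 0] = c[:, 1]
        theta[:, 0, 2] = theta[:, 2, 0] = c[:, 2]
        theta[:, 1, 1] = c[:, 3]
        theta[:, 1, 2] = theta[:, 2, 1] = c[:, 4]
        theta[:, 2, 2] = c[:, 5]
        tr = np.trace(theta, axis1=-2, axis2=-1)
        if np.any(np.abs(tr) > 1e-8):
            warnings.warn(
                f"{path}: quadrupole trace up to {np.abs(tr).max():.3g} e·bohr² "
                "detraced on load (traceless Buckingham convention)",
                stacklevel=2,
            )
        theta = _detrace(theta)
    return AtomicMultipoleSet(order=order, q=q, mu=mu, theta=theta)


def write_multipole_table(mps: AtomicMultipoleSet, path) -> None:
    """Write the CSV dialect read by :func:`read_multipole_table`."""
    data: dict[str, np.ndarray] = {"q": mps.q}
    if mps.order >= 1:
        for k, c in enumerate(_DIPOLE_COLS):
            data[c] = mps.mu[:, k]
    if mps.order >= 2:
        th = mps.theta
        for c, (i, j) in zip(_QUAD_COLS, [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]):
            data[c] = th[:, i, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12e")


@dataclass(frozen=True)
class GridSpec:
    """A regular Cartesian grid: origin (Å), shape (nx,ny,nz), spacing (Å)."""

    origin: np.ndarray
    shape: tuple[int, int, int]
    spacing: np.ndarray  # (3,) step along x, y, z in Å

    def points(self) -> np.ndarray:
        """Grid points in cube-file order (x slowest, z fastest), Å."""
        origin = np.asarray(self.origin, float).reshape(3)
        spacing = np.asarray(self.spacing, float).reshape(3)
        nx, ny, nz = self.shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return origin + idx * spacing


def write_field_outputs(values, stem, cube_grid: GridSpec | None = None) -> None:
    """Write catalytic-field values to disk.

    Always writes ``<stem>.csv`` with columns
    ``site_label,x,y,z,V_S,V_TS,delta_s`` (6 decimals).  If any probe is
    surface-kind, also writes ``<stem>.pdb`` with one HETATM pseudo-atom
    (element X) per probe carrying Δs in the B-factor column, clamped to
    ±999.99.  If *cube_grid* is given and the probes lie exactly on it in
    grid order, also writes ``<stem>.cube`` (Gaussian cube, positions in
    bohr, values in kcal mol⁻¹ e⁻¹).
    """
    from .constants import ANGSTROM_TO_BOHR

    values = list(values)
    if not values:
        raise UsageError("write_field_outputs: empty value list")
    stem = str(stem)

    rows = []
    for v in values:
        p = v.probe
        label = p.site_index if p.site_index is not None else ""
        rows.append(
            {
                "site_label": label,
                "x": p.position[0],
                "y": p.position[1],
                "z": p.position[2],
                "V_S": v.V_S,
                "V_TS": v.V_TS,
                "delta_s": v.delta_s,
            }
        )
    pd.DataFrame(rows).to_csv(stem + ".csv", index=False, float_format="%.6f")

    if any(v.probe.kind == "surface" for v in values):
        with open(stem + ".pdb", "w") as fh:
            for i, v in enumerate(values, start=1):
                b = v.delta_s
                if abs(b) > PDB_BFACTOR_CLAMP:
                    warnings.warn(
                        f"probe {i}: Δs {b:.2f} exceeds the PDB B-factor field; "
                        f"clamped to ±{PDB_BFACTOR_CLAMP}",
                        stacklevel=2,
                    )
                    b = PDB_BFACTOR_CLAMP if b > 0 else -PDB_BFACTOR_CLAMP
                x, y, z = v.probe.position
                fh.write(
                    f"HETATM{i % 100000:5d}  X   PRB A{i % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
                    f"          {'X':>2s}\n"
                )
            fh.write("END\n")

    if cube_grid is not None:
        pts = cube_grid.points()
        got = np.array([v.probe.position for v in values])
        if got.shape != pts.shape or not np.allclose(got, pts, atol=1e-8):
            raise UsageError(
                "cube output requested but the values do not lie on the "
                "declared regular grid in grid order"
            )
        origin_b = np.asarray(cube_grid.origin, float) * ANGSTROM_TO_BOHR
        step_b = np.asarray(cube_grid.spacing, float) * ANGSTROM_TO_BOHR
        nx, ny, nz = cube_grid.shape
        vals = np.array([v.delta_s for v in values]).reshape(nx, ny, nz)
        with open(stem + ".cube", "w") as fh:
            fh.write("catfield static catalytic field map\n")
            fh.write("delta_s values in kcal mol^-1 e^-1; grid in bohr\n")
            fh.write(f"{1:5d}{origin_b[0]:12.6f}{origin_b[1]:12.6f}{origin_b[2]:12.6f}\n")
            fh.write(f"{nx:5d}{step_b[0]:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
            fh.write(f"{ny:5d}{0.0:12.6f}{step_b[1]:12.6f}{0.0:12.6f}\n")
            fh.write(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{step_b[2]:12.6f}\n")
            fh.write(f"{1:5d}{0.0:12.6f}{origin_b[0]:12.6f}{origin_b[1]:12.6f}{origin_b[2]:12.6f}\n")
            flat = vals.reshape(nx * ny, nz)
            for row in flat:
                for k in range(0, nz, 6):
                    fh.write("".join(f"{v:13.5e}" for v in row[k : k + 6]) + "\n")
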