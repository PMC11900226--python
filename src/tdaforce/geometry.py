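"""Molecular geometries and XYZ input/output.

All internal coordinates are in Bohr.  The geometry is the carrier of the
external parameter with respect to which excited-state energies are
differentiated: displacing one Cartesian coordinate of one atom defines the
one-dimensional path along which finite differences are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BOHR_PER_ANGSTROM = 1.8897259886

AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


class GeometryError(ValueError):
    """Raised for invalid or degenerate geometries."""


@dataclass(frozen=True)
class Geometry:
    """Atom labels plus Cartesian positions in Bohr.

    Parameters
    ----------
    labels:
        One text tag per atom (element symbols by convention, but any tag
        is accepted; the model Hamiltonian only looks at distances).
    positions:
        ``(n_atoms, 3)`` array of Cartesian coordinates, Bohr.
    units_tag:
        Declared length unit of the stored coordinates; always ``"bohr"``
        after construction (conversion happens at the I/O boundary).
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    units_tag: str = "bohr"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError(f"positions must be (n, 3), got {pos.shape}")
        if pos.shape[0] < 1:
            raise GeometryError("geometry needs at least one atom")
        if len(self.labels) != pos.shape[0]:
            raise GeometryError("labels and positions disagree in length")
        if not np.all(np.isfinite(pos)):
            raise GeometryError("non-finite coordinates")
        if self.units_tag != "bohr":
            raise GeometryError("internal geometries must be in Bohr")
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.n_atoms > 1:
            d = self.distance_matrix()
            iu = np.triu_indices(self.n_atoms, k=1)
            if np.min(d[iu]) <= 1e-8:
                raise GeometryError("coincident atoms (zero interatomic distance)")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def distance_matrix(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def displace(self, atom: int, axis: int | str, amount: float) -> "Geometry":
        """Return a copy with one Cartesian coordinate shifted by `amount` Bohr."""
        ax = AXES[axis]
        if not 0 <= atom < self.n_atoms:
            raise IndexError(f"atom index {atom} out of range")
        pos = self.positions.copy()
        pos[atom, ax] += amount
        return replace(self, positions=pos)


def displace(geometry: Geometry, atom: int, axis: int | str, amount: float) -> Geometry:
    """Functional form of :meth:`Geometry.displace`."""
    return geometry.displace(atom, axis, amount)


def read_xyz(path, angstrom: bool = False) -> Geometry:
    """Read a standard XYZ file (count line, comment line, `label x y z` rows).

    Coordinates are interpreted as Bohr unless ``angstrom=True``.
    """
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines()]
    if not lines:
        raise GeometryError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryError(f"{path}: malformed count line {lines[0]!r}") from exc
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise GeometryError(f"{path}: expected {n} atom lines, found {len(body)}")
    labels, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"{path}: malformed atom line {ln!r}")
        labels.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    pos = np.asarray(coords, dtype=float)
    if angstrom:
        pos = pos * BOHR_PER_ANGSTROM
    return Geometry(labels=tuple(labels), positions=pos)


def write_xyz(path, geometry: Geometry, comment: str = "", angstrom: bool = False) -> None:
    pos = geometry.positions
    if angstrom:
        pos = pos / BOHR_PER_ANGSTROM
    unit = "angstrom" if angstrom else "bohr"
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms}\n")
        fh.write(f"{comment or f'units={unit}'}\n")
        for lab, (x, y, z) in zip(geometry.labels, pos):
            fh.write(f"{lab} {x:.12e} {y:.12e} {z:.12e}\n")
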