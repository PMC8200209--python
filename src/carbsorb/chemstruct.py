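"""Molecular-geometry data model, XYZ/PDB I/O and connectivity utilities.

All coordinates are Cartesian ångström throughout the package; there is no
internal unit switching.  Atom ordering is authoritative: no operation in
this module reorders atoms silently.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "MoleculeGeometry",
    "SurfaceSlab",
    "ATOMIC_NUMBERS",
    "ATOMIC_MASSES",
    "COVALENT_RADII",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "write_pdb",
    "infer_bonds",
    "electron_parity",
    "center_of_mass",
]

# Small element tables sufficient for C/H/O (+ a few common extras).
# Masses: IUPAC 2021 standard atomic weights.  Covalent radii: Cordero 2008.
ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}


class UnknownElementError(KeyError):
    """Raised when an element symbol is outside the supported table."""


def _check_element(element: str) -> str:
    symbol = element.capitalize()
    if symbol not in ATOMIC_NUMBERS:
        raise UnknownElementError(f"unsupported element symbol: {element!r}")
    return symbol


@dataclass
class AtomRecord:
    """A single atom: element symbol, Cartesian position (Å) and optional
    partial charge (e) / van-der-Waals class label."""

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    vdw_class: str | None = None

    def __post_init__(self) -> None:
        self.element = _check_element(self.element)
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


@dataclass
class MoleculeGeometry:
    """An ordered collection of atoms with optional explicit bonds.

    The universal structure carrier: adsorbates, PAH flakes, amorphous
    slabs and carved clusters are all ``MoleculeGeometry`` instances.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    net_charge: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    # -- convenience views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.position for a in self.atoms])

    def formula(self) -> str:
        """Hill-order molecular formula, e.g. ``C8H16O``."""
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        parts = []
        for el in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
            if el in counts:
                parts.append(el + (str(counts[el]) if counts[el] > 1 else ""))
        return "".join(parts)

    def translated(self, shift: Sequence[float]) -> "MoleculeGeometry":
        shift = np.asarray(shift, dtype=float)
        atoms = [
            AtomRecord(a.element, a.position + shift, a.partial_charge, a.vdw_class)
            for a in self.atoms
        ]
        return MoleculeGeometry(atoms, list(self.bonds), self.net_charge, self.name)

    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "MoleculeGeometry":
        """Apply ``x -> R x + t`` to every atom."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        pos = self.positions @ rotation.T + translation
        atoms = [
            AtomRecord(a.element, p, a.partial_charge, a.vdw_class)
            for a, p in zip(self.atoms, pos)
        ]
        return MoleculeGeometry(atoms, list(self.bonds), self.net_charge, self.name)


@dataclass
class SurfaceSlab:
    """A surface: geometry plus in-plane periodic cell and outward normal.

    ``cell_a``/``cell_b`` are the in-plane lattice vectors (Å); the vacuum
    (outward-normal) axis is z by construction everywhere in this package.
    """

    geometry: MoleculeGeometry
    cell_a: np.ndarray
    cell_b: np.ndarray
    vacuum_axis: int = 2
    periodic: bool = True

    def __post_init__(self) -> None:
        self.cell_a = np.asarray(self.cell_a, dtype=float).reshape(3)
        self.cell_b = np.asarray(self.cell_b, dtype=float).reshape(3)
        if np.linalg.norm(self.cell_a) == 0 or np.linalg.norm(self.cell_b) == 0:
            raise ValueError("cell vectors must be nonzero")
        cross = np.cross(self.cell_a, self.cell_b)
        if np.linalg.norm(cross) < 1e-9:
            raise ValueError("cell vectors must not be parallel")

    @property
    def top_z(self) -> float:
        return float(self.geometry.positions[:, 2].max())


# ---------------------------------------------------------------------------
# XYZ I/O (plain xyz: count line, comment line, then "El x y z" records)
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> MoleculeGeometry:
    """Read a plain XYZ file.

    Raises ``ValueError`` when the declared atom count disagrees with the
    body, and ``UnknownElementError`` for unsupported symbols.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed atom count line {lines[0]!r}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise ValueError(
            f"{path}: header declares {count} atoms but body has {len(body)}"
        )
    atoms = []
    for ln in body:
        fields = ln.split()
        if len(fields) < 4:
            raise ValueError(f"{path}: malformed atom record {ln!r}")
        atoms.append(AtomRecord(fields[0], [float(x) for x in fields[1:4]]))
    return MoleculeGeometry(atoms, name=comment.strip())


def write_xyz(geometry: MoleculeGeometry, path: str | Path) -> None:
    """Write ``geometry`` as plain XYZ with 6-decimal coordinates."""
    buf = io.StringIO()
    buf.write(f"{geometry.n_atoms}\n")
    buf.write(f"{geometry.name}\n")
    for a in geometry.atoms:
        x, y, z = a.position
        buf.write(f"{a.element:<2s} {x:16.6f} {y:16.6f} {z:16.6f}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# PDB I/O via biotite (fixed-column ATOM/HETATM; CRYST1 for periodic slabs)
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> MoleculeGeometry:
    """Read ATOM/HETATM records of a PDB file into a ``MoleculeGeometry``.

    The element column (77–78) is used when populated, falling back to the
    atom-name column.  Raises ``ValueError`` on a file with no atoms.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        array = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises on empty models
        raise ValueError(f"{path}: no parsable ATOM/HETATM records") from exc
    if array.array_length() == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    atoms = []
    for el, name, pos in zip(array.element, array.atom_name, array.coord):
        symbol = el.strip().capitalize() if el.strip() else name.strip()[0]
        atoms.append(AtomRecord(symbol, pos))
    return MoleculeGeometry(atoms, name=Path(path).stem)


def write_pdb(
    geometry: MoleculeGeometry,
    path: str | Path,
    cell: tuple[float, float, float] | None = None,
) -> None:
    """Write HETATM records (occupancy 1.00, B-factor 0.00) via biotite.

    ``cell`` — optional orthorhombic (a, b, c) in Å, emitted as CRYST1 for
    periodic slabs.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = geometry.n_atoms
    array = struc.AtomArray(n)
    array.coord = geometry.positions.astype(np.float32)
    array.element = np.array(geometry.elements, dtype="U2")
    counts: dict[str, int] = {}
    names = []
    for el in geometry.elements:
        counts[el] = counts.get(el, 0) + 1
        names.append(f"{el}{counts[el]}"[:4])
    array.atom_name = np.array(names, dtype="U6")
    array.res_name = np.array(["MOL"] * n, dtype="U5")
    array.res_id = np.ones(n, dtype=int)
    array.chain_id = np.array(["A"] * n, dtype="U4")
    array.hetero = np.ones(n, dtype=bool)
    array.set_annotation("occupancy", np.ones(n))
    array.set_annotation("b_factor", np.zeros(n))
    if cell is not None:
        array.box = np.diag(cell).astype(np.float32)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Connectivity / bookkeeping
# ---------------------------------------------------------------------------

def infer_bonds(
    geometry: MoleculeGeometry, tolerance_factor: float = 1.15
) -> list[tuple[int, int]]:
    """Distance-based bond perception.

    Pair (i, j) is bonded iff ``d_ij <= tolerance_factor * (r_i + r_j)``
    with covalent radii from the bundled Cordero table.  Returns sorted
    index pairs (i < j).  Empty geometry yields an empty list.
    """
    if not 1.0 < tolerance_factor <= 1.5:
        raise ValueError("tolerance_factor must be in (1.0, 1.5]")
    n = geometry.n_atoms
    if n < 2:
        return []
    from scipy.spatial import cKDTree

    pos = geometry.positions
    radii = np.array([COVALENT_RADII[e] for e in geometry.elements])
    max_cut = tolerance_factor * 2 * radii.max()
    tree = cKDTree(pos)
    bonds = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        cutoff = tolerance_factor * (radii[i] + radii[j])
        if np.linalg.norm(pos[i] - pos[j]) <= cutoff:
            bonds.append((i, j))
    return bonds


def electron_parity(geometry: MoleculeGeometry) -> str:
    """Parity ("even"|"odd") of the total electron count.

    Electron count = sum of atomic numbers minus net charge.  An odd count
    implies a non-singlet (radical) species; downstream cluster carving
    discards such structures.
    """
    total = sum(ATOMIC_NUMBERS[a.element] for a in geometry.atoms)
    return "even" if (total - geometry.net_charge) % 2 == 0 else "odd"


def center_of_mass(geometry: MoleculeGeometry) -> np.ndarray:
    """Mass-weighted mean position (Å) using standard atomic masses."""
    if geometry.n_atoms == 0:
        raise ValueError("center of mass of empty geometry")
    masses = np.array([ATOMIC_MASSES[e] for e in geometry.elements])
    return masses @ geometry.positions / masses.sum()


def neighbor_counts(
    geometry: MoleculeGeometry, bonds: Iterable[tuple[int, int]]
) -> np.ndarray:
    """Coordination number per atom given a bond list."""
    counts = np.zeros(geometry.n_atoms, dtype=int)
    for i, j in bonds:
        counts[i] += 1
        counts[j] += 1
    return counts
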