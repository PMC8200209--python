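"""Synthetic carbon surfaces and MCHM conformers.

Generators for the three structure families the physisorption analysis
needs: planar fused-ring PAH flakes (an idealised graphene-like surface),
hydrogen-capped amorphous carbon slabs (a procedural surrogate for
activated-carbon filter media), and chair conformers of cis-/trans-
4-methylcyclohexane methanol (MCHM, C8H16O).

Every generator is a pure function of its arguments, seed included:
repeated calls yield bitwise-identical geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chemstruct import (
    ATOMIC_MASSES,
    AtomRecord,
    MoleculeGeometry,
    SurfaceSlab,
    infer_bonds,
    neighbor_counts,
)

__all__ = [
    "SlabSpec",
    "ConformerSet",
    "build_pah_flake",
    "build_mchm",
    "classify_mchm_isomer",
    "enumerate_mchm_conformers",
    "build_amorphous_slab",
]

CC_AROMATIC = 1.42  # Å, graphene / PAH
CC_SINGLE = 1.54  # Å, sp3 C-C
CH_BOND = 1.09  # Å
CO_BOND = 1.43  # Å
OH_BOND = 0.96  # Å
TET_ANGLE = math.degrees(math.acos(-1.0 / 3.0))  # 109.471°

AMU_TO_G = 1.66053907e-24
GRAPHITE_SPACING = 3.35  # Å, interlayer


@dataclass(frozen=True)
class SlabSpec:
    """Target geometry of a synthetic amorphous carbon slab.

    lx, ly, lz — box extents in nm; target_density in g cm⁻³ (must lie in
    (1.0, 3.6), i.e. between porous carbons and diamond); sp3_bias — the
    fraction of carbon sites displaced out of their graphitic layer to mimic
    sp3 cross-linking / surface roughness; seed — RNG seed (reproducible).
    """

    lx: float = 5.0
    ly: float = 5.0
    lz: float = 3.0
    target_density: float = 2.0
    sp3_bias: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError("slab extents must be positive")
        if not 1.0 < self.target_density < 3.6:
            raise ValueError(
                f"target density {self.target_density} g/cc unattainable "
                "(must lie strictly between 1.0 and diamond's 3.6)"
            )
        if not 0.0 <= self.sp3_bias <= 1.0:
            raise ValueError("sp3_bias must be in [0, 1]")


@dataclass
class ConformerSet:
    """Rotamer ensemble of one MCHM isomer, sorted by surrogate strain.

    ``strain_energies`` are kcal/mol relative to the set minimum (which is
    exactly 0); all members share the C8H16O formula.
    """

    isomer: str
    geometries: list[MoleculeGeometry]
    strain_energies: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.strain_energies = np.asarray(self.strain_energies, dtype=float)
        if len(self.geometries) != len(self.strain_energies):
            raise ValueError("geometries and strain energies must align")
        if len(self.geometries):
            if self.strain_energies.min() != 0.0:
                raise ValueError("minimum strain must be exactly 0")
            for g in self.geometries:
                if g.formula() != "C8H16O":
                    raise ValueError(f"conformer formula {g.formula()} != C8H16O")

    def __len__(self) -> int:
        return len(self.geometries)


# ---------------------------------------------------------------------------
# Planar PAH flakes
# ---------------------------------------------------------------------------

def build_pah_flake(rows: int = 3, cols: int = 4) -> MoleculeGeometry:
    """Planar peri-fused hexagonal carbon flake with perimeter H at 1.09 Å.

    ``rows`` rows of fused hexagons; the central row holds ``cols`` rings and
    each row further out holds one fewer.  (1, 1) is benzene; the default
    (3, 4) is the ovalene-like C32 flake used as the idealised planar
    surface.  All atoms lie at z = 0; C–C = 1.42 Å.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    a = CC_AROMATIC
    dx = math.sqrt(3.0) * a  # center spacing within a row
    dy = 1.5 * a  # row spacing
    centers = []
    mid = (rows - 1) / 2.0
    for j in range(rows):
        k = abs(j - mid)
        n_row = cols - math.ceil(k)
        if n_row < 1:
            continue
        # snap the row onto the honeycomb center sublattice for its parity
        # (adjacent rows must be offset by dx/2 to share edges correctly)
        parity_shift = (j % 2) * dx / 2.0
        m = round((-(n_row - 1) / 2.0 * dx - parity_shift) / dx)
        for i in range(n_row):
            centers.append(((m + i) * dx + parity_shift, (j - mid) * dy))
    # hexagon vertices (pointy-top), deduplicated on a fine grid
    seen: dict[tuple[int, int], int] = {}
    carbons: list[np.ndarray] = []
    for cx, cy in centers:
        for k in range(6):
            ang = math.radians(30.0 + 60.0 * k)
            x, y = cx + a * math.cos(ang), cy + a * math.sin(ang)
            key = (round(x * 1000), round(y * 1000))
            if key not in seen:
                seen[key] = len(carbons)
                carbons.append(np.array([x, y, 0.0]))
    pos = np.vstack(carbons)
    tree = cKDTree(pos)
    pairs = sorted(tree.query_pairs(a * 1.1))
    counts = np.zeros(len(pos), dtype=int)
    for i, j in pairs:
        counts[i] += 1
        counts[j] += 1
    atoms = [AtomRecord("C", p) for p in pos]
    centroid = pos.mean(axis=0)
    for i, c in enumerate(counts):
        if c == 2:  # perimeter carbon -> one in-plane H pointing outward
            neigh = [j for (p, q) in pairs for j in (p, q) if (p == i or q == i) and j != i]
            direction = pos[i] - 0.5 * (pos[neigh[0]] + pos[neigh[1]])
            if np.linalg.norm(direction) < 1e-9:
                direction = pos[i] - centroid
            direction = direction / np.linalg.norm(direction)
            atoms.append(AtomRecord("H", pos[i] + CH_BOND * direction))
    geom = MoleculeGeometry(atoms, name=f"pah_flake_{rows}x{cols}")
    geom.bonds = infer_bonds(geom)
    return geom


# ---------------------------------------------------------------------------
# MCHM construction
# ---------------------------------------------------------------------------

def _nerf_place(a, b, c, r, theta_deg, phi_deg):
    """Place atom D at distance r from C, angle B-C-D = theta, dihedral
    A-B-C-D = phi (natural-extension reference frame)."""
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    theta, phi = math.radians(theta_deg), math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(phi), r * math.sin(theta) * math.sin(phi)]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d2


def _tetra_completions(center, n1, n2):
    """The two remaining tetrahedral bond directions at ``center`` given
    bonded neighbours ``n1``, ``n2`` (unit vectors returned)."""
    u1 = (np.asarray(n1) - center) / np.linalg.norm(np.asarray(n1) - center)
    u2 = (np.asarray(n2) - center) / np.linalg.norm(np.asarray(n2) - center)
    p = -(u1 + u2)
    p /= np.linalg.norm(p)
    m = np.cross(u1, u2)
    m /= np.linalg.norm(m)
    cos_t = -1.0 / 3.0
    phi = math.acos(max(-1.0, min(1.0, cos_t / np.dot(p, u1))))
    return (
        math.cos(phi) * p + math.sin(phi) * m,
        math.cos(phi) * p - math.sin(phi) * m,
    )


def build_mchm(
    isomer: str,
    ring_pucker: str = "chair",
    rotamer_angles: tuple[float, float, float] = (180.0, 180.0, 60.0),
) -> MoleculeGeometry:
    """Ideal-geometry chair MCHM (4-methylcyclohexane methanol, C8H16O).

    The hydroxymethyl (CH2OH) group sits at C1 and the methyl at C4.  trans
    puts both substituents equatorial (the low-strain arrangement); cis puts
    the methyl axial.  ``rotamer_angles`` are the C2–C1–C7–O, C1–C7–O–H and
    methyl torsions in degrees.

    Atom order: ring C1–C6 (0–5), C7 (6), O (7), H(O) (8), 2×H(C7) (9–10),
    C8 methyl (11), 3×H(C8) (12–14), H(C1) (15), H(C4) (16), ring H (17–24).
    """
    if isomer not in ("cis", "trans"):
        raise ValueError(f"isomer must be 'cis' or 'trans', got {isomer!r}")
    if ring_pucker != "chair":
        raise ValueError(f"unsupported ring pucker {ring_pucker!r}")
    tor1, tor2, tor3 = rotamer_angles

    z0 = 0.25
    rho = math.sqrt(CC_SINGLE**2 - 4 * z0**2)
    ring = np.array(
        [
            [rho * math.cos(math.radians(60 * k)), rho * math.sin(math.radians(60 * k)), z0 * (-1) ** k]
            for k in range(6)
        ]
    )

    def ring_dirs(k):
        ax, eq = _tetra_completions(ring[k], ring[(k - 1) % 6], ring[(k + 1) % 6])
        # axial = direction with the larger |z| component
        if abs(ax[2]) < abs(eq[2]):
            ax, eq = eq, ax
        return ax, eq

    ax1, eq1 = ring_dirs(0)  # C1, up-puckered (z=+z0)
    ax4, eq4 = ring_dirs(3)  # C4, down-puckered

    d_ch2oh = eq1  # hydroxymethyl equatorial in both isomers (default)
    d_methyl = eq4 if isomer == "trans" else ax4

    c7 = ring[0] + CC_SINGLE * d_ch2oh
    o = _nerf_place(ring[1], ring[0], c7, CO_BOND, TET_ANGLE, tor1)
    h_o = _nerf_place(ring[0], c7, o, OH_BOND, 108.5, tor2)
    h7a_dir, h7b_dir = _tetra_completions(c7, ring[0], o)
    h7a, h7b = c7 + CH_BOND * h7a_dir, c7 + CH_BOND * h7b_dir

    c8 = ring[3] + CC_SINGLE * d_methyl
    h8 = [
        _nerf_place(ring[2], ring[3], c8, CH_BOND, TET_ANGLE, tor3 + 120.0 * i)
        for i in range(3)
    ]

    h1 = ring[0] + CH_BOND * (ax1 if d_ch2oh is eq1 else eq1)
    h4 = ring[3] + CH_BOND * (ax4 if isomer == "trans" else eq4)

    atoms = [AtomRecord("C", p) for p in ring]
    atoms.append(AtomRecord("C", c7))
    atoms.append(AtomRecord("O", o))
    atoms.append(AtomRecord("H", h_o))
    atoms.append(AtomRecord("H", h7a))
    atoms.append(AtomRecord("H", h7b))
    atoms.append(AtomRecord("C", c8))
    for p in h8:
        atoms.append(AtomRecord("H", p))
    atoms.append(AtomRecord("H", h1))
    atoms.append(AtomRecord("H", h4))
    for k in (1, 2, 4, 5):
        da, db = ring_dirs(k)
        atoms.append(AtomRecord("H", ring[k] + CH_BOND * da))
        atoms.append(AtomRecord("H", ring[k] + CH_BOND * db))

    geom = MoleculeGeometry(atoms, name=f"{isomer}-mchm")
    geom.bonds = infer_bonds(geom)
    return geom


def classify_mchm_isomer(geometry: MoleculeGeometry) -> str:
    """cis/trans assignment for a 1,4-disubstituted cyclohexane.

    Finds the six-carbon ring, fits its mean plane, and compares the side of
    each substituent's first carbon relative to that plane: same side → cis,
    opposite sides → trans.  Robust to ring puckering and to mirror images
    (cis/trans is achirality-invariant).
    """
    bonds = geometry.bonds or infer_bonds(geometry)
    elements = geometry.elements
    adj: dict[int, list[int]] = {i: [] for i in range(geometry.n_atoms)}
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)

    ring = _find_carbon_sixring(elements, adj)
    if ring is None:
        raise ValueError("no six-membered carbon ring found")
    ring_set = set(ring)
    attachments = []
    for r in ring:
        for nb in adj[r]:
            if nb not in ring_set and elements[nb] == "C":
                attachments.append((r, nb))
    if len(attachments) != 2:
        raise ValueError(
            f"expected exactly 2 ring substituents, found {len(attachments)}"
        )
    pos = geometry.positions
    ring_pos = pos[list(ring)]
    centroid = ring_pos.mean(axis=0)
    # mean-plane normal = singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(ring_pos - centroid)
    normal = vt[2]
    sides = [float(np.dot(pos[sub] - centroid, normal)) for _, sub in attachments]
    return "cis" if sides[0] * sides[1] > 0 else "trans"


def _find_carbon_sixring(elements, adj):
    """Depth-first search for a 6-cycle of carbon atoms."""
    carbons = [i for i, e in enumerate(elements) if e == "C"]
    for start in carbons:
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            if len(path) == 6:
                if start in adj[node]:
                    return path
                continue
            for nb in adj[node]:
                if elements[nb] == "C" and nb not in path:
                    stack.append((nb, path + [nb]))
    return None


# ---------------------------------------------------------------------------
# Conformer enumeration
# ---------------------------------------------------------------------------

# UFF-style nonbonded parameters used only by the intramolecular surrogate
_NB_EPS = {"C": 0.105, "H": 0.044, "O": 0.060}  # kcal/mol
_NB_SIGMA = {"C": 3.431, "H": 2.571, "O": 3.118}  # Å


def _intramolecular_strain(geom: MoleculeGeometry) -> float:
    """Surrogate strain: Lennard-Jones over atom pairs separated by more
    than three bonds, plus a 3-fold torsional cosine on the two backbone
    rotors.  Arbitrary-offset — only differences are meaningful."""
    bonds = geom.bonds or infer_bonds(geom)
    n = geom.n_atoms
    # graph distances up to 3 via BFS
    adj = {i: set() for i in range(n)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    near = [set([i]) for i in range(n)]
    for i in range(n):
        frontier = {i}
        for _ in range(3):
            frontier = set().union(*(adj[k] for k in frontier)) - near[i]
            near[i] |= frontier
    pos = geom.positions
    els = geom.elements
    energy = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if j in near[i]:
                continue
            eps = math.sqrt(_NB_EPS[els[i]] * _NB_EPS[els[j]])
            sig = 0.5 * (_NB_SIGMA[els[i]] + _NB_SIGMA[els[j]])
            r = float(np.linalg.norm(pos[i] - pos[j]))
            sr6 = (sig / r) ** 6
            energy += 4.0 * eps * (sr6 * sr6 - sr6)
    return energy


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return math.degrees(math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def _heavy_rmsd(a: MoleculeGeometry, b: MoleculeGeometry) -> float:
    """Heavy-atom RMSD after optimal (Kabsch) superposition."""
    from scipy.spatial.transform import Rotation

    ia = [i for i, e in enumerate(a.elements) if e != "H"]
    pa = a.positions[ia] - a.positions[ia].mean(axis=0)
    pb = b.positions[ia] - b.positions[ia].mean(axis=0)
    rot, _ = Rotation.align_vectors(pa, pb)
    diff = pa - rot.apply(pb)
    return float(np.sqrt((diff**2).sum() / len(ia)))


def enumerate_mchm_conformers(
    isomer: str,
    dihedral_grid_step: float = 120.0,
    include_methyl: bool = False,
    duplicate_tol: float = 0.05,
) -> ConformerSet:
    """Grid enumeration of MCHM backbone rotamers with surrogate scoring.

    Scans the C1–CH2OH and O–H torsions (and optionally the methyl torsion)
    on a ``dihedral_grid_step``° grid, scores each rotamer with the
    intramolecular surrogate, removes duplicates (heavy-atom RMSD below
    ``duplicate_tol`` Å after superposition) and returns the set sorted by
    strain, minimum normalised to exactly 0.
    """
    if 360.0 % dihedral_grid_step != 0:
        raise ValueError("dihedral_grid_step must divide 360")
    angles = np.arange(0.0, 360.0, dihedral_grid_step)
    methyl_angles = angles if include_methyl else np.array([60.0])
    candidates = []
    for t1 in angles:
        for t2 in angles:
            for t3 in methyl_angles:
                g = build_mchm(isomer, rotamer_angles=(float(t1), float(t2), float(t3)))
                candidates.append(((t1, t2, t3), _intramolecular_strain(g), g))
    candidates.sort(key=lambda c: (c[1], c[0]))
    kept: list[tuple[float, MoleculeGeometry]] = []
    for _, e, g in candidates:
        if all(_heavy_rmsd(g, other) > duplicate_tol for _, other in kept):
            kept.append((e, g))
    energies = np.array([e for e, _ in kept])
    energies -= energies.min()
    energies[0] = 0.0  # exact after subtraction
    return ConformerSet(isomer, [g for _, g in kept], energies)


# ---------------------------------------------------------------------------
# Amorphous carbon slab
# ---------------------------------------------------------------------------

def build_amorphous_slab(spec: SlabSpec) -> SurfaceSlab:
    """Procedural hydrogen-capped amorphous carbon slab.

    Stand-in for thermally equilibrated tight-binding amorphous carbon:
    (1) fill the box with carbon on a perturbed layered-graphite template at
    the target density; (2) displace an ``sp3_bias`` fraction of sites out of
    their layer (cross-link roughness); (3) relax with short-range pair
    repulsion until no C–C pair is closer than 1.2 Å; (4) leave vacuum along
    z; (5) cap under-coordinated carbons with H at 1.09 Å along the mean
    missing-bond direction.  Periodic in-plane; deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.lx * 10.0, spec.ly * 10.0, spec.lz * 10.0  # nm -> Å

    # rectangular graphene cell: 4 atoms, (3a, sqrt(3) a)
    a = CC_AROMATIC
    cell_x, cell_y = 3.0 * a, math.sqrt(3.0) * a
    nx = max(1, round(lx / cell_x))
    ny = max(1, round(ly / cell_y))
    Lx, Ly = nx * cell_x, ny * cell_y

    n_target = spec.target_density * (Lx * Ly * lz * 1e-24) / (
        ATOMIC_MASSES["C"] * AMU_TO_G
    )
    per_layer = 4 * nx * ny
    n_layers = max(1, round(n_target / per_layer))
    spacing = lz / n_layers

    frac = np.array([[0.0, 0.0], [1.0 / 3.0, 0.0], [0.5, 0.5], [5.0 / 6.0, 0.5]])
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    base = np.stack([ix.ravel(), iy.ravel()], axis=1)[:, None, :] + frac[None, :, :]
    layer_xy = (base.reshape(-1, 2)) * np.array([cell_x, cell_y])

    pos = []
    for layer in range(n_layers):
        xy = layer_xy.copy()
        if layer % 2 == 1:  # AB-like stacking offset
            xy = xy + np.array([a, 0.0])
        z = np.full(len(xy), (layer + 0.5) * spacing)
        pos.append(np.column_stack([xy, z]))
    pos = np.vstack(pos)

    # thermal-like perturbation
    pos += rng.normal(scale=0.12, size=pos.shape)

    # sp3 bias: kick a fraction of sites out of plane toward a random side
    n_sp3 = int(round(spec.sp3_bias * len(pos)))
    if n_sp3:
        idx = rng.choice(len(pos), size=n_sp3, replace=False)
        pos[idx, 2] += rng.choice([-0.5, 0.5], size=n_sp3)

    pos[:, 0] %= Lx
    pos[:, 1] %= Ly

    pos = _relax_min_distance(pos, Lx, Ly, min_dist=1.2)
    pos[:, 0] %= Lx
    pos[:, 1] %= Ly

    cc_cut = 1.15 * 2 * 0.76  # same rule as infer_bonds for C-C
    pos, caps = _prune_and_cap(pos, Lx, Ly, lz, cc_cut)
    atoms = [AtomRecord("C", p) for p in pos] + [AtomRecord("H", p) for p in caps]

    geom = MoleculeGeometry(
        atoms,
        name=(
            f"amorphous_carbon_slab lx={spec.lx} ly={spec.ly} lz={spec.lz} "
            f"rho={spec.target_density} sp3={spec.sp3_bias} seed={spec.seed}"
        ),
    )
    return SurfaceSlab(geom, [Lx, 0.0, 0.0], [0.0, Ly, 0.0])


def _prune_and_cap(pos, Lx, Ly, lz, cc_cut):
    """Make the carbon network chemically sensible, then hydrogen-cap it.

    Iterates: (a) delete carbons that are isolated or >4-coordinate in the
    periodic C-C network; (b) cap every carbon with fewer than 3 C
    neighbours with one H at 1.09 Å along the mean missing-bond direction,
    rejecting cap positions that would bond to a foreign atom (alternate
    cone directions are tried for singly-coordinated carbons, which must be
    capped; if none fits the carbon is deleted and the pass repeats).
    Terminates with every C coordination in {2, 3, 4} and every H at
    exactly one bond.
    """
    ch_cut = 1.15 * (0.76 + 0.31)
    hh_cut = 1.15 * 2 * 0.31
    up = np.array([0.0, 0.0, 1.0])
    for _ in range(30):
        neighbors = _periodic_neighbor_vectors(pos, Lx, Ly, cc_cut)
        counts = np.array([len(neighbors[i]) for i in range(len(pos))])
        bad = (counts == 0) | (counts > 4)
        if bad.any():
            pos = pos[~bad]
            continue
        shifts = [
            np.array([i * Lx, j * Ly, 0.0]) for i in (-1, 0, 1) for j in (-1, 0, 1)
        ]
        c_tree = cKDTree(np.vstack([pos + s for s in shifts]))
        caps: list[np.ndarray] = []
        delete: list[int] = []
        for i in range(len(pos)):
            vecs = neighbors[i]
            if len(vecs) >= 3:
                continue
            units = [v / np.linalg.norm(v) for v in vecs]
            primary = -np.sum(units, axis=0)
            nrm = np.linalg.norm(primary)
            if nrm < 1e-6:  # collinear neighbours: cap toward nearer vacuum
                primary = up if pos[i, 2] > lz / 2 else -up
                nrm = 1.0
            candidates = [primary / nrm]
            if len(units) == 1:
                # cone of fallback directions at ~130 deg from the bond
                u1 = units[0]
                perp = np.cross(u1, up)
                if np.linalg.norm(perp) < 1e-6:
                    perp = np.cross(u1, np.array([1.0, 0.0, 0.0]))
                perp /= np.linalg.norm(perp)
                perp2 = np.cross(u1, perp)
                c130, s130 = math.cos(math.radians(130)), math.sin(math.radians(130))
                for k in range(8):
                    az = 2 * math.pi * k / 8
                    candidates.append(
                        c130 * u1 + s130 * (math.cos(az) * perp + math.sin(az) * perp2)
                    )
            placed = False
            for d in candidates:
                cand = pos[i] + CH_BOND * d
                foreign_c = any(
                    np.linalg.norm(c_tree.data[h] - pos[i]) > 1e-9
                    for h in c_tree.query_ball_point(cand, ch_cut)
                )
                near_h = any(
                    np.linalg.norm(_min_image(cand - h, Lx, Ly)) < hh_cut
                    for h in caps
                )
                if not foreign_c and not near_h:
                    caps.append(cand)
                    placed = True
                    break
            if not placed and len(units) == 1:
                delete.append(i)  # uncappable dangling carbon
        if delete:
            pos = np.delete(pos, delete, axis=0)
            continue
        return pos, caps
    raise RuntimeError("slab capping did not converge")


def _min_image(vec, Lx, Ly):
    """Wrap a displacement vector to the in-plane minimum image."""
    vec = np.array(vec, dtype=float)
    vec[0] -= Lx * round(vec[0] / Lx)
    vec[1] -= Ly * round(vec[1] / Ly)
    return vec


def _periodic_neighbor_vectors(pos, Lx, Ly, cutoff):
    """Per-atom bond vectors with minimum image in x/y."""
    shifts = [
        np.array([i * Lx, j * Ly, 0.0]) for i in (-1, 0, 1) for j in (-1, 0, 1)
    ]
    tiled = np.vstack([pos + s for s in shifts])
    tree = cKDTree(tiled)
    base_tree = cKDTree(pos)
    coo = base_tree.sparse_distance_matrix(tree, cutoff, output_type="coo_matrix")
    mask = coo.data > 1e-9
    rows, cols = coo.row[mask], coo.col[mask]
    vecs = tiled[cols] - pos[rows]
    neighbors: dict[int, list[np.ndarray]] = {i: [] for i in range(len(pos))}
    for r, v in zip(rows, vecs):
        neighbors[int(r)].append(v)
    return neighbors


def _relax_min_distance(pos, Lx, Ly, min_dist=1.2, max_sweeps=60):
    """Push apart any pair closer than ``min_dist`` (in-plane minimum
    image) until none remain; deterministic."""
    pos = pos.copy()
    for _ in range(max_sweeps):
        shifts = [
            np.array([i * Lx, j * Ly, 0.0]) for i in (-1, 0, 1) for j in (-1, 0, 1)
        ]
        tiled = np.vstack([pos + s for s in shifts])
        tree = cKDTree(tiled)
        base = cKDTree(pos)
        moved = False
        for i, hits in enumerate(base.query_ball_tree(tree, min_dist)):
            for h in hits:
                j = h % len(pos)
                vec = pos[i] - tiled[h]
                d = np.linalg.norm(vec)
                if d < 1e-9:
                    if j == i:
                        continue
                    vec, d = np.array([0.0, 0.0, 1.0]), 1.0
                if d < min_dist:
                    push = 0.5 * (min_dist - d) * vec / d
                    pos[i] += push
                    moved = True
        if not moved:
            break
    return pos
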