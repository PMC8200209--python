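"""Pairwise van-der-Waals physisorption engine.

Pose sampling above a carbon surface, rigid-body minimization of the
adsorbate against the frozen surface, conformer filtering/averaging,
cis-vs-trans binding-difference extraction and spherical cluster carving.

The interaction model is deliberately generic: an element-wise dispersion
potential (12-6 Lennard-Jones or buffered 14-7) with standard published
parameters, evaluated with a hard 12 Å cutoff and in-plane minimum image.
Electrostatics are off by default — the adsorbate:surface potential is
vdW-only — so absolute well depths are qualitative; isomer *differences*
are the quantity of interest.

Sign convention: ``E_int`` is the interaction energy (negative =
attractive); the physisorption potential ``E_phys = -E_int`` is reported
positive for bound poses, and the isomer difference is
``delta = mean_trans - mean_cis``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .chemstruct import MoleculeGeometry, AtomRecord, SurfaceSlab, center_of_mass
from .surfaces import ConformerSet, CH_BOND

__all__ = [
    "VdwParameterSet",
    "AdsorptionPose",
    "PhysisorptionResult",
    "IsomerBindingSummary",
    "CarvedCluster",
    "UFF_LJ",
    "MMFF_BUF147",
    "default_params",
    "pair_vdw_energy",
    "interaction_energy",
    "sample_poses",
    "minimize_pose",
    "filter_conformers",
    "conformer_referenced_potential",
    "isomer_binding_summary",
    "carve_cluster",
]

DEFAULT_CUTOFF = 12.0  # Å
OVERLAP_DISTANCE = 0.5  # Å — any closer pair flags the pose as overlapping


@dataclass(frozen=True)
class VdwParameterSet:
    """Element-wise dispersion parameters.

    form — "lj126" (``4 eps [(sigma/r)^12 - (sigma/r)^6]``, ``size`` is
    sigma) or "buffered147" (well minimum ``-eps`` at ``r* = size``).
    Cross parameters by ``combination`` — "lorentz_berthelot" (arithmetic
    size, geometric eps) or "geometric" (both geometric).
    """

    form: str
    eps: dict[str, float]  # kcal/mol
    size: dict[str, float]  # Å
    combination: str = "lorentz_berthelot"

    def __post_init__(self) -> None:
        if self.form not in ("lj126", "buffered147"):
            raise ValueError(f"unknown functional form {self.form!r}")
        if self.combination not in ("lorentz_berthelot", "geometric"):
            raise ValueError(f"unknown combination rule {self.combination!r}")
        for el in self.eps:
            if self.eps[el] <= 0 or self.size.get(el, 0) <= 0:
                raise ValueError(f"parameters for {el} must be positive")

    def cross(self, el_i: str, el_j: str) -> tuple[float, float]:
        """(eps_ij, size_ij) by the declared combination rule (symmetric)."""
        try:
            ei, ej = self.eps[el_i], self.eps[el_j]
            si, sj = self.size[el_i], self.size[el_j]
        except KeyError as exc:
            raise KeyError(f"element not parameterized: {exc}") from exc
        eps = math.sqrt(ei * ej)
        if self.combination == "lorentz_berthelot":
            size = 0.5 * (si + sj)
        else:
            size = math.sqrt(si * sj)
        return eps, size


# UFF nonbonded parameters (Rappé et al. 1992), sigma = x_I / 2^(1/6)
UFF_LJ = VdwParameterSet(
    form="lj126",
    eps={"C": 0.105, "H": 0.044, "O": 0.060},
    size={"C": 3.431, "H": 2.571, "O": 3.118},
)

# MMFF94-style buffered 14-7 minima (approximate r*, eps per element)
MMFF_BUF147 = VdwParameterSet(
    form="buffered147",
    eps={"C": 0.105, "H": 0.044, "O": 0.060},
    size={"C": 3.85, "H": 2.886, "O": 3.50},
)


def default_params(form: str = "lj126") -> VdwParameterSet:
    return {"lj126": UFF_LJ, "buffered147": MMFF_BUF147}[form]


@dataclass
class AdsorptionPose:
    """A rigid placement of one adsorbate conformer above a surface.

    ``orientation`` is a unit quaternion (x, y, z, w — scipy convention);
    the placed geometry is ``R(orientation) @ (x - com) + translation``
    applied to the conformer's atoms, i.e. ``translation`` is the placed
    center of mass.
    """

    conformer_index: int
    translation: np.ndarray
    orientation: np.ndarray
    adsorbate: MoleculeGeometry

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(4)
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must have unit norm")

    def place(self) -> MoleculeGeometry:
        """The adsorbate geometry in the surface frame."""
        rot = Rotation.from_quat(self.orientation)
        com = center_of_mass(self.adsorbate)
        pos = rot.apply(self.adsorbate.positions - com) + self.translation
        atoms = [
            AtomRecord(a.element, p, a.partial_charge, a.vdw_class)
            for a, p in zip(self.adsorbate.atoms, pos)
        ]
        return MoleculeGeometry(
            atoms, list(self.adsorbate.bonds), self.adsorbate.net_charge,
            self.adsorbate.name,
        )


@dataclass
class PhysisorptionResult:
    """Minimized (or evaluated) pose with its interaction energy.

    ``E_phys = -E_int`` exactly: positive values mean net attraction, the
    reporting convention used throughout.
    """

    pose: AdsorptionPose
    E_int: float
    converged: bool = False
    overlap: bool = False
    n_iterations: int = 0

    @property
    def E_phys(self) -> float:
        return -self.E_int


@dataclass
class IsomerBindingSummary:
    """Per-isomer physisorption statistics and their difference.

    ``delta = mean_trans - mean_cis`` (kcal/mol); positive when the trans
    isomer binds more strongly.
    """

    mean_cis: float
    sd_cis: float
    n_cis: int
    mean_trans: float
    sd_trans: float
    n_trans: int

    @property
    def delta(self) -> float:
        return self.mean_trans - self.mean_cis


def pair_vdw_energy(
    r: float, element_i: str, element_j: str, params: VdwParameterSet
) -> float:
    """Dispersion pair energy (kcal/mol) at separation ``r`` Å."""
    if r <= 0:
        raise ValueError("separation must be positive")
    eps, size = params.cross(element_i, element_j)
    if params.form == "lj126":
        sr6 = (size / r) ** 6
        return 4.0 * eps * (sr6 * sr6 - sr6)
    # buffered 14-7 (Halgren): minimum exactly -eps at r = r*
    rho = r / size
    return eps * (1.07 / (rho + 0.07)) ** 7 * (1.12 / (rho**7 + 0.12) - 2.0)


def _pair_energy_vec(r: np.ndarray, eps: np.ndarray, size: np.ndarray, form: str):
    if form == "lj126":
        sr6 = (size / r) ** 6
        return 4.0 * eps * (sr6 * sr6 - sr6)
    rho = r / size
    return eps * (1.07 / (rho + 0.07)) ** 7 * (1.12 / (rho**7 + 0.12) - 2.0)


def _surface_arrays(surface):
    """(positions, elements, cell_a, cell_b, periodic) for slab or bare
    geometry surfaces."""
    if isinstance(surface, SurfaceSlab):
        geom = surface.geometry
        return (
            geom.positions,
            np.array(geom.elements),
            surface.cell_a,
            surface.cell_b,
            surface.periodic,
        )
    geom = surface
    return geom.positions, np.array(geom.elements), None, None, False


def interaction_energy(
    pose,
    surface,
    cutoff: float = DEFAULT_CUTOFF,
    params: VdwParameterSet = UFF_LJ,
    details: bool = False,
):
    """Adsorbate–surface vdW energy (kcal/mol) with a hard cutoff.

    ``pose`` may be an :class:`AdsorptionPose` or an already-placed
    ``MoleculeGeometry``.  Periodic surfaces use the in-plane minimum image
    (the cutoff must not exceed half the shortest in-plane cell length).
    Intramolecular pairs are excluded by construction.  With
    ``details=True`` returns ``(energy, overlap_flag)`` where the flag marks
    any pair closer than 0.5 Å.
    """
    ads = pose.place() if isinstance(pose, AdsorptionPose) else pose
    spos, sels, cell_a, cell_b, periodic = _surface_arrays(surface)
    if periodic:
        la, lb = np.linalg.norm(cell_a), np.linalg.norm(cell_b)
        if cutoff > 0.5 * min(la, lb):
            raise ValueError(
                f"cutoff {cutoff} exceeds half the shortest cell length "
                f"{0.5 * min(la, lb):.2f}"
            )
        shifts = [i * cell_a + j * cell_b for i in (-1, 0, 1) for j in (-1, 0, 1)]
        spos = np.vstack([spos + s for s in shifts])
        sels = np.tile(sels, 9)

    apos = ads.positions
    aels = np.array(ads.elements)
    tree = cKDTree(spos)
    energy = 0.0
    overlap = False
    for i, p in enumerate(apos):
        hits = tree.query_ball_point(p, cutoff)
        if not hits:
            continue
        hits = np.asarray(hits)
        d = np.linalg.norm(spos[hits] - p, axis=1)
        if (d < OVERLAP_DISTANCE).any():
            overlap = True
            d = np.maximum(d, 1e-3)  # keep the energy finite, still huge
        eps = np.empty(len(hits))
        size = np.empty(len(hits))
        for k, j in enumerate(hits):
            eps[k], size[k] = params.cross(aels[i], sels[j])
        energy += float(_pair_energy_vec(d, eps, size, params.form).sum())
    if details:
        return energy, overlap
    return energy


def sample_poses(
    surface,
    conformers: ConformerSet,
    n_poses: int,
    patch_fraction: float = 0.6,
    height_range: tuple[float, float] = (2.5, 4.5),
    seed: int = 0,
) -> list[AdsorptionPose]:
    """Random rigid poses over the central patch of a surface.

    Lateral positions are uniform over the central ``patch_fraction`` of
    each in-plane cell vector (0.6 of a 5 nm cell is the central ~3×3 nm
    patch); orientations are uniform over rotations; the initial height is
    uniform in ``height_range`` above the highest surface atom.  The
    lowest-strain conformers (up to three) are guaranteed membership in the
    sample; the remainder are drawn uniformly.  Deterministic per seed.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    if not 0 < patch_fraction <= 1:
        raise ValueError("patch_fraction must be in (0, 1]")
    if len(conformers) == 0:
        raise ValueError("empty conformer set")
    rng = np.random.default_rng(seed)
    spos, _, cell_a, cell_b, periodic = _surface_arrays(surface)
    if periodic:
        center = 0.5 * (cell_a + cell_b)
        half_a = 0.5 * patch_fraction * cell_a
        half_b = 0.5 * patch_fraction * cell_b
    else:
        lo, hi = spos.min(axis=0), spos.max(axis=0)
        center = 0.5 * (lo + hi)
        half_a = np.array([0.5 * patch_fraction * (hi - lo)[0], 0.0, 0.0])
        half_b = np.array([0.0, 0.5 * patch_fraction * (hi - lo)[1], 0.0])
    top = spos[:, 2].max()

    n_forced = min(3, len(conformers), n_poses)
    conformer_ids = list(range(n_forced))
    if n_poses > n_forced:
        conformer_ids += list(
            rng.integers(0, len(conformers), size=n_poses - n_forced)
        )
    rotations = Rotation.random(n_poses, random_state=rng)
    u = rng.uniform(-1.0, 1.0, size=n_poses)
    v = rng.uniform(-1.0, 1.0, size=n_poses)
    heights = rng.uniform(height_range[0], height_range[1], size=n_poses)
    poses = []
    for k in range(n_poses):
        lateral = center + u[k] * half_a + v[k] * half_b
        translation = np.array([lateral[0], lateral[1], top + heights[k]])
        quat = rotations[k].as_quat()
        quat = quat / np.linalg.norm(quat)
        poses.append(
            AdsorptionPose(
                conformer_index=int(conformer_ids[k]),
                translation=translation,
                orientation=quat,
                adsorbate=conformers.geometries[conformer_ids[k]],
            )
        )
    return poses


def minimize_pose(
    pose: AdsorptionPose,
    surface,
    params: VdwParameterSet = UFF_LJ,
    cutoff: float = DEFAULT_CUTOFF,
    step_tol: float = 1e-3,
    energy_tol: float = 1e-6,
    max_iters: int = 2000,
) -> PhysisorptionResult:
    """Rigid-body local descent of a pose against the frozen surface.

    Derivative-free pattern search over the six rigid degrees of freedom
    (translation + rotation) with shrinking step sizes — robust for the
    non-smooth hard-cutoff energy surface.  Only downhill moves are
    accepted, so the energy trace is non-increasing by construction.
    ``converged`` is set when the translation step falls below ``step_tol``
    (rotation step below step_tol rad) and the last sweep improved by less
    than ``energy_tol``.
    """
    translation = pose.translation.copy()
    rot = Rotation.from_quat(pose.orientation)
    com = center_of_mass(pose.adsorbate)
    base = pose.adsorbate.positions - com
    spos, sels, cell_a, cell_b, periodic = _surface_arrays(surface)
    if periodic:
        la, lb = np.linalg.norm(cell_a), np.linalg.norm(cell_b)
        if cutoff > 0.5 * min(la, lb):
            raise ValueError("cutoff exceeds half the shortest cell length")
        shifts = [i * cell_a + j * cell_b for i in (-1, 0, 1) for j in (-1, 0, 1)]
        spos = np.vstack([spos + s for s in shifts])
        sels = np.tile(sels, 9)
    tree = cKDTree(spos)
    aels = np.array(pose.adsorbate.elements)

    # precompute cross parameters per (adsorbate atom, surface element)
    surf_kinds = sorted(set(sels))
    kind_index = {el: k for k, el in enumerate(surf_kinds)}
    sel_idx = np.array([kind_index[e] for e in sels])
    eps_tab = np.empty((len(aels), len(surf_kinds)))
    size_tab = np.empty((len(aels), len(surf_kinds)))
    for i, ea in enumerate(aels):
        for el, k in kind_index.items():
            eps_tab[i, k], size_tab[i, k] = params.cross(ea, el)

    def energy_at(t, rotation):
        pos = rotation.apply(base) + t
        total = 0.0
        for i, p in enumerate(pos):
            hits = tree.query_ball_point(p, cutoff)
            if not hits:
                continue
            hits = np.asarray(hits)
            d = np.linalg.norm(spos[hits] - p, axis=1)
            if not np.all(np.isfinite(d)):
                raise FloatingPointError("non-finite distance in minimization")
            d = np.maximum(d, 1e-3)
            k = sel_idx[hits]
            total += float(
                _pair_energy_vec(d, eps_tab[i, k], size_tab[i, k], params.form).sum()
            )
        if not np.isfinite(total):
            raise FloatingPointError("non-finite energy in minimization")
        return total

    e_cur = energy_at(translation, rot)
    t_step, r_step = 0.4, 0.15
    axes = np.eye(3)
    iters = 0
    converged = False
    while iters < max_iters:
        improved = 0.0
        for axis in axes:
            for sign in (1.0, -1.0):
                cand = translation + sign * t_step * axis
                e = energy_at(cand, rot)
                if e < e_cur:
                    improved += e_cur - e
                    translation, e_cur = cand, e
        for axis in axes:
            for sign in (1.0, -1.0):
                cand_rot = Rotation.from_rotvec(sign * r_step * axis) * rot
                e = energy_at(translation, cand_rot)
                if e < e_cur:
                    improved += e_cur - e
                    rot, e_cur = cand_rot, e
        iters += 1
        if improved == 0.0:
            if t_step < step_tol and r_step < step_tol:
                converged = True
                break
            t_step *= 0.5
            r_step *= 0.5
        elif improved < energy_tol and t_step < step_tol:
            converged = True
            break

    quat = rot.as_quat()
    quat = quat / np.linalg.norm(quat)
    out_pose = AdsorptionPose(
        conformer_index=pose.conformer_index,
        translation=translation,
        orientation=quat,
        adsorbate=pose.adsorbate,
    )
    _, overlap = interaction_energy(out_pose, surface, cutoff, params, details=True)
    return PhysisorptionResult(
        pose=out_pose, E_int=e_cur, converged=converged, overlap=overlap,
        n_iterations=iters,
    )


def filter_conformers(
    results: Sequence[PhysisorptionResult], window: float = 7.0
) -> list[PhysisorptionResult]:
    """Keep results whose interaction energy lies within ``window``
    kcal/mol of the lowest-energy member (the retention rule applied to
    adsorbate:surface complexes).  Order-independent: the retained set is a
    subsequence of the input."""
    if not results:
        raise ValueError("empty result list")
    e_min = min(r.E_int for r in results)
    return [r for r in results if r.E_int - e_min <= window]


def conformer_referenced_potential(
    complex_energy: float,
    surface_energy: float,
    conformer_energies: Sequence[float],
    n_lowest: int = 5,
) -> float:
    """Apparent physisorption potential referenced to low-lying conformers.

    ``E_phys = -(E_complex - E_surface - mean(n_lowest lowest conformer
    energies))``; when fewer than ``n_lowest`` energies are supplied, all
    are used.  Ties broken by stable sort (energy, then input index).
    """
    energies = sorted(conformer_energies)[: max(1, n_lowest)]
    if not energies:
        raise ValueError("conformer_energies must be nonempty")
    reference = float(np.mean(energies))
    return -(complex_energy - surface_energy - reference)


def isomer_binding_summary(
    cis_results: Sequence[PhysisorptionResult],
    trans_results: Sequence[PhysisorptionResult],
) -> IsomerBindingSummary:
    """Mean/SD/count of E_phys per isomer and their difference (sample SD,
    n-1 denominator; SD reported as 0 for a single result)."""
    if not cis_results or not trans_results:
        raise ValueError("both isomer result lists must be nonempty")

    def stats(rs):
        vals = np.array([r.E_phys for r in rs])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), sd, len(vals)

    mc, sc, nc = stats(cis_results)
    mt, st, nt = stats(trans_results)
    return IsomerBindingSummary(mc, sc, nc, mt, st, nt)


@dataclass
class CarvedCluster:
    """A hydrogen-capped spherical cut of a surface around an adsorption
    site.  ``cap_start`` is the index of the first capping hydrogen;
    ``discarded`` marks clusters rejected by the charge/multiplicity screen
    (odd electron count or nonzero formal charge)."""

    geometry: MoleculeGeometry
    cap_start: int
    discarded: bool
    reason: str = ""

    @property
    def n_caps(self) -> int:
        return self.geometry.n_atoms - self.cap_start

    def without_caps(self) -> MoleculeGeometry:
        return MoleculeGeometry(
            self.geometry.atoms[: self.cap_start], name=self.geometry.name
        )


def carve_cluster(
    surface,
    pose,
    radius: float = 12.0,
) -> CarvedCluster:
    """Carve the surface atoms within ``radius`` Å of the adsorbate center
    of mass; cap every broken C–C bond with H at 1.09 Å along the former
    bond vector.

    The cluster is built from the in-plane periodic images nearest the
    adsorption site, so it is contiguous in Cartesian space.  Clusters with
    odd electron count (non-singlet stand-in) or nonzero formal charge are
    flagged ``discarded`` rather than raised.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ads = pose.place() if isinstance(pose, AdsorptionPose) else pose
    com = center_of_mass(ads)
    spos, sels, cell_a, cell_b, periodic = _surface_arrays(surface)
    if periodic:
        shifts = [i * cell_a + j * cell_b for i in (-1, 0, 1) for j in (-1, 0, 1)]
        allpos = np.vstack([spos + s for s in shifts])
        allels = np.tile(sels, 9)
    else:
        allpos, allels = spos, sels

    dist = np.linalg.norm(allpos - com, axis=1)
    inside = np.where(dist <= radius)[0]
    if len(inside) == 0:
        return CarvedCluster(
            MoleculeGeometry([], name="empty_cluster"), 0, True, "no atoms in sphere"
        )
    # broken-bond capping: neighbours of inside atoms that fall outside
    cc_cut = 1.15 * 2 * 0.76
    tree = cKDTree(allpos)
    inside_set = set(int(i) for i in inside)
    atoms = [AtomRecord(allels[i], allpos[i]) for i in inside]
    caps = []
    for i in inside:
        if allels[i] != "C":
            continue
        for j in tree.query_ball_point(allpos[i], cc_cut):
            if j in inside_set or allels[j] != "C":
                continue
            d = np.linalg.norm(allpos[j] - allpos[i])
            if d < 1e-9:
                continue
            vec = (allpos[j] - allpos[i]) / d
            caps.append(AtomRecord("H", allpos[i] + CH_BOND * vec))
    cluster = MoleculeGeometry(atoms + caps, name="carved_cluster")
    from .chemstruct import electron_parity

    discarded = False
    reason = ""
    if cluster.net_charge != 0:
        discarded, reason = True, "nonzero formal charge"
    elif electron_parity(cluster) == "odd":
        discarded, reason = True, "odd electron count (non-singlet)"
    return CarvedCluster(cluster, len(atoms), discarded, reason)
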