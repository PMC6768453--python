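"""Implicit-solvent enclosed-hydration spheres and their energy term.

A hydration sphere is a water-sized sphere anchored to receptor internal
coordinates (lone-pair constructions on carbonyl/carboxylate groups, a
polar-hydrogen axis, or the geometric center of a group of atoms).  Each
sphere carries a hydration strength ``h_s`` (kcal/mol, positive for
energetically frustrated enclosed water).  Its contribution is gated by its
water occupancy factor

    w_s = V_s^free / V_s,

the fraction of the sphere volume not occluded by solute atoms, passed
through a smooth switching function S.  The enclosed-hydration solvation
term is

    dG_hs = sum_s h_s * S(w_s).

Displacing an unfavorable (h_s > 0) enclosed water by adding ligand atoms
drives its contribution to zero, which favors binding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import vdw_radius

__all__ = [
    "SoluteAtom",
    "AnchorSpec",
    "HydrationSphere",
    "OccupancyResult",
    "place_sphere",
    "free_volume",
    "switching",
    "enclosed_hydration_energy",
    "read_spheres_json",
    "write_spheres_json",
]


@dataclass(frozen=True)
class SoluteAtom:
    """A solute atom acting as an occluder of hydration-sphere volume."""

    serial: int
    element: str
    position: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"atom {self.serial}: radius must be positive")


@dataclass
class AnchorSpec:
    """How a hydration sphere is positioned from receptor internal coordinates.

    anchoring_type
        ``center_of_mass`` — geometric centroid of the listed atoms;
        ``polar_hydrogen`` — along the donor→H axis, ``distance`` Å beyond H
        (atoms: donor, H);
        ``backbone_carbonyl`` / ``sidechain_carboxylate`` — sp² lone-pair
        construction in the plane of three atoms.  For a carbonyl the atoms
        are (C, O, in-plane reference); for a carboxylate (C, O1, O2) with
        ``oxygen`` selecting which oxygen carries the site.  ``angle`` is
        the C–O–site angle in degrees, ``distance`` the O–site distance in
        Å, ``branch`` ±1 selects the mirror image across the C–O axis.
    """

    anchoring_type: str
    anchor_atom_serials: list[int]
    geometry_params: dict = field(default_factory=dict)

    _MIN_ATOMS = {
        "center_of_mass": 1,
        "polar_hydrogen": 2,
        "backbone_carbonyl": 3,
        "sidechain_carboxylate": 3,
    }

    def __post_init__(self):
        if self.anchoring_type not in self._MIN_ATOMS:
            raise ValueError(f"unknown anchoring type {self.anchoring_type!r}")
        need = self._MIN_ATOMS[self.anchoring_type]
        if len(self.anchor_atom_serials) < need:
            raise ValueError(
                f"{self.anchoring_type} anchor needs >= {need} atoms, "
                f"got {len(self.anchor_atom_serials)}"
            )


@dataclass
class HydrationSphere:
    sphere_id: int
    h_s: float
    anchor: AnchorSpec | None = None
    center: tuple[float, float, float] | None = None  # fixed center if no anchor
    radius_rs: float = 1.4
    switch_lo: float = 0.1
    switch_hi: float = 0.5

    def __post_init__(self):
        if self.radius_rs <= 0:
            raise ValueError("radius_rs must be positive")
        if not 0.0 <= self.switch_lo < self.switch_hi <= 1.0:
            raise ValueError("switch thresholds must satisfy 0 <= lo < hi <= 1")
        if self.anchor is None and self.center is None:
            raise ValueError("sphere needs an anchor or a fixed center")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_rs**3


@dataclass
class OccupancyResult:
    sphere_id: int
    v_free: float
    w_s: float
    s_of_w: float
    contribution: float


def _atom_lookup(atoms, serials) -> list[np.ndarray]:
    by_serial = {a.serial: a for a in atoms}
    out = []
    for s in serials:
        if s not in by_serial:
            raise KeyError(f"anchor atom serial {s} not found in structure")
        out.append(np.asarray(by_serial[s].position, float))
    return out


def _lone_pair(c: np.ndarray, o: np.ndarray, ref: np.ndarray,
               distance: float, angle_deg: float, branch: int) -> np.ndarray:
    u = o - c
    u /= np.linalg.norm(u)
    v = ref - c
    v = v - (v @ u) * u
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("plane reference atom is collinear with the C=O axis")
    v /= norm
    theta = math.radians(180.0 - angle_deg)
    direction = math.cos(theta) * u + branch * math.sin(theta) * v
    return o + distance * direction


def place_sphere(anchor: AnchorSpec, atoms) -> np.ndarray:
    """Resolve the 3-D position of an anchored hydration sphere (Å)."""
    p = _atom_lookup(atoms, anchor.anchor_atom_serials)
    g = anchor.geometry_params
    kind = anchor.anchoring_type
    if kind == "center_of_mass":
        return np.mean(p, axis=0)
    if kind == "polar_hydrogen":
        donor, h = p[0], p[1]
        axis = h - donor
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise ValueError("donor and hydrogen coincide")
        return h + g.get("distance", 1.0) * axis / norm
    # sp2 lone-pair constructions
    distance = g.get("distance", 2.5)
    angle = g.get("angle", 120.0)
    branch = int(g.get("branch", 1))
    if branch not in (-1, 1):
        raise ValueError("branch must be +1 or -1")
    if kind == "backbone_carbonyl":
        c, o, ref = p[0], p[1], p[2]
        return _lone_pair(c, o, ref, distance, angle, branch)
    # sidechain_carboxylate: atoms (C, O1, O2); the non-selected oxygen
    # defines the sp2 plane.
    oxygen = int(g.get("oxygen", 1))
    if oxygen not in (1, 2):
        raise ValueError("oxygen must be 1 or 2")
    c, o, ref = p[0], p[oxygen], p[2 if oxygen == 1 else 1]
    return _lone_pair(c, o, ref, distance, angle, branch)


def free_volume(
    center,
    radius_rs: float,
    occluders,
    grid_spacing: float = 0.1,
    probe_offset: float = 0.0,
) -> float:
    """Sphere volume (Å³) not occluded by solute atoms, by grid integration.

    A cell-centered cubic grid samples the sphere; the free volume is the
    exact sphere volume scaled by the unoccluded fraction of interior grid
    points, which cancels the discretisation error of the sphere boundary
    itself.  Occluder effective radius = vdW radius + ``probe_offset``.
    """
    if radius_rs <= 0:
        raise ValueError("radius_rs must be positive")
    center = np.asarray(center, float)
    v_exact = 4.0 / 3.0 * math.pi * radius_rs**3

    occ = [
        (np.asarray(a.position, float), a.radius + probe_offset)
        for a in occluders
        if np.linalg.norm(np.asarray(a.position, float) - center)
        < radius_rs + a.radius + probe_offset
    ]
    if not occ:
        return v_exact

    n = int(math.ceil(2.0 * radius_rs / grid_spacing))
    h = 2.0 * radius_rs / n
    axis = -radius_rs + (np.arange(n) + 0.5) * h
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = (pts**2).sum(axis=1) <= radius_rs**2
    pts = pts[inside] + center
    n_inside = len(pts)
    if n_inside == 0:
        return 0.0

    free = np.ones(n_inside, dtype=bool)
    for pos, r_eff in occ:
        d2 = ((pts - pos) ** 2).sum(axis=1)
        free &= d2 > r_eff**2
    return v_exact * free.sum() / n_inside


def switching(w: float, lo: float, hi: float) -> float:
    """Cubic smoothstep gate on the water occupancy factor.

    Returns 0 for w <= lo, 1 for w >= hi, and 3t²−2t³ with
    t = (w−lo)/(hi−lo) in between — continuous with continuous first
    derivative (zero slope at both thresholds).
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("switching thresholds must satisfy 0 <= lo < hi <= 1")
    if w <= lo:
        return 0.0
    if w >= hi:
        return 1.0
    t = (w - lo) / (hi - lo)
    return 3.0 * t * t - 2.0 * t * t * t


def enclosed_hydration_energy(
    spheres,
    atoms,
    grid_spacing: float = 0.1,
    probe_offset: float = 0.0,
) -> tuple[float, list[OccupancyResult]]:
    """Enclosed-hydration solvation term dG_hs = Σ_s h_s · S(w_s).

    ``atoms`` are all occluders (receptor plus any ligand atoms).  The term
    is additive over spheres; a fully open unfavorable sphere contributes
    its full h_s, and occluding it (e.g. with ligand atoms) drives the
    contribution to zero.
    """
    results: list[OccupancyResult] = []
    total = 0.0
    atoms = list(atoms)
    for sphere in spheres:
        if sphere.center is not None:
            center = np.asarray(sphere.center, float)
        else:
            center = place_sphere(sphere.anchor, atoms)
        v_free = free_volume(center, sphere.radius_rs, atoms,
                             grid_spacing=grid_spacing, probe_offset=probe_offset)
        w_s = min(v_free / sphere.volume, 1.0)
        s = switching(w_s, sphere.switch_lo, sphere.switch_hi)
        contribution = sphere.h_s * s
        total += contribution
        results.append(OccupancyResult(sphere.sphere_id, v_free, w_s, s, contribution))
    return total, results


# ---------------------------------------------------------------------------
# I/O

def write_spheres_json(spheres, path) -> None:
    payload = []
    for s in spheres:
        rec = {
            "sphere_id": s.sphere_id,
            "h_s": s.h_s,
            "radius_rs": s.radius_rs,
            "switch_lo": s.switch_lo,
            "switch_hi": s.switch_hi,
        }
        if s.anchor is not None:
            rec["anchoring_type"] = s.anchor.anchoring_type
            rec["anchor_atom_serials"] = list(s.anchor.anchor_atom_serials)
            rec["geometry_params"] = s.anchor.geometry_params
        if s.center is not None:
            rec["center"] = list(s.center)
        payload.append(rec)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_spheres_json(path) -> list[HydrationSphere]:
    with open(path) as fh:
        payload = json.load(fh)
    spheres = []
    for rec in payload:
        anchor = None
        if "anchoring_type" in rec:
            anchor = AnchorSpec(
                anchoring_type=rec["anchoring_type"],
                anchor_atom_serials=list(rec["anchor_atom_serials"]),
                geometry_params=rec.get("geometry_params", {}),
            )
        spheres.append(
            HydrationSphere(
                sphere_id=rec["sphere_id"],
                h_s=rec["h_s"],
                anchor=anchor,
                center=tuple(rec["center"]) if "center" in rec else None,
                radius_rs=rec.get("radius_rs", 1.4),
                switch_lo=rec.get("switch_lo", 0.1),
                switch_hi=rec.get("switch_hi", 0.5),
            )
        )
    return spheres
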