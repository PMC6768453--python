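"""Integration of per-structure hydration maps and sphere-weight assignment.

Receptors are flexible: a single structure under-samples the hydration
layer, so hydration maps computed for several (pre-superposed) receptor
conformations are merged into one consensus map by averaging the scores of
neighboring sites.  Merged sites are then converted into implicit-solvent
hydration-sphere weights: nearby sites are grouped onto a single sphere
carrying the sum of their scores, and the weight of a site adjacent to a
carboxylate group is distributed over the water-occupied members of the
carboxylate's sphere set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hsa import HydrationMap

__all__ = [
    "MergedSite",
    "SphereAssignment",
    "merge_maps",
    "group_nearby_sites",
    "distribute_carboxylate",
    "assignments_to_table",
    "superpose",
]

ANCHORING_TYPES = (
    "backbone_carbonyl",
    "sidechain_carboxylate",
    "polar_hydrogen",
    "center_of_mass",
)


@dataclass
class MergedSite:
    merged_id: int
    center: tuple[float, float, float]
    per_map_scores: list[tuple[str, float]]
    averaged_score: float
    contributing_maps: int


@dataclass
class SphereAssignment:
    agbnp_site_id: int
    source_hsa_ids: list[int]
    anchoring_type: str = "center_of_mass"
    h_s: float = 0.0

    def __post_init__(self):
        if self.anchoring_type not in ANCHORING_TYPES:
            raise ValueError(f"unknown anchoring type {self.anchoring_type!r}")


def merge_maps(
    maps: list[HydrationMap],
    merge_radius: float = 2.0,
    mode: str = "contributing",
) -> list[MergedSite]:
    """Merge hydration maps from superposed structures into consensus sites.

    Sites (from any map) are processed in order of decreasing score; a site
    joins the first existing merged cluster whose running mean center lies
    within ``merge_radius``, else it seeds a new cluster.  The merged center
    is the unweighted mean of contributing site centers.

    ``mode`` controls the averaged score:

    - ``"contributing"`` (default): mean over the maps that contribute to
      the cluster; a map contributing several sites contributes their sum.
    - ``"all"``: sum of contributions divided by the total number of input
      maps (a map with no site near the cluster counts as zero).
    """
    if merge_radius <= 0:
        raise ValueError("merge_radius must be positive")
    if mode not in ("contributing", "all"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    if not maps:
        return []

    radii = {m.config.site_radius for m in maps}
    if len(radii) > 1:
        warnings.warn(
            f"maps have mismatched site radii {sorted(radii)}; "
            f"using {maps[0].config.site_radius}"
        )

    entries = []  # (score, label, center)
    for m in maps:
        for s in m.sites:
            entries.append((s.score, m.structure_label, np.asarray(s.center, float)))
    entries.sort(key=lambda e: -e[0])

    clusters: list[dict] = []
    for score, label, center in entries:
        joined = False
        for cl in clusters:
            if np.linalg.norm(cl["center"] - center) <= merge_radius:
                cl["members"].append((label, score, center))
                cl["center"] = np.mean([c for _, _, c in cl["members"]], axis=0)
                joined = True
                break
        if not joined:
            clusters.append({"center": center.copy(), "members": [(label, score, center)]})

    merged: list[MergedSite] = []
    n_maps = len(maps)
    for i, cl in enumerate(clusters):
        per_map: dict[str, float] = {}
        for label, score, _ in cl["members"]:
            per_map[label] = per_map.get(label, 0.0) + score
        denom = len(per_map) if mode == "contributing" else n_maps
        merged.append(
            MergedSite(
                merged_id=i,
                center=tuple(float(v) for v in cl["center"]),
                per_map_scores=sorted(per_map.items()),
                averaged_score=sum(per_map.values()) / denom,
                contributing_maps=len(per_map),
            )
        )
    merged.sort(key=lambda s: -s.averaged_score)
    for new_id, s in enumerate(merged):
        s.merged_id = new_id
    return merged


def group_nearby_sites(
    merged: list[MergedSite],
    group_radius: float,
    anchoring_type: str = "center_of_mass",
) -> list[SphereAssignment]:
    """Group nearby merged sites onto single hydration spheres.

    Sites within ``group_radius`` of a group's seed are represented by one
    sphere whose weight h_s is the sum of the member scores, preserving the
    total energetic weight of the map.
    """
    if group_radius < 0:
        raise ValueError("group_radius must be non-negative")
    order = sorted(merged, key=lambda s: -s.averaged_score)
    groups: list[dict] = []
    for site in order:
        center = np.asarray(site.center, float)
        for g in groups:
            if np.linalg.norm(g["seed"] - center) <= group_radius:
                g["members"].append(site)
                break
        else:
            groups.append({"seed": center, "members": [site]})

    return [
        SphereAssignment(
            agbnp_site_id=i,
            source_hsa_ids=sorted(s.merged_id for s in g["members"]),
            anchoring_type=anchoring_type,
            h_s=float(sum(s.averaged_score for s in g["members"])),
        )
        for i, g in enumerate(groups)
    ]


def distribute_carboxylate(
    total_score: float, occupied_sphere_ids: list[int]
) -> list[tuple[int, float]]:
    """Distribute a site's total weight equally over occupied carboxylate spheres.

    Carboxylate groups carry a fixed set of equivalent hydration spheres;
    the excess energy of an adjacent hydration site is split equally among
    the subset with non-zero water occupancy so the total is conserved
    exactly.
    """
    ids = list(occupied_sphere_ids)
    if not ids:
        raise ValueError("at least one occupied carboxylate sphere is required")
    share = total_score / len(ids)
    out = [(int(i), share) for i in ids]
    # enforce exact conservation against float division residue
    residue = total_score - share * len(ids)
    if residue != 0.0:
        last_id, last_share = out[-1]
        out[-1] = (last_id, last_share + residue)
    return out


def assignments_to_table(
    assignments: list[SphereAssignment],
    merged: list[MergedSite] | None = None,
) -> pd.DataFrame:
    """Tabulate sphere assignments (HSA site ids, anchoring type, h_s)."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "agbnp_site_id": a.agbnp_site_id,
                "hsa_site_ids": ",".join(str(i) for i in a.source_hsa_ids),
                "anchoring_type": a.anchoring_type,
                "h_s": a.h_s,
            }
        )
    return pd.DataFrame(rows)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Rigid-body least-squares superposition (Kabsch).

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    Alignment quality is the caller's responsibility — maps must be in a
    common frame before merging.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd
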