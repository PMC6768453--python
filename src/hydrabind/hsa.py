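"""Hydration site analysis (HSA) of water trajectory observations.

Identifies spherical high-water-density sites in a binding-site region,
computes per-site occupancies and inhomogeneous-solvation energetics, and
scores each site relative to bulk water.  A site's score,

    score = (E_total - E_bulk) * p,

is the excess solvation energy of the site weighted by its water
occupancy ``p``; positive scores mark energetically frustrated sites whose
displacement by a ligand favors binding.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import E_BULK_DEFAULT

logger = logging.getLogger(__name__)

__all__ = [
    "WaterObservation",
    "WaterObservations",
    "ClusterConfig",
    "HydrationSite",
    "HydrationMap",
    "cluster_hydration_sites",
    "compute_site_thermodynamics",
    "score_site",
    "read_water_csv",
    "write_water_csv",
    "write_map_json",
    "read_map_json",
]


@dataclass(frozen=True)
class WaterObservation:
    """A single water-oxygen observation from one trajectory frame."""

    frame_index: int
    molecule_id: int
    position: tuple[float, float, float]
    e_sw: float  # solute-water interaction energy, kcal/mol
    e_ww: float  # water-water interaction energy, kcal/mol


class WaterObservations:
    """Column-oriented container of water observations.

    Wraps numpy arrays for efficient clustering; constructible from
    :class:`WaterObservation` records, a pandas DataFrame with columns
    ``frame,mol_id,x,y,z,e_sw,e_ww``, or a CSV file in that layout.
    """

    def __init__(self, frames, mol_ids, positions, e_sw, e_ww):
        self.frames = np.asarray(frames, dtype=int)
        self.mol_ids = np.asarray(mol_ids, dtype=int)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.e_sw = np.asarray(e_sw, dtype=float)
        self.e_ww = np.asarray(e_ww, dtype=float)
        n = len(self.frames)
        if not all(len(a) == n for a in (self.mol_ids, self.positions, self.e_sw, self.e_ww)):
            raise ValueError("column lengths disagree")
        if n and not np.isfinite(self.positions).all():
            raise ValueError("non-finite water coordinates")
        if n and (self.frames < 0).any():
            raise ValueError("negative frame indices")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_records(cls, records: Iterable[WaterObservation]) -> "WaterObservations":
        recs = list(records)
        return cls(
            [r.frame_index for r in recs],
            [r.molecule_id for r in recs],
            [r.position for r in recs],
            [r.e_sw for r in recs],
            [r.e_ww for r in recs],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "WaterObservations":
        cols = ["frame", "mol_id", "x", "y", "z", "e_sw", "e_ww"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing water-observation columns: {missing}")
        return cls(
            df["frame"].to_numpy(),
            df["mol_id"].to_numpy(),
            df[["x", "y", "z"]].to_numpy(),
            df["e_sw"].to_numpy(),
            df["e_ww"].to_numpy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "mol_id": self.mol_ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "e_sw": self.e_sw,
                "e_ww": self.e_ww,
            }
        )

    def subset(self, mask: np.ndarray) -> "WaterObservations":
        return WaterObservations(
            self.frames[mask],
            self.mol_ids[mask],
            self.positions[mask],
            self.e_sw[mask],
            self.e_ww[mask],
        )


def _as_observations(observations) -> WaterObservations:
    if isinstance(observations, WaterObservations):
        return observations
    if isinstance(observations, pd.DataFrame):
        return WaterObservations.from_dataframe(observations)
    return WaterObservations.from_records(observations)


@dataclass
class ClusterConfig:
    """Parameters of the site-identification analysis.

    site_radius
        Radius of a hydration site sphere (Å).  Observations within this
        distance of a site center belong to the site.
    region_center, region_radius
        Spherical analysis region (Å); observations outside are ignored.
    min_occupancy
        Sites whose water occupancy falls below this fraction are dropped.
    n_frames
        Total number of trajectory frames, the denominator of occupancy.
    e_bulk
        Bulk water reference energy (kcal/mol).
    e_total_convention
        ``"half-half"``: E_total = ½⟨E_sw⟩ + ½⟨E_ww⟩ (default);
        ``"sw-plus-half-ww"``: E_total = ⟨E_sw⟩ + ½⟨E_ww⟩.
    """

    n_frames: int
    region_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region_radius: float = 8.0
    site_radius: float = 1.0
    min_occupancy: float = 0.25
    e_bulk: float = E_BULK_DEFAULT
    e_total_convention: str = "half-half"

    def __post_init__(self):
        if self.site_radius <= 0:
            raise ValueError("site_radius must be positive")
        if self.region_radius <= self.site_radius:
            raise ValueError("region_radius must exceed site_radius")
        if not 0.0 <= self.min_occupancy <= 1.0:
            raise ValueError("min_occupancy must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.e_total_convention not in ("half-half", "sw-plus-half-ww"):
            raise ValueError(f"unknown e_total convention {self.e_total_convention!r}")


@dataclass
class HydrationSite:
    site_id: int
    center: tuple[float, float, float]
    occupancy_p: float
    n_waters: int
    mean_e_sw: float = float("nan")
    mean_e_ww: float = float("nan")
    e_total: float = float("nan")
    score: float = float("nan")


@dataclass
class HydrationMap:
    structure_label: str
    sites: list[HydrationSite]
    config: ClusterConfig

    def __len__(self) -> int:
        return len(self.sites)


def score_site(e_total: float, e_bulk: float, p: float) -> float:
    """Occupancy-weighted excess site energy, (E_total − E_bulk)·p.

    Positive values mark unfavorable sites — displacement by a ligand
    favors binding.  ``p`` must be a fraction in [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"occupancy p must lie in [0, 1], got {p}")
    return (e_total - e_bulk) * p


def _region_mask(obs: WaterObservations, config: ClusterConfig) -> np.ndarray:
    d = np.linalg.norm(obs.positions - np.asarray(config.region_center, float), axis=1)
    return d <= config.region_radius


def cluster_hydration_sites(observations, config: ClusterConfig, label: str = "") -> HydrationMap:
    """Identify hydration sites by greedy density clustering.

    Repeatedly selects the observation position with the largest number of
    observations within ``site_radius`` (ties broken by lexicographically
    smallest position), emits it as a site center, removes its members, and
    stops when
    the best count drops below ``min_occupancy × n_frames``.  Observations
    are then assigned to the nearest emitted center within ``site_radius``
    and sites below the occupancy threshold are dropped.
    """
    obs = _as_observations(observations)
    if len(obs) == 0:
        return HydrationMap(label, [], config)

    region = obs.subset(_region_mask(obs, config))
    if len(region) == 0:
        return HydrationMap(label, [], config)

    pos = region.positions
    tree = cKDTree(pos)
    neighbors = tree.query_ball_point(pos, config.site_radius)
    counts = np.array([len(nb) for nb in neighbors])
    alive = np.ones(len(pos), dtype=bool)
    threshold = max(config.min_occupancy * config.n_frames, 1.0)

    # tie-break among equal-count candidates: lexicographically smallest
    # position, so the result is invariant under permutation of observations
    lex_rank = np.empty(len(pos), dtype=int)
    lex_rank[np.lexsort((pos[:, 2], pos[:, 1], pos[:, 0]))] = np.arange(len(pos))

    centers: list[np.ndarray] = []
    while True:
        masked = np.where(alive, counts, -1)
        best_count = masked.max()
        if best_count < threshold:
            break
        tied = np.flatnonzero(masked == best_count)
        best = int(tied[np.argmin(lex_rank[tied])])
        centers.append(pos[best].copy())
        members = [i for i in neighbors[best] if alive[i]]
        for m in members:
            alive[m] = False
            for q in neighbors[m]:
                counts[q] -= 1

    if not centers:
        return HydrationMap(label, [], config)

    # Final assignment: each observation goes to the nearest center within
    # site_radius, so no observation is double-counted.
    carr = np.vstack(centers)
    ctree = cKDTree(carr)
    dist, idx = ctree.query(pos, k=1)
    assigned = dist <= config.site_radius

    sites: list[HydrationSite] = []
    for j in range(len(centers)):
        mask = assigned & (idx == j)
        n_waters = int(mask.sum())
        if n_waters == 0:
            continue
        occ_frames = len(np.unique(region.frames[mask]))
        p = min(occ_frames / config.n_frames, 1.0)
        if p < config.min_occupancy:
            continue
        sites.append(
            HydrationSite(
                site_id=j,
                center=tuple(float(v) for v in centers[j]),
                occupancy_p=p,
                n_waters=n_waters,
            )
        )

    sites.sort(key=lambda s: -s.n_waters)
    for new_id, s in enumerate(sites):
        s.site_id = new_id
    return HydrationMap(label, sites, config)


def compute_site_thermodynamics(hydration_map: HydrationMap, observations) -> HydrationMap:
    """Populate per-site mean energies, E_total and the site score.

    Members are the observations within ``site_radius`` of the site center
    (nearest-center assignment, so each observation contributes to one
    site).  E_total follows the convention in the map's config; the score
    is (E_total − E_bulk)·p.  Sites left with zero member observations are
    removed with a warning.
    """
    obs = _as_observations(observations)
    config = hydration_map.config
    if not hydration_map.sites:
        return hydration_map

    region = obs.subset(_region_mask(obs, config))
    carr = np.array([s.center for s in hydration_map.sites], float)
    if len(region) == 0:
        warnings.warn("no observations in region; all sites removed")
        hydration_map.sites = []
        return hydration_map

    ctree = cKDTree(carr)
    dist, idx = ctree.query(region.positions, k=1)
    assigned = dist <= config.site_radius

    kept: list[HydrationSite] = []
    for j, site in enumerate(hydration_map.sites):
        mask = assigned & (idx == j)
        if not mask.any():
            warnings.warn(f"hydration site {site.site_id} has no member waters; removed")
            continue
        mean_sw = float(region.e_sw[mask].mean())
        mean_ww = float(region.e_ww[mask].mean())
        if config.e_total_convention == "half-half":
            e_total = 0.5 * mean_sw + 0.5 * mean_ww
        else:
            e_total = mean_sw + 0.5 * mean_ww
        site.mean_e_sw = mean_sw
        site.mean_e_ww = mean_ww
        site.e_total = e_total
        site.n_waters = int(mask.sum())
        site.score = score_site(e_total, config.e_bulk, site.occupancy_p)
        kept.append(site)
    hydration_map.sites = kept
    return hydration_map


# ---------------------------------------------------------------------------
# I/O

def read_water_csv(path) -> WaterObservations:
    """Read water observations from CSV (columns frame,mol_id,x,y,z,e_sw,e_ww)."""
    return WaterObservations.from_dataframe(pd.read_csv(path))


def write_water_csv(obs: WaterObservations, path) -> None:
    _as_observations(obs).to_dataframe().to_csv(path, index=False)


def write_map_json(hydration_map: HydrationMap, path) -> None:
    """Serialize a hydration map with per-site occupancy, relative energy and score."""
    payload = {
        "structure_label": hydration_map.structure_label,
        "config": asdict(hydration_map.config),
        "sites": [
            {
                "site_id": s.site_id,
                "center": list(s.center),
                "p": s.occupancy_p,
                "n_waters": s.n_waters,
                "mean_e_sw": s.mean_e_sw,
                "mean_e_ww": s.mean_e_ww,
                "e_total": s.e_total,
                "e_rel_bulk": s.e_total - hydration_map.config.e_bulk,
                "score": s.score,
            }
            for s in hydration_map.sites
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_map_json(path) -> HydrationMap:
    with open(path) as fh:
        payload = json.load(fh)
    config = ClusterConfig(**payload["config"])
    sites = [
        HydrationSite(
            site_id=rec["site_id"],
            center=tuple(rec["center"]),
            occupancy_p=rec["p"],
            n_waters=rec["n_waters"],
            mean_e_sw=rec.get("mean_e_sw", float("nan")),
            mean_e_ww=rec.get("mean_e_ww", float("nan")),
            e_total=rec.get("e_total", float("nan")),
            score=rec.get("score", float("nan")),
        )
        for rec in payload["sites"]
    ]
    return HydrationMap(payload["structure_label"], sites, config)
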