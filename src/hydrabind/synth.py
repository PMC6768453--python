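"""Synthetic fixtures with known ground truth.

Three generators mirror the inputs the analysis modules consume:

- planted hydration sites in a toy binding pocket, emitting per-frame water
  observations whose occupancies, positions and energy distributions are
  known exactly;
- λ-state binding-energy samples from a Gaussian base ensemble, for which
  the alchemical free-energy profile has the closed form
  ΔG(λ) = λμ − βλ²σ²/2 (and the λ-tilted sample distribution is
  N(μ − λβσ², σ²));
- a toy concave pocket of pseudo-atoms with planted hydration spheres and
  nested ligand atom sets that occlude a recorded subset of the spheres.

Every generator is reproducible given (seed, parameters) and returns its
truth record alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alchemy import LambdaSampleSet, LambdaSchedule, SoftCoreParams, swap_acceptance
from .constants import kbt
from .hsa import WaterObservations
from .spheres import HydrationSphere, SoluteAtom

__all__ = [
    "PlantedSite",
    "GaussianAlchemyTruth",
    "ToyPocket",
    "generate_water_frames",
    "generate_lambda_samples",
    "generate_toy_pocket",
    "simulate_replica_exchange",
]


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one hydration site in the water-frame generator."""

    center: tuple[float, float, float]
    true_occupancy: float
    e_sw_dist: tuple[float, float] = (-14.0, 1.0)  # (mean, sd), kcal/mol
    e_ww_dist: tuple[float, float] = (-10.0, 1.0)
    jitter_sd: float = 0.3  # Å; < site_radius/2 keeps sites resolvable

    def __post_init__(self):
        if not 0.0 <= self.true_occupancy <= 1.0:
            raise ValueError("true_occupancy must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    def expected_e_total(self, convention: str = "half-half") -> float:
        if convention == "half-half":
            return 0.5 * self.e_sw_dist[0] + 0.5 * self.e_ww_dist[0]
        return self.e_sw_dist[0] + 0.5 * self.e_ww_dist[0]

    def expected_score(self, e_bulk: float, convention: str = "half-half") -> float:
        return (self.expected_e_total(convention) - e_bulk) * self.true_occupancy


def generate_water_frames(
    sites: list[PlantedSite], n_frames: int, seed: int
) -> WaterObservations:
    """Draw per-frame water observations from planted hydration sites.

    Each frame, each site is occupied independently with probability
    ``true_occupancy``; an occupied site contributes one water at
    center + isotropic Gaussian jitter with energies drawn from the site's
    normal distributions.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames, mol_ids, positions, e_sw, e_ww = [], [], [], [], []
    mol = 0
    for si, site in enumerate(sites):
        occupied = rng.random((n_frames,)) < site.true_occupancy
        idx = np.flatnonzero(occupied)
        n = len(idx)
        pos = np.asarray(site.center, float) + rng.normal(0.0, site.jitter_sd, (n, 3)) \
            if site.jitter_sd > 0 else np.tile(np.asarray(site.center, float), (n, 1))
        frames.append(idx)
        mol_ids.append(np.arange(mol, mol + n))
        mol += n
        positions.append(pos)
        e_sw.append(rng.normal(site.e_sw_dist[0], site.e_sw_dist[1], n))
        e_ww.append(rng.normal(site.e_ww_dist[0], site.e_ww_dist[1], n))
    if not sites:
        return WaterObservations([], [], np.empty((0, 3)), [], [])
    order = np.argsort(np.concatenate(frames), kind="stable")
    return WaterObservations(
        np.concatenate(frames)[order],
        np.concatenate(mol_ids)[order],
        np.vstack(positions)[order],
        np.concatenate(e_sw)[order],
        np.concatenate(e_ww)[order],
    )


@dataclass(frozen=True)
class GaussianAlchemyTruth:
    """Gaussian base ensemble: u ~ N(mu, sigma²) at λ=0.

    Under the λ-linear coupling the exact profile is
    ΔG(λ) = λ·mu − λ²·sigma²/(2 k_B T) and the λ-state sample distribution
    is N(mu − λ·sigma²/(k_B T), sigma²).
    """

    mu: float = -40.0
    sigma: float = 3.0
    temperature: float = 300.0

    def dG(self, lam: float) -> float:
        return lam * self.mu - (lam**2 * self.sigma**2) / (2.0 * kbt(self.temperature))

    def tilted_mean(self, lam: float) -> float:
        return self.mu - lam * self.sigma**2 / kbt(self.temperature)


def generate_lambda_samples(
    truth: GaussianAlchemyTruth,
    schedule: LambdaSchedule,
    n_per_state: int,
    seed: int,
    softcore: SoftCoreParams | None = None,
) -> LambdaSampleSet:
    """Draw binding-energy samples from the exact λ-tilted Gaussian at each state."""
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [
        rng.normal(truth.tilted_mean(lam), truth.sigma, n_per_state)
        for lam in schedule.values
    ]
    return LambdaSampleSet(
        schedule,
        samples,
        temperature=truth.temperature,
        softcore=softcore if softcore is not None else SoftCoreParams(enabled=False),
    )


@dataclass
class ToyPocket:
    """A concave shell of pseudo-atoms with planted hydration spheres.

    ``ligand_sets[k]`` occludes exactly the sphere ids in ``occluded_by[k]``
    (construction truth, verified at generation time).
    """

    pocket_atoms: list[SoluteAtom]
    spheres: list[HydrationSphere]
    ligand_sets: list[list[SoluteAtom]]
    occluded_by: list[list[int]]


def generate_toy_pocket(
    seed: int,
    n_spheres: int = 3,
    h_s_values: tuple[float, ...] | None = None,
) -> ToyPocket:
    """Build a toy pocket, planted spheres, and nested occluding ligands.

    Sphere centers sit 3.5 Å apart on a line inside a hemispherical shell
    of pseudo-atoms; shell atoms are kept far enough away that pocket atoms
    alone leave every sphere above its switching threshold.  Ligand set k
    consists of k oversized atoms placed exactly on the first k sphere
    centers, fully occluding them (S = 0).
    """
    rng = np.random.default_rng(seed)
    if h_s_values is None:
        h_s_values = tuple(float(v) for v in rng.uniform(0.5, 3.0, n_spheres))
    if len(h_s_values) != n_spheres:
        raise ValueError("h_s_values length must equal n_spheres")

    centers = [np.array([3.5 * i, 0.0, 0.0]) for i in range(n_spheres)]
    midpoint = np.mean(centers, axis=0)
    shell_radius = 3.5 * n_spheres / 2 + 5.0

    # hemispherical shell (z < 0 opening upward), jittered for irregularity
    pocket_atoms: list[SoluteAtom] = []
    serial = 1
    n_shell = 80
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for i in range(n_shell):
        z = -1.0 + (i + 0.5) / n_shell  # only keep lower hemisphere below
        theta = golden * i
        point = np.array(
            [math.cos(theta) * math.sqrt(1 - z * z),
             math.sin(theta) * math.sqrt(1 - z * z), z]
        )
        if point[2] > 0.2:  # leave the pocket mouth open
            continue
        pos = midpoint + shell_radius * point + rng.normal(0.0, 0.15, 3)
        pocket_atoms.append(
            SoluteAtom(serial=serial, element="C", position=tuple(pos), radius=1.70)
        )
        serial += 1

    spheres = [
        HydrationSphere(sphere_id=i, h_s=h_s_values[i],
                        center=tuple(float(v) for v in centers[i]))
        for i in range(n_spheres)
    ]

    # construction constraint: pocket atoms alone keep every sphere open
    from .spheres import free_volume

    for sp in spheres:
        v = free_volume(sp.center, sp.radius_rs, pocket_atoms, grid_spacing=0.2)
        if v / sp.volume < sp.switch_hi:
            raise RuntimeError("toy pocket construction left a sphere occluded")

    ligand_sets: list[list[SoluteAtom]] = []
    occluded_by: list[list[int]] = []
    for k in range(n_spheres + 1):
        atoms = [
            SoluteAtom(serial=1000 + j, element="C",
                       position=tuple(float(v) for v in centers[j]), radius=2.0)
            for j in range(k)
        ]
        ligand_sets.append(atoms)
        occluded_by.append(list(range(k)))
    return ToyPocket(pocket_atoms, spheres, ligand_sets, occluded_by)


def simulate_replica_exchange(
    truth: GaussianAlchemyTruth,
    schedule: LambdaSchedule,
    n_cycles: int,
    seed: int,
    reservoir_size: int = 1000,
) -> tuple[LambdaSampleSet, np.ndarray]:
    """Toy Hamiltonian replica-exchange bookkeeping on the Gaussian model.

    Each replica carries a configuration (its u value); every cycle each
    replica redraws u from its current λ-tilted distribution (a perfect
    within-state move), then neighboring λ pairs attempt Metropolis swaps.
    A replica visiting the uncoupled state (λ=0) resamples its configuration
    from a pre-drawn reservoir pool, mirroring reservoir exchange.  Returns
    the per-state sample set and the replica→state visit counts.
    """
    rng = np.random.default_rng(seed)
    n_states = len(schedule)
    lams = np.asarray(schedule.values)
    reservoir = rng.normal(truth.mu, truth.sigma, reservoir_size)
    state_of_replica = np.arange(n_states)
    samples: list[list[float]] = [[] for _ in range(n_states)]
    visits = np.zeros((n_states, n_states), dtype=int)
    u = np.array([rng.normal(truth.tilted_mean(l), truth.sigma) for l in lams])

    for cycle in range(n_cycles):
        for r in range(n_states):
            k = state_of_replica[r]
            if lams[k] == 0.0:
                u[r] = reservoir[rng.integers(reservoir_size)]
            else:
                u[r] = rng.normal(truth.tilted_mean(lams[k]), truth.sigma)
            samples[k].append(u[r])
            visits[r, k] += 1
        # neighbor swaps, alternating even/odd pairings
        start = cycle % 2
        replica_of_state = np.empty(n_states, dtype=int)
        replica_of_state[state_of_replica] = np.arange(n_states)
        for k in range(start, n_states - 1, 2):
            ri, rj = replica_of_state[k], replica_of_state[k + 1]
            p = swap_acceptance(lams[k], lams[k + 1], u[ri], u[rj], truth.temperature)
            if rng.random() < p:
                state_of_replica[ri], state_of_replica[rj] = k + 1, k
                replica_of_state[k], replica_of_state[k + 1] = rj, ri

    sample_set = LambdaSampleSet(
        schedule,
        [np.asarray(s) for s in samples],
        temperature=truth.temperature,
        softcore=SoftCoreParams(enabled=False),
    )
    return sample_set, visits
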