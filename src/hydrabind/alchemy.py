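"""Alchemical binding free-energy estimation from λ-state binding energies.

The single-decoupling alchemical potential is U_λ = U_0 + λ·u, where u is
the binding energy function (the change in effective energy on bringing
receptor and ligand from infinite separation into the complex conformation)
and λ couples them linearly from 0 (uncoupled) to 1 (coupled).  Binding
energy samples collected at a ladder of λ states are combined with UWHAM
(unbinned multistate reweighting) to yield the excess binding free energy
ΔG_b = G(λ=1) − G(λ=0) with an asymptotic uncertainty.

The standard-state result adds the transfer term ΔG_t° = −k_B T ln(C°·V_site)
for confining the ligand from standard concentration C° into the binding
site volume, plus any externally supplied ionization penalty.  The mean
binding energy ΔE_b at λ=1 and the reorganization free energy
ΔG_reorg° = ΔG_b° − ΔE_b complete the decomposition.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .constants import KB, STANDARD_VOLUME_A3, T_DEFAULT, kbt

__all__ = [
    "LambdaSchedule",
    "SoftCoreParams",
    "LambdaSampleSet",
    "TransferConfig",
    "UWHAMResult",
    "FreeEnergyResult",
    "softcore_transform",
    "swap_acceptance",
    "uwham_solve",
    "transfer_free_energy",
    "decompose",
    "read_samples_csv",
    "write_samples_csv",
]

# The 28-state λ ladder used for the receptor-ligand decoupling runs,
# densely spaced near the uncoupled end where du/dλ varies fastest.
_D3_28 = (
    0.0, 0.002, 0.005, 0.008, 0.009, 0.01, 0.0105, 0.012, 0.0135, 0.015,
    0.02, 0.0225, 0.025, 0.03, 0.035, 0.04, 0.07, 0.1, 0.25, 0.35,
    0.45, 0.55, 0.65, 0.71, 0.78, 0.85, 0.92, 1.0,
)

SCHEDULE_PRESETS = {"d3-28": _D3_28}


@dataclass(frozen=True)
class LambdaSchedule:
    values: tuple[float, ...]

    def __post_init__(self):
        v = self.values
        if len(v) < 2:
            raise ValueError("schedule needs at least two lambda values")
        if v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("schedule must start at 0 and end at 1")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("lambda values must be strictly increasing")

    def __len__(self):
        return len(self.values)

    @classmethod
    def preset(cls, name: str) -> "LambdaSchedule":
        try:
            return cls(SCHEDULE_PRESETS[name])
        except KeyError:
            raise KeyError(f"unknown schedule preset {name!r}") from None

    @classmethod
    def uniform(cls, n: int) -> "LambdaSchedule":
        return cls(tuple(np.linspace(0.0, 1.0, n)))


@dataclass(frozen=True)
class SoftCoreParams:
    """Bounded soft-core transform of the binding energy.

    Identity below the onset u_c; above it the value saturates smoothly at
    u_max via a tanh cap.  Tames the divergent repulsive energies sampled
    near the uncoupled state.
    """

    u_c: float = 100.0
    u_max: float = 300.0
    enabled: bool = True

    def __post_init__(self):
        if self.u_c >= self.u_max:
            raise ValueError("u_c must be below u_max")


def softcore_transform(u, params: SoftCoreParams):
    """Apply the soft-core cap: identity for u <= u_c, tanh saturation above.

    Monotone, continuous with continuous first derivative, bounded above by
    u_max (= u_c + (u_max − u_c) asymptotically).
    """
    if not params.enabled:
        return u
    u = np.asarray(u, dtype=float)
    span = params.u_max - params.u_c
    out = np.where(u <= params.u_c, u, params.u_c + span * np.tanh(
        np.clip((u - params.u_c) / span, 0.0, None)))
    return float(out) if out.ndim == 0 else out


@dataclass
class LambdaSampleSet:
    """Binding-energy samples collected at each λ state of a schedule."""

    schedule: LambdaSchedule
    samples: list[np.ndarray]  # one array of u values (kcal/mol) per state
    temperature: float = 300.0
    softcore: SoftCoreParams = field(default_factory=SoftCoreParams)

    def __post_init__(self):
        if len(self.samples) != len(self.schedule):
            raise ValueError("one sample array required per schedule state")
        self.samples = [np.asarray(s, dtype=float).ravel() for s in self.samples]
        for i, s in enumerate(self.samples):
            if s.size and not np.isfinite(softcore_transform(s, self.softcore)).all():
                raise ValueError(f"state {i}: non-finite binding energies")

    @property
    def n_states(self) -> int:
        return len(self.schedule)

    def discard_initial(self, fraction: float) -> "LambdaSampleSet":
        """Drop the leading ``fraction`` of each state's samples (equilibration)."""
        if not 0.0 <= fraction < 1.0:
            raise ValueError("discard fraction must lie in [0, 1)")
        return LambdaSampleSet(
            self.schedule,
            [s[int(len(s) * fraction):] for s in self.samples],
            self.temperature,
            self.softcore,
        )


def swap_acceptance(lam_i: float, lam_j: float, u_i: float, u_j: float,
                    temperature: float) -> float:
    """Metropolis probability of exchanging λ values between two replicas.

    For the λ-linear Hamiltonian the energy change of swapping
    (λ_i, u_i) ↔ (λ_j, u_j) is (λ_i − λ_j)(u_j − u_i), giving
    min{1, exp[−β(λ_i − λ_j)(u_j − u_i)]} — detailed balance for the swap
    move on fixed configurations.
    """
    beta = 1.0 / kbt(temperature)
    return min(1.0, math.exp(-beta * (lam_i - lam_j) * (u_j - u_i)))


@dataclass
class UWHAMResult:
    lambdas: np.ndarray
    free_energies: np.ndarray      # kcal/mol, G(λ=0) = 0
    errors: np.ndarray             # kcal/mol, var(G_k − G_0)^0.5
    n_samples: np.ndarray
    overlap: np.ndarray            # K×K overlap matrix
    converged: bool
    n_iterations: int

    @property
    def dG(self) -> float:
        """Excess binding free energy G(λ=1) − G(λ=0), kcal/mol."""
        return float(self.free_energies[-1])

    @property
    def dG_err(self) -> float:
        return float(self.errors[-1])


def _reduced_energies(sample_set: LambdaSampleSet) -> tuple[np.ndarray, np.ndarray]:
    """Pool samples and build the K×N reduced-energy matrix βλ_k u_n."""
    beta = 1.0 / kbt(sample_set.temperature)
    pooled = [softcore_transform(s, sample_set.softcore) for s in sample_set.samples]
    u_all = np.concatenate([p for p in pooled]) if pooled else np.empty(0)
    lambdas = np.asarray(sample_set.schedule.values)
    e_kn = beta * np.outer(lambdas, u_all)
    n_k = np.array([len(s) for s in sample_set.samples])
    return e_kn, n_k


def uwham_solve(sample_set: LambdaSampleSet, tol: float = 1e-10,
                max_iter: int = 10000) -> UWHAMResult:
    """Unbinned multistate reweighting (UWHAM/MBAR) over the λ ladder.

    Minimizes the standard convex objective with L-BFGS-B, then polishes by
    self-consistent iteration until successive dimensionless free energies
    change by less than ``tol``.  States with zero samples are evaluated by
    reweighting (with one sampled state this reduces to Zwanzig exponential
    averaging).  Uncertainties come from the asymptotic covariance of the
    estimator; the overlap matrix is returned as a diagnostic.
    """
    e_kn, n_k = _reduced_energies(sample_set)
    k_states = len(n_k)
    if (n_k > 0).sum() < 1:
        raise ValueError("at least one state must have samples")
    n_total = int(n_k.sum())
    if n_total == 0:
        raise ValueError("no samples provided")

    sampled = np.flatnonzero(n_k > 0)
    e_s = e_kn[sampled]                     # (Ks, N)
    log_nk = np.log(n_k[sampled])

    def objective(f_free):
        f = np.concatenate([[0.0], f_free])
        a = log_nk[:, None] + f[:, None] - e_s
        lse = logsumexp(a, axis=0)
        val = lse.mean() - (n_k[sampled] @ f) / n_total
        w = np.exp(a - lse)                 # (Ks, N), columns sum to 1
        grad = w.sum(axis=1) / n_total - n_k[sampled] / n_total
        return val, grad[1:]

    f0 = np.zeros(len(sampled) - 1)
    if len(f0):
        res = minimize(objective, f0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10})
        f_sampled = np.concatenate([[0.0], res.x])
    else:
        f_sampled = np.zeros(1)

    # self-consistent polish
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_c = logsumexp(log_nk[:, None] + f_sampled[:, None] - e_s, axis=0)
        f_new = -logsumexp(-e_s - log_c, axis=1)
        f_new -= f_new[0]
        delta = np.abs(f_new - f_sampled).max()
        f_sampled = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("UWHAM self-consistent iteration did not fully converge")

    log_c = logsumexp(log_nk[:, None] + f_sampled[:, None] - e_s, axis=0)
    f_all = -logsumexp(-e_kn - log_c, axis=1)
    f_all -= f_all[np.flatnonzero(n_k >= 0)[0]]  # anchor at state 0 (λ=0)
    f_all -= f_all[0]

    # weight matrix over all K states for covariance / overlap diagnostics
    w_all = np.exp(f_all[:, None] - e_kn - log_c).T   # (N, K), columns sum to 1
    overlap = (w_all * n_k).T @ w_all                 # O_ij = N_i Σ_n W_ni W_nj

    off = np.array([overlap[i, i + 1] for i in range(k_states - 1)])
    if n_k.min() > 0 and off.min() < 1e-6:
        warnings.warn(
            "poor overlap between adjacent lambda states; free energies may "
            f"be unreliable (min adjacent overlap {off.min():.2e})"
        )

    theta = _asymptotic_covariance(w_all, n_k)
    var = theta.diagonal() + theta[0, 0] - 2.0 * theta[0, :]
    var = np.clip(var, 0.0, None)
    kt = kbt(sample_set.temperature)
    return UWHAMResult(
        lambdas=np.asarray(sample_set.schedule.values),
        free_energies=kt * f_all,
        errors=kt * np.sqrt(var),
        n_samples=n_k,
        overlap=overlap,
        converged=converged,
        n_iterations=n_iter,
    )


def _asymptotic_covariance(w_all: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the dimensionless free energies.

    Uses the SVD form Θ = V S (I − S Vᵀ N V S)⁺ S Vᵀ with W = U S Vᵀ the
    N×K weight matrix and N = diag(sample counts).
    """
    _, s, vt = np.linalg.svd(w_all, full_matrices=False)
    v = vt.T
    s_mat = np.diag(s)
    inner = np.eye(len(s)) - s_mat @ vt @ np.diag(n_k.astype(float)) @ v @ s_mat
    theta = v @ s_mat @ np.linalg.pinv(inner, rcond=1e-10) @ s_mat @ vt
    return theta


@dataclass
class TransferConfig:
    """Standard-state transfer parameters: site radius, C°, temperature."""

    site_radius: float = 3.5
    standard_concentration: float = 1.0  # mol/L
    temperature: float = T_DEFAULT

    def __post_init__(self):
        if min(self.site_radius, self.standard_concentration, self.temperature) <= 0:
            raise ValueError("site_radius, concentration and temperature must be positive")

    @property
    def v_site(self) -> float:
        return 4.0 / 3.0 * math.pi * self.site_radius**3


def transfer_free_energy(config: TransferConfig) -> float:
    """Standard-state transfer term ΔG_t° = −k_B T ln(C°·V_site), kcal/mol.

    The free-energy cost of confining the ligand from a solution at
    standard concentration C° into the binding-site volume V_site
    (hard spherical volume; 1 M corresponds to 1/1660.54 Å⁻³).
    """
    c_per_a3 = config.standard_concentration / STANDARD_VOLUME_A3
    return -kbt(config.temperature) * math.log(c_per_a3 * config.v_site)


@dataclass
class FreeEnergyResult:
    dG_b: float
    dG_b_err: float
    dG_transfer: float
    dG_ionization: float
    dG_b_standard: float
    dE_b: float
    dE_b_err: float
    dG_reorg: float
    dG_reorg_err: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def decompose(
    sample_set: LambdaSampleSet,
    uwham_out: UWHAMResult,
    config: TransferConfig,
    dG_ionization: float = 0.0,
) -> FreeEnergyResult:
    """Assemble the standard binding free energy and its decomposition.

    dE_b is the mean (soft-core-transformed) binding energy at λ=1 with a
    standard-error-of-the-mean uncertainty; ΔG_b° = ΔG_b + ΔG_t° + ΔG_ion;
    ΔG_reorg° = ΔG_b° − ΔE_b with errors combined in quadrature (the
    correlation between the two estimates is neglected).
    """
    u1 = softcore_transform(sample_set.samples[-1], sample_set.softcore)
    if u1.size == 0:
        raise ValueError("no samples at the coupled state (lambda = 1)")
    de_b = float(np.mean(u1))
    de_b_err = float(np.std(u1, ddof=1) / math.sqrt(len(u1))) if len(u1) > 1 else 0.0

    dg_b = uwham_out.dG
    dg_b_err = uwham_out.dG_err
    dg_t = transfer_free_energy(config)
    dg_std = dg_b + dg_t + dG_ionization
    dg_reorg = dg_std - de_b
    dg_reorg_err = math.hypot(dg_b_err, de_b_err)
    return FreeEnergyResult(
        dG_b=dg_b,
        dG_b_err=dg_b_err,
        dG_transfer=dg_t,
        dG_ionization=dG_ionization,
        dG_b_standard=dg_std,
        dE_b=de_b,
        dE_b_err=de_b_err,
        dG_reorg=dg_reorg,
        dG_reorg_err=dg_reorg_err,
    )


# ---------------------------------------------------------------------------
# I/O

def write_samples_csv(sample_set: LambdaSampleSet, path, metadata_path=None) -> None:
    """Write λ samples as CSV (state_index,lambda,cycle,u) plus metadata JSON."""
    rows = []
    for k, (lam, s) in enumerate(zip(sample_set.schedule.values, sample_set.samples)):
        for cycle, u in enumerate(s):
            rows.append((k, lam, cycle, u))
    pd.DataFrame(rows, columns=["state_index", "lambda", "cycle", "u"]).to_csv(
        path, index=False
    )
    if metadata_path is not None:
        meta = {
            "temperature": sample_set.temperature,
            "softcore": {
                "u_c": sample_set.softcore.u_c,
                "u_max": sample_set.softcore.u_max,
                "enabled": sample_set.softcore.enabled,
            },
            "schedule": list(sample_set.schedule.values),
        }
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_samples_csv(path, metadata_path=None, schedule: LambdaSchedule | None = None,
                     temperature: float | None = None,
                     softcore: SoftCoreParams | None = None) -> LambdaSampleSet:
    """Read λ samples from CSV; schedule/temperature from metadata JSON if given."""
    df = pd.read_csv(path)
    if metadata_path is not None:
        with open(metadata_path) as fh:
            meta = json.load(fh)
        schedule = LambdaSchedule(tuple(meta["schedule"]))
        temperature = meta.get("temperature", temperature)
        sc = meta.get("softcore")
        if sc is not None:
            softcore = SoftCoreParams(sc["u_c"], sc["u_max"], sc["enabled"])
    if schedule is None:
        lams = df.sort_values("state_index").groupby("state_index")["lambda"].first()
        schedule = LambdaSchedule(tuple(lams.to_numpy()))
    samples = []
    for k in range(len(schedule)):
        sub = df[df["state_index"] == k].sort_values("cycle")
        samples.append(sub["u"].to_numpy())
    return LambdaSampleSet(
        schedule,
        samples,
        temperature=temperature if temperature is not None else 300.0,
        softcore=softcore if softcore is not None else SoftCoreParams(),
    )
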