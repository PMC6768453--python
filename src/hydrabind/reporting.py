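"""Experimental-affinity conversion and model-accuracy summaries.

Inhibition constants K_i are converted to experimental binding free
energies via ΔG_exp° = k_B T ln K_i (K_i in mol/L), and paired
experimental/calculated free energies are summarised by RMSE and the
Pearson correlation coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import kbt, T_DEFAULT

__all__ = [
    "ExperimentRecord",
    "AccuracySummary",
    "ki_to_dg",
    "accuracy_summary",
    "read_experiment_csv",
]


@dataclass(frozen=True)
class ExperimentRecord:
    compound_id: str
    ki_molar: float
    temperature: float = T_DEFAULT

    @property
    def dG_exp(self) -> float:
        return ki_to_dg(self.ki_molar, self.temperature)


def ki_to_dg(ki: float, temperature: float = T_DEFAULT, unit: str = "M") -> float:
    """Experimental binding free energy ΔG_exp° = k_B T ln K_i, kcal/mol.

    ``unit`` may be ``"M"`` (mol/L, default) or ``"nM"``.  Negative for any
    K_i below 1 M; strictly increasing in K_i.
    """
    if ki <= 0:
        raise ValueError(f"K_i must be positive, got {ki}")
    if unit == "nM":
        ki = ki * 1e-9
    elif unit != "M":
        raise ValueError(f"unsupported K_i unit {unit!r}")
    return kbt(temperature) * math.log(ki)


@dataclass(frozen=True)
class AccuracySummary:
    rmse: float
    pearson_r: float | None
    n: int


def accuracy_summary(pairs) -> AccuracySummary:
    """RMSE and Pearson r over paired (dG_exp, dG_calc) values.

    Pairs with a missing member are dropped.  rmse = sqrt(mean((calc−exp)²));
    r is the sample Pearson correlation (undefined and reported as None when
    either column has zero variance or fewer than two pairs remain).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one pair is required")
    arr = arr[np.isfinite(arr).all(axis=1)]
    n = len(arr)
    if n == 0:
        raise ValueError("all pairs had missing values")
    exp, calc = arr[:, 0], arr[:, 1]
    rmse = float(np.sqrt(np.mean((calc - exp) ** 2)))
    pearson = None
    if n >= 2:
        if np.std(exp) == 0.0 or np.std(calc) == 0.0:
            warnings.warn("zero variance in a column; Pearson r undefined")
        else:
            pearson = float(np.corrcoef(exp, calc)[0, 1])
    return AccuracySummary(rmse=rmse, pearson_r=pearson, n=n)


def read_experiment_csv(path, temperature: float = T_DEFAULT) -> list[ExperimentRecord]:
    """Read an experimental table (columns compound_id,Ki_nM)."""
    df = pd.read_csv(path)
    for col in ("compound_id", "Ki_nM"):
        if col not in df.columns:
            raise ValueError(f"experimental CSV missing column {col!r}")
    return [
        ExperimentRecord(str(r.compound_id), float(r.Ki_nM) * 1e-9, temperature)
        for r in df.itertuples()
    ]
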