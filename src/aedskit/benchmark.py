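"""Benchmark statistics: anchoring predictions to experiment and scoring.

Reference-state free energies come out as ΔΔG relative to an arbitrary
reference Hamiltonian. To compare with experimental binding free energies
they are shifted by a single constant — the mean difference between
experiment and prediction — which zeroes the mean residual and costs one
degree of freedom. The headline statistics are then

    RMSE = √( Σ (pred_shifted − exp)² / (n − 1) )     (n−1: the lost dof)
    slope, R²: ordinary least squares of prediction on experiment.

A packaged 11-ligand benchmark table of cavity binders (experimental
binding free energies with errors, plus three sets of predictions from
boosted reference-state simulations) ships with the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkTable",
    "load_benchmark",
    "shift_to_experiment",
    "rmse_dof",
    "linear_fit",
]

#: prediction columns available in the packaged benchmark table
PREDICTION_COLUMNS = ("aeds_full", "aeds_groups", "aeds_helix")


@dataclass(frozen=True)
class BenchmarkStats:
    """Shift constant and fit statistics of one prediction column."""

    column: str
    n: int
    shift: float
    rmse: float
    slope: float
    r2: float

    def as_dict(self) -> dict:
        return {
            "column": self.column,
            "n": self.n,
            "shift_kJ_per_mol": self.shift,
            "rmse_kJ_per_mol": self.rmse,
            "slope": self.slope,
            "r2": self.r2,
        }


class BenchmarkTable:
    """Ligand names with experimental ΔG_bind and predicted values.

    Thin wrapper over a DataFrame with at least the columns
    ``ligand``, ``experiment`` and one or more prediction columns, all
    energies in kJ·mol⁻¹. Experimental errors (``experiment_err``) are
    carried but not propagated into the statistics.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"ligand", "experiment"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"benchmark table missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def experimental(self) -> np.ndarray:
        return self.frame["experiment"].to_numpy(dtype=float)

    def predictions(self, column: str) -> np.ndarray:
        if column not in self.frame.columns:
            raise KeyError(f"no prediction column {column!r}")
        return self.frame[column].to_numpy(dtype=float)

    def evaluate(self, column: str, dof_lost: int = 1) -> BenchmarkStats:
        """Shift one prediction column to experiment and score it."""
        exp = self.experimental
        pred = self.predictions(column)
        shifted, shift = shift_to_experiment(pred, exp)
        rmse = rmse_dof(shifted, exp, dof_lost)
        slope, r2 = linear_fit(exp, shifted)
        return BenchmarkStats(column, len(exp), shift, rmse, slope, r2)


def load_benchmark(path: str | Path | None = None) -> BenchmarkTable:
    """Load a benchmark CSV; defaults to the packaged 11-ligand table."""
    if path is None:
        with resources.files("aedskit.data").joinpath("t4l_l99a_benchmark.csv").open() as fh:
            frame = pd.read_csv(fh)
    else:
        frame = pd.read_csv(path)
    return BenchmarkTable(frame)


def shift_to_experiment(predicted, experimental):
    """Anchor predictions to the experimental scale by a single constant.

    shift = mean(experimental − predicted); returns
    ``(predicted + shift, shift)``. The shifted residuals have zero mean
    by construction.
    """
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape or predicted.ndim != 1 or predicted.size < 1:
        raise ValueError("predicted and experimental must be equal-length 1-D vectors")
    shift = float(np.mean(experimental - predicted))
    return predicted + shift, shift


def rmse_dof(shifted, experimental, dof_lost: int = 1) -> float:
    """Root-mean-square error with ``dof_lost`` degrees of freedom removed.

    The default removes one degree of freedom for the fitted shift
    constant: RMSE = √( Σ r² / (n − dof_lost) ).
    """
    shifted = np.asarray(shifted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    n = len(shifted)
    if len(experimental) != n:
        raise ValueError("length mismatch")
    if n <= dof_lost:
        raise ValueError(f"need more than {dof_lost} points, got {n}")
    r = shifted - experimental
    return float(np.sqrt(np.sum(r**2) / (n - dof_lost)))


def linear_fit(experimental, predicted):
    """OLS of predictions on experiment: returns ``(slope, R²)``.

    R² is the squared Pearson correlation. Requires ≥ 3 points and
    nonzero variance in the experimental values.
    """
    experimental = np.asarray(experimental, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(experimental) != len(predicted) or len(experimental) < 3:
        raise ValueError("need at least 3 paired points")
    if np.allclose(experimental, experimental[0]):
        raise ValueError("experimental values have zero variance")
    fit = stats.linregress(experimental, predicted)
    return float(fit.slope), float(fit.rvalue**2)
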