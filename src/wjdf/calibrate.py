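"""Parameter estimation from metabolite/cell-count time series.

Two-stage scheme: a pooled fit on both passages' data (stage 1, every free
parameter), then a per-passage refit of the sensitive subset plus the
respiration capacity ``vmaxresp`` (stage 2), all other values frozen at
their stage-1 estimates.

The fit objective is a max-normalized mean squared residual

    E = (1/N) * sum_s sum_t ((sim_st - obs_st) / norm_s)^2,
    norm_s = max_t |obs_st|  (floored),

which puts species spanning five orders of magnitude (mM medium
concentrations vs 1e-7 mmol/1e6 cells pools) on one scale.  Optimization
runs in log10 parameter space with a bounded trust-region least-squares
solver and seeded multi-start.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .network import MetabolicNetwork, ParameterSet
from .simulate import (
    CultureState,
    SimulationError,
    SolverSettings,
    Trajectory,
    default_initial_state,
    simulate,
)

__all__ = [
    "ExperimentDataset",
    "CalibrationResult",
    "global_simulation_error",
    "fit_stage1",
    "fit_stage2",
    "fold_change_report",
]

log = logging.getLogger("wjdf")

#: Floor for the per-species normalization constant.
NORM_FLOOR = 1e-12

#: Relative half-width of the "idem" band in the fold-change report.
IDEM_BAND = 0.15

#: Residual filler when the integrator fails at a trial parameter vector.
_FAIL_RESIDUAL = 1e3


@dataclass
class ExperimentDataset:
    """Observed time series for one condition (P4 or P9).

    ``observations``: one row per sample time (index named ``time``), one
    column per measured quantity — cell density ``X`` plus measured species.
    ``sem`` optionally carries replicate standard errors on the same grid.
    ``initial`` is the full culture state at t=0 used to simulate the
    condition; when absent it is reconstructed from defaults overridden by
    the t=0 observations.
    """

    condition: str
    observations: pd.DataFrame
    sem: pd.DataFrame | None = None
    initial: CultureState | None = None
    network: MetabolicNetwork | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.observations.index, dtype=float)
        if times.size == 0:
            raise ValueError("dataset has no sample times")
        if not np.all(np.diff(times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if "X" in self.observations and not (self.observations["X"] > 0).all():
            raise ValueError("cell counts must be positive")
        if self.network is not None:
            known = set(self.network.species_ids) | {"X"}
            unknown = set(self.observations.columns) - known
            if unknown:
                raise ValueError(
                    f"observed species not in the network: {sorted(unknown)}"
                )

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.observations.index, dtype=float)

    def initial_state(self, network: MetabolicNetwork) -> CultureState:
        if self.initial is not None:
            return self.initial.copy()
        state = default_initial_state(network)
        row = self.observations.iloc[0]
        if "X" in row:
            state.X = float(row["X"])
        for sid, value in row.items():
            if sid in state.c_ext:
                state.c_ext[sid] = float(value)
            elif sid in state.c_int:
                state.c_int[sid] = float(value)
        return state


def _species_errors(
    traj: Trajectory,
    dataset: ExperimentDataset,
    weights: Mapping[str, float] | None,
) -> tuple[dict[str, float], int]:
    """Sum of squared normalized residuals per species + total point count."""
    sim = traj.states
    missing = [c for c in dataset.observations.columns if c not in sim.columns]
    if missing:
        raise KeyError(f"species in dataset absent from trajectory: {missing}")
    try:
        sim_at = sim.loc[dataset.times]
    except KeyError as exc:
        raise ValueError(
            "trajectory was not evaluated at the dataset sample times"
        ) from exc
    out: dict[str, float] = {}
    n_total = 0
    for col in dataset.observations.columns:
        obs = dataset.observations[col].to_numpy(dtype=float)
        norm = max(np.nanmax(np.abs(obs)), NORM_FLOOR)
        res = (sim_at[col].to_numpy() - obs) / norm
        w = 1.0 if weights is None else float(weights.get(col, 1.0))
        out[col] = w * float(np.nansum(res**2))
        n_total += int(np.sum(~np.isnan(obs)))
    return out, n_total


def global_simulation_error(
    traj: Trajectory,
    dataset: ExperimentDataset,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Max-normalized mean squared simulation-vs-data error (>= 0).

    Zero iff the simulation reproduces every observation exactly.
    """
    per_species, n_total = _species_errors(traj, dataset, weights)
    return sum(per_species.values()) / n_total


@dataclass
class CalibrationResult:
    params: ParameterSet
    objective: float
    per_species_error: dict[str, float]
    trace: list[float] = field(default_factory=list)
    seed: int | None = None
    n_restarts: int = 1
    free_names: list[str] = field(default_factory=list)

    def best_so_far(self) -> np.ndarray:
        """Monotone non-increasing best objective across restarts."""
        return np.minimum.accumulate(np.asarray(self.trace, dtype=float))


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------


class _Problem:
    """Residual function over log10 parameter space for one or two datasets."""

    def __init__(
        self,
        network: MetabolicNetwork,
        datasets: Sequence[ExperimentDataset],
        base: ParameterSet,
        free_names: Sequence[str],
        weights: Mapping[str, float] | None,
        solver: SolverSettings,
    ):
        self.network = network
        self.datasets = list(datasets)
        self.base = base
        self.free = list(free_names)
        self.weights = weights
        self.solver = solver
        self.initials = [ds.initial_state(network) for ds in self.datasets]
        self.n_points = []
        self.norms = []
        for ds in self.datasets:
            cols = list(ds.observations.columns)
            norms = {
                c: max(np.nanmax(np.abs(ds.observations[c].to_numpy(float))),
                       NORM_FLOOR)
                for c in cols
            }
            self.norms.append(norms)
            self.n_points.append(
                int(ds.observations.notna().to_numpy().sum())
            )
        self.n_res = sum(
            ds.observations.size for ds in self.datasets
        )

    def params_at(self, z: np.ndarray) -> ParameterSet:
        return self.base.with_values(
            {name: 10.0**zi for name, zi in zip(self.free, z)}
        )

    def residuals(self, z: np.ndarray) -> np.ndarray:
        params = self.params_at(z)
        blocks = []
        for ds, init, norms, n in zip(
            self.datasets, self.initials, self.norms, self.n_points
        ):
            try:
                traj = simulate(
                    self.network,
                    params,
                    initial=init,
                    t_end=float(ds.times.max()),
                    t_eval=ds.times,
                    solver=self.solver,
                )
            except SimulationError:
                blocks.append(
                    np.full(ds.observations.size, _FAIL_RESIDUAL)
                )
                continue
            sim_at = traj.states.loc[ds.times]
            for col in ds.observations.columns:
                obs = ds.observations[col].to_numpy(float)
                w = 1.0 if self.weights is None else float(
                    self.weights.get(col, 1.0)
                )
                res = (sim_at[col].to_numpy() - obs) / norms[col]
                res = np.where(np.isnan(obs), 0.0, res)
                blocks.append(np.sqrt(w / n) * res)
        return np.concatenate(blocks)

    def objective(self, z: np.ndarray) -> float:
        r = self.residuals(z)
        return float(r @ r)

    def pooled_error(self, params: ParameterSet) -> tuple[float, dict[str, float]]:
        total = 0.0
        per_species: dict[str, float] = {}
        for ds, init in zip(self.datasets, self.initials):
            traj = simulate(
                self.network,
                params,
                initial=init,
                t_end=float(ds.times.max()),
                t_eval=ds.times,
                solver=self.solver,
            )
            errs, n = _species_errors(traj, ds, self.weights)
            total += sum(errs.values()) / n
            for col, e in errs.items():
                per_species[f"{ds.condition}:{col}"] = e / n
        return total, per_species


def _default_bounds(base: ParameterSet, free: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([base.bounds(n)[0] for n in free])
    hi = np.array([base.bounds(n)[1] for n in free])
    return lo, hi


def _fit(
    problem: _Problem,
    condition: str,
    n_restarts: int,
    seed: int,
    max_nfev: int | None,
    ftol: float,
    diff_step: float,
) -> CalibrationResult:
    base = problem.base
    free = problem.free
    lo, hi = _default_bounds(base, free)
    if np.any(lo <= 0):
        raise ValueError("parameter lower bounds must be positive (log-space fit)")
    z0 = np.log10([base[n] for n in free])
    zlo, zhi = np.log10(lo), np.log10(hi)
    rng = np.random.default_rng(seed)

    start_obj = problem.objective(z0)
    best_z, best_obj = z0, start_obj
    trace = [start_obj]
    for k in range(n_restarts):
        if k == 0:
            z_start = z0
        else:
            # log-uniform x[1/3, 3] perturbation around the nominal start
            z_start = np.clip(
                z0 + rng.uniform(np.log10(1 / 3), np.log10(3), size=len(free)),
                zlo,
                zhi,
            )
        result = least_squares(
            problem.residuals,
            np.clip(z_start, zlo, zhi),
            bounds=(zlo, zhi),
            method="trf",
            ftol=ftol,
            xtol=1e-10,
            # finite-difference step must clear the ODE solver's noise floor
            # (1e-2 in log10 space ~ 2.3% parameter change)
            diff_step=diff_step,
            max_nfev=max_nfev,
        )
        obj = float(result.fun @ result.fun)
        trace.append(obj)
        if obj < best_obj:
            best_obj, best_z = obj, result.x
    if best_obj >= start_obj and n_restarts > 0 and start_obj > 0:
        if not np.allclose(best_z, z0):
            warnings.warn(
                "no restart improved on the initial objective; "
                "returning the initial parameters"
            )
            best_z = z0

    fitted = problem.params_at(best_z).with_condition(condition)
    objective, per_species = problem.pooled_error(fitted)
    return CalibrationResult(
        params=fitted,
        objective=objective,
        per_species_error=per_species,
        trace=trace,
        seed=seed,
        n_restarts=n_restarts,
        free_names=list(free),
    )


def fit_stage1(
    network: MetabolicNetwork,
    datasets: Sequence[ExperimentDataset],
    initial_params: ParameterSet,
    free_names: Sequence[str] | None = None,
    weights: Mapping[str, float] | None = None,
    n_restarts: int = 8,
    seed: int = 0,
    solver: SolverSettings | None = None,
    max_nfev: int | None = None,
    ftol: float = 1e-8,
    diff_step: float = 1e-2,
) -> CalibrationResult:
    """Stage 1: pooled fit on both conditions' data simultaneously.

    Each condition is simulated from its own initial state; the objective is
    the sum of the two conditions' normalized errors.  ``free_names``
    defaults to every parameter.  Deterministic for a fixed seed.
    """
    if len(datasets) < 2:
        raise ValueError("stage 1 requires both condition datasets")
    free = list(free_names) if free_names is not None else initial_params.names
    missing = [n for n in free if n not in initial_params]
    if missing:
        raise KeyError(f"free parameters not in the parameter set: {missing}")
    problem = _Problem(
        network, datasets, initial_params, free, weights,
        solver or SolverSettings(),
    )
    return _fit(problem, "combined", n_restarts, seed, max_nfev, ftol, diff_step)


def fit_stage2(
    network: MetabolicNetwork,
    dataset: ExperimentDataset,
    stage1: CalibrationResult,
    free_names: Sequence[str],
    weights: Mapping[str, float] | None = None,
    n_restarts: int = 1,
    seed: int = 0,
    solver: SolverSettings | None = None,
    max_nfev: int | None = None,
    ftol: float = 1e-8,
    diff_step: float = 1e-2,
) -> CalibrationResult:
    """Stage 2: per-passage refit of the sensitive subset (+ vmaxresp).

    Only the listed parameters move; every other value is returned bitwise
    equal to its stage-1 estimate.
    """
    if not free_names:
        raise ValueError("stage 2 requires a non-empty free-parameter list")
    missing = [n for n in free_names if n not in getattr(stage1, "params", stage1)]
    if missing:
        raise KeyError(f"free parameters not in the stage-1 set: {missing}")
    base = getattr(stage1, "params", stage1)
    problem = _Problem(
        network, [dataset], base, list(free_names), weights,
        solver or SolverSettings(),
    )
    return _fit(problem, dataset.condition, n_restarts, seed, max_nfev, ftol, diff_step)


# ---------------------------------------------------------------------------
# fold-change report
# ---------------------------------------------------------------------------


def _fold_label(ratio: float) -> str:
    if abs(ratio - 1.0) <= IDEM_BAND:
        return "idem"
    if ratio >= 10:
        return f"{ratio:.0f}x"
    return f"{ratio:.1f}x"


def fold_change_report(result_p4, result_p9) -> pd.DataFrame:
    """P9-vs-P4 parameter ratios in the published table's style.

    Ratios within +/-15% of unity are classified ``idem``; larger changes
    are printed with one decimal below 10x and as integers above.
    Accepts :class:`CalibrationResult` or :class:`ParameterSet` inputs.
    """
    p4 = getattr(result_p4, "params", result_p4)
    p9 = getattr(result_p9, "params", result_p9)
    if set(p4.names) != set(p9.names):
        raise ValueError("parameter sets do not cover the same names")
    rows = []
    for name in p4.names:
        v4, v9 = p4[name], p9[name]
        ratio = v9 / v4 if v4 != 0 else np.inf
        rows.append(
            {
                "name": name,
                "value_P4": v4,
                "value_P9": v9,
                "ratio": ratio,
                "label": _fold_label(ratio),
            }
        )
    return pd.DataFrame(rows)
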