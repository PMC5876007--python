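"""Synthetic metabolomics datasets with the study's sampling design.

The study's raw measurements are not deposited, so testing the calibration
and sensitivity machinery needs data with the same structure: two passage
conditions sampled on their own schedules over 72 h from a common
inoculum, a fixed measured-species panel, and replicate noise.  The
generator forward-simulates a known ground-truth parameter set, samples
the trajectory on the schedule, applies multiplicative lognormal replicate
noise (unbiased in the mean), and records replicate means and SEMs for
n = 3 replicates, mirroring the study's error bars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import ExperimentDataset
from .network import MetabolicNetwork, ParameterSet, build_wjmsc_network
from .simulate import (
    CultureState,
    SolverSettings,
    default_initial_state,
    simulate,
)

__all__ = [
    "NoiseModel",
    "SCHEDULES",
    "generate_dataset",
    "make_paper_fixtures",
]

#: Sampling schedules (h): later passages were sampled more sparsely so
#: every sample still contained enough cells for metabolite quantification.
SCHEDULES = {
    "P4": (0.0, 12.0, 24.0, 32.0, 40.0, 48.0, 56.0, 64.0, 72.0),
    "P9": (0.0, 18.0, 27.0, 36.0, 45.0, 54.0, 63.0, 72.0),
}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal replicate noise, one CV per species class.

    Concentrations are positive and span decades, so noise scales with the
    signal; the lognormal factor is parameterized to have mean one
    (unbiased replicate means).  ``detection_floor`` censors values below
    a quantification limit to zero.
    """

    cv_intracellular: float = 0.05
    cv_extracellular: float = 0.03
    cv_counts: float = 0.10
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        for cv in (self.cv_intracellular, self.cv_extracellular, self.cv_counts):
            if cv < 0:
                raise ValueError("noise CVs must be non-negative")

    def cv_for(self, compartment: str) -> float:
        if compartment == "biomass":
            return self.cv_counts
        if compartment == "extracellular":
            return self.cv_extracellular
        return self.cv_intracellular

    def draw_factors(
        self, rng: np.random.Generator, cv: float, size
    ) -> np.ndarray:
        """Mean-one lognormal factors with coefficient of variation ``cv``."""
        if cv == 0.0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_dataset(
    network: MetabolicNetwork,
    true_params: ParameterSet,
    initial: CultureState | None = None,
    schedule: str | Sequence[float] = "P4",
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    condition: str | None = None,
    solver: SolverSettings | None = None,
    t_end: float | None = None,
) -> tuple[ExperimentDataset, pd.DataFrame]:
    """Simulate, sample on the schedule, add replicate noise, average.

    Returns the dataset (replicate means + SEMs) together with the exact
    noiseless sample table for oracle use.  Reproducible under ``seed``.
    """
    if isinstance(schedule, str):
        condition = condition or schedule
        times = np.asarray(SCHEDULES[schedule], dtype=float)
    else:
        times = np.asarray(schedule, dtype=float)
        condition = condition or "custom"
    if noise is None:
        noise = NoiseModel()
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if initial is None:
        initial = default_initial_state(network)
    horizon = float(t_end) if t_end is not None else float(times.max())
    if horizon < times.max():
        raise ValueError("schedule extends beyond the simulation horizon")

    traj = simulate(
        network,
        true_params,
        initial=initial,
        t_end=horizon,
        t_eval=times,
        solver=solver,
    )
    measured = ["X"] + network.measured_species()
    measured = list(dict.fromkeys(measured))
    truth = traj.states.loc[times, measured].copy()

    rng = np.random.default_rng(seed)
    means = {}
    sems = {}
    for col in measured:
        comp = (
            "biomass"
            if col == "X"
            else network.get_species(col).compartment
        )
        cv = noise.cv_for(comp)
        base = truth[col].to_numpy()
        if cv == 0.0 and noise.detection_floor == 0.0:
            # exact zero-noise path: replicate means equal the simulation
            # bitwise (no mean-of-identical-values rounding)
            means[col] = base.copy()
            sems[col] = np.zeros(base.size)
            continue
        reps = base[None, :] * noise.draw_factors(
            rng, cv, (n_replicates, base.size)
        )
        if noise.detection_floor > 0.0:
            reps = np.where(reps < noise.detection_floor, 0.0, reps)
        means[col] = reps.mean(axis=0)
        sems[col] = (
            reps.std(axis=0, ddof=1) / np.sqrt(n_replicates)
            if n_replicates > 1
            else np.zeros(base.size)
        )

    index = pd.Index(times, name="time")
    observations = pd.DataFrame(means, index=index)
    sem = pd.DataFrame(sems, index=index)
    dataset = ExperimentDataset(
        condition=condition,
        observations=observations,
        sem=sem,
        initial=initial.copy(),
        network=network,
        truth=truth,
    )
    return dataset, truth


def make_paper_fixtures(
    seed: int = 0,
    noise: NoiseModel | None = None,
    network: MetabolicNetwork | None = None,
    solver: SolverSettings | None = None,
) -> tuple[ExperimentDataset, ExperimentDataset]:
    """The packaged two-condition study emulation.

    P4-like and P9-like datasets generated from the published passage-
    specific parameter columns as ground truth, each on its own sampling
    schedule, from the common inoculum (0.0375 x 10^6 cells/mL).  Returns
    (P4 dataset, P9 dataset); the noiseless tables ride along on each
    dataset's ``truth`` attribute.
    """
    from .io_cli import default_parameter_set

    if network is None:
        network = build_wjmsc_network()
    ds = []
    for i, condition in enumerate(("P4", "P9")):
        params = default_parameter_set(network, condition)
        dataset, _ = generate_dataset(
            network,
            params,
            schedule=condition,
            noise=noise,
            seed=seed + i,
            condition=condition,
            solver=solver,
        )
        ds.append(dataset)
    return ds[0], ds[1]
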