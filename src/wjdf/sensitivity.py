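"""One-at-a-time (OAT) local sensitivity of the data-fit error.

Each parameter is perturbed multiplicatively by +/-15% (one at a time,
all others held fixed), the culture is re-simulated, and the global
simulation error is recomputed.  The summary score is the larger of the
two relative error changes (in percent); parameters scoring above the
10% threshold are classified sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import ExperimentDataset, _Problem
from .network import MetabolicNetwork, ParameterSet
from .simulate import SimulationError, SolverSettings

__all__ = ["SensitivityReport", "oat_sensitivity", "sensitive_set"]

log = logging.getLogger("wjdf")

#: Floor applied to the baseline error (relative scores need E0 > 0).
BASELINE_FLOOR = 1e-30


@dataclass
class SensitivityReport:
    """Per-parameter error changes under +/- perturbation.

    ``frame`` columns: name, score_up, score_down (percent error change in
    each direction; NaN if the perturbed simulation failed), score (the
    direction reduction), sensitive — sorted by score descending, ties
    alphabetical.
    """

    frame: pd.DataFrame
    baseline_error: float
    threshold: float
    perturbation: float
    reduction: str

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def __len__(self) -> int:
        return len(self.frame)


def oat_sensitivity(
    network: MetabolicNetwork,
    params: ParameterSet,
    datasets: Sequence[ExperimentDataset],
    threshold: float = 10.0,
    perturbation: float = 0.15,
    names: Sequence[str] | None = None,
    reduction: str = "max",
    solver: SolverSettings | None = None,
) -> SensitivityReport:
    """Score every parameter by its leverage on the pooled data-fit error.

    score_p = max(|E(p*(1+d)) - E0|, |E(p*(1-d)) - E0|) / E0 * 100
    with d the perturbation (default 15%); ``reduction="mean"`` averages
    the two directions instead.  Zero-valued parameters are perturbed
    additively by d times their bound span (multiplying zero is degenerate).
    A failed simulation leaves that direction NaN and is logged.
    """
    if reduction not in ("max", "mean"):
        raise ValueError("reduction must be 'max' or 'mean'")
    datasets = list(datasets)
    if isinstance(datasets[0], ExperimentDataset) is False:
        raise TypeError("datasets must be ExperimentDataset instances")
    names = list(names) if names is not None else params.names
    missing = [n for n in names if n not in params]
    if missing:
        raise KeyError(f"unknown parameters: {missing}")

    problem = _Problem(
        network, datasets, params, [], None, solver or SolverSettings()
    )
    e0, _ = problem.pooled_error(params)
    e0 = max(e0, BASELINE_FLOOR)

    rows = []
    for name in names:
        value = params[name]
        if value != 0.0:
            trials = (value * (1 + perturbation), value * (1 - perturbation))
        else:
            lo, hi = params.bounds(name)
            span = hi - lo if np.isfinite(hi - lo) else 1.0
            log.info(
                "parameter %s is zero; perturbing additively by %g",
                name, perturbation * span,
            )
            trials = (perturbation * span, -perturbation * span)
        changes = []
        for trial in trials:
            try:
                e, _ = problem.pooled_error(params.with_values({name: trial}))
                changes.append(abs(e - e0) / e0 * 100.0)
            except (SimulationError, ValueError) as exc:
                log.warning("sensitivity of %s at %g failed: %s", name, trial, exc)
                changes.append(np.nan)
        up, down = changes
        finite = [c for c in changes if np.isfinite(c)]
        if not finite:
            score = np.nan
        elif reduction == "max":
            score = max(finite)
        else:
            score = float(np.mean(finite))
        rows.append(
            {
                "name": name,
                "score_up": up,
                "score_down": down,
                "score": score,
                "sensitive": bool(np.isfinite(score) and score > threshold),
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["score", "name"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return SensitivityReport(
        frame=frame,
        baseline_error=e0,
        threshold=threshold,
        perturbation=perturbation,
        reduction=reduction,
    )


def sensitive_set(report: SensitivityReport) -> list[str]:
    """Names classified sensitive, by score descending (ties alphabetical)."""
    frame = report.frame
    sel = frame[frame["sensitive"].astype(bool)]
    return list(sel["name"])
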