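"""Metabolic-biomarker analytics derived from trajectories and count data.

The passage-effect biomarkers of the study system: growth metrics
(specific growth rate, doubling time), the glycolytic split at the
pyruvate node (lactate vs TCA vs PPP), the pentose-phosphate branch
partition, ATP turnover and its origin (glycolysis / TCA / oxidative
phosphorylation), adenylate ratios, and the two-sample t helper used for
the mixed-lymphocyte-reaction comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import ExperimentDataset
from .simulate import Trajectory

__all__ = [
    "FluxPartition",
    "GrowthSummary",
    "TTestResult",
    "specific_growth_rate_from_counts",
    "doubling_time",
    "growth_summary",
    "glycolysis_partition",
    "ppp_partition",
    "atp_turnover",
    "nucleotide_ratios",
    "mlr_t_statistic",
    "biomarker_report",
]

#: ATP-recycling reaction groups used in the turnover decomposition.  SDH's
#: direct contribution is counted with the TCA group (not with oxidative
#: phosphorylation), matching the study's accounting; adenylate-kinase and
#: creatine-kinase buffering is interconversion, not turnover, and is
#: excluded.
ATP_GROUPS = {
    "glycolysis": ("PGK", "PK"),
    "tca": ("SCOAS", "SDH"),
    "oxphos": ("resp",),
}


@dataclass
class FluxPartition:
    """Fractions of a flux split at one network node over time.

    Fractions sum to one at every time point where the denominator is
    nonzero; times with a zero denominator carry NaN rows.
    """

    node: str
    fractions: pd.DataFrame  # index time, one column per branch label

    @property
    def labels(self) -> list[str]:
        return list(self.fractions.columns)

    def at(self, t: float) -> pd.Series:
        i = int(np.argmin(np.abs(self.fractions.index.to_numpy() - t)))
        return self.fractions.iloc[i]


@dataclass(frozen=True)
class GrowthSummary:
    mu_avg: float  # 1/h
    doubling_time: float  # h
    x0: float
    xT: float
    window: tuple[float, float]  # h


class TTestResult(NamedTuple):
    t: float
    df: int
    critical: float  # one-sided 95% Student's t reference value


def specific_growth_rate_from_counts(x0: float, xT: float, t: float) -> float:
    """Average specific growth rate mu = ln(xT/x0)/t (1/h)."""
    if x0 <= 0 or xT <= 0:
        raise ValueError("cell densities must be positive")
    if t <= 0:
        raise ValueError("elapsed time must be positive")
    return float(np.log(xT / x0) / t)


def doubling_time(mu: float) -> float:
    """Population doubling time ln(2)/mu (h)."""
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    return float(np.log(2.0) / mu)


def growth_summary(
    x0: float, xT: float, window: tuple[float, float]
) -> GrowthSummary:
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window start must precede window end")
    mu = specific_growth_rate_from_counts(x0, xT, t1 - t0)
    return GrowthSummary(
        mu_avg=mu,
        doubling_time=doubling_time(mu),
        x0=x0,
        xT=xT,
        window=window,
    )


def _partition(node: str, parts: dict[str, np.ndarray], index) -> FluxPartition:
    frame = pd.DataFrame(parts, index=index)
    denom = frame.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = frame.div(denom, axis=0)
    frac[denom == 0.0] = np.nan
    return FluxPartition(node=node, fractions=frac)


def glycolysis_partition(traj: Trajectory) -> FluxPartition:
    """Split of the glycolytic flux at the G6P/pyruvate node.

    Fractions of LDH (lactate), PDH (TCA feed) and G6PDH (PPP feed) in
    their sum, per time point — the three branches are plotted as one
    stacked distribution in the study's figures, so all three share one
    denominator.
    """
    f = traj.fluxes
    for rid in ("LDH", "PDH", "G6PDH"):
        if rid not in f.columns:
            raise KeyError(f"trajectory lacks required flux {rid!r}")
    return _partition(
        "pyruvate_node",
        {
            "lactate": f["LDH"].to_numpy(),
            "tca": f["PDH"].to_numpy(),
            "ppp": f["G6PDH"].to_numpy(),
        },
        f.index,
    )


def ppp_partition(traj: Trajectory) -> FluxPartition:
    """Destinations of the pentose-phosphate flux downstream of G6PDH.

    The R5P produced by the oxidative branch either returns to glycolysis
    (transketolase), is drained into biomass by growth, or feeds nucleotide
    synthesis (PPRibP and NAT); fractions are of the summed sink flux,
    weighted by each sink's R5P stoichiometry.
    """
    f = traj.fluxes
    network = traj.diagnostics["network"]

    def r5p_drain(rid: str) -> np.ndarray:
        coeff = network.reaction(rid).stoichiometry.get("R5P", 0.0)
        if isinstance(coeff, str):  # parametric coefficient: weight by 1
            coeff = -1.0
        return abs(float(coeff)) * f[rid].to_numpy()

    for rid in ("G6PDH", "TK", "PPRibP", "NAT"):
        if rid not in f.columns:
            raise KeyError(f"trajectory lacks required flux {rid!r}")
    growth_id = network.growth_reaction.id
    return _partition(
        "ppp_node",
        {
            "return_to_glycolysis": r5p_drain("TK"),
            "cell_synthesis": r5p_drain(growth_id),
            "nucleotide_synthesis": r5p_drain("PPRibP") + r5p_drain("NAT"),
        },
        f.index,
    )


def atp_turnover(traj: Trajectory) -> tuple[pd.Series, FluxPartition]:
    """Total ATP turnover rate and its origin decomposition.

    Total = sum over the recycling groups (glycolysis PGK+PK, TCA
    SCOAS+SDH, oxidative phosphorylation) of ATP stoichiometry x flux,
    mmol/1e6 cells/h; the partition gives each group's fraction.  The
    total equals the sum of the partition components by construction.
    """
    f = traj.fluxes
    network = traj.diagnostics["network"]
    parts = {}
    for group, rids in ATP_GROUPS.items():
        contrib = np.zeros(len(f))
        for rid in rids:
            if rid not in f.columns:
                raise KeyError(f"trajectory lacks required flux {rid!r}")
            coeff = float(network.reaction(rid).stoichiometry.get("ATP", 0.0))
            if coeff <= 0:
                raise ValueError(f"reaction {rid!r} does not produce ATP")
            contrib = contrib + coeff * f[rid].to_numpy()
        parts[group] = contrib
    total = pd.Series(
        sum(parts.values()), index=f.index, name="atp_turnover"
    )
    return total, _partition("atp", parts, f.index)


def nucleotide_ratios(data) -> pd.DataFrame:
    """ATP/ADP and AMP/ATP ratio series.

    Accepts a :class:`Trajectory`, an :class:`ExperimentDataset` or any
    DataFrame with ATP, ADP and AMP columns.  Zero denominators propagate
    as missing values (with a warning); NaN inputs propagate.
    """
    if isinstance(data, Trajectory):
        frame = data.states
    elif isinstance(data, ExperimentDataset):
        frame = data.observations
    else:
        frame = data
    for col in ("ATP", "ADP", "AMP"):
        if col not in frame.columns:
            raise KeyError(f"adenylate column {col!r} missing")
    atp = frame["ATP"].to_numpy(dtype=float)
    adp = frame["ADP"].to_numpy(dtype=float)
    amp = frame["AMP"].to_numpy(dtype=float)
    if np.any(adp == 0.0) or np.any(atp == 0.0):
        warnings.warn("zero adenylate denominators; ratios set to NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        atp_adp = np.where(adp != 0.0, atp / adp, np.nan)
        amp_atp = np.where(atp != 0.0, amp / atp, np.nan)
    return pd.DataFrame(
        {"atp_adp": atp_adp, "amp_atp": amp_atp}, index=frame.index
    )


def mlr_t_statistic(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TTestResult:
    """Two-sample pooled-variance Student's t with its one-sided 95% reference.

    Returns (t, df, critical) with df = n_a + n_b - 2 and the critical value
    the 95th percentile of Student's t at that df.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    denom = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    t = 0.0 if denom == 0.0 else float((a.mean() - b.mean()) / denom)
    critical = float(stats.t.ppf(0.95, df))
    return TTestResult(t=t, df=df, critical=critical)


def biomarker_report(
    traj: Trajectory,
    condition: str,
    times: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Tidy per-condition biomarker table (biomarker, time, value).

    Summarizes the growth metrics over the trajectory window plus the flux
    partitions, ATP turnover and adenylate ratios at the requested times
    (default: the trajectory grid ends).
    """
    x = traj.states["X"]
    t0, t1 = float(traj.time[0]), float(traj.time[-1])
    summary = growth_summary(float(x.iloc[0]), float(x.iloc[-1]), (t0, t1))
    rows = [
        {"condition": condition, "biomarker": "mu_avg", "time": t1,
         "value": summary.mu_avg},
        {"condition": condition, "biomarker": "doubling_time", "time": t1,
         "value": summary.doubling_time},
    ]
    times = list(times) if times is not None else [t0, t1]
    glyc = glycolysis_partition(traj)
    ppp = ppp_partition(traj)
    total, atp = atp_turnover(traj)
    ratios = nucleotide_ratios(traj)
    for t in times:
        for label, value in glyc.at(t).items():
            rows.append(
                {"condition": condition, "biomarker": f"glycolysis_{label}",
                 "time": t, "value": value}
            )
        for label, value in ppp.at(t).items():
            rows.append(
                {"condition": condition, "biomarker": f"ppp_{label}",
                 "time": t, "value": value}
            )
        for label, value in atp.at(t).items():
            rows.append(
                {"condition": condition, "biomarker": f"atp_{label}",
                 "time": t, "value": value}
            )
        i = int(np.argmin(np.abs(traj.time - t)))
        rows.append(
            {"condition": condition, "biomarker": "atp_turnover", "time": t,
             "value": float(total.iloc[i])}
        )
        for col in ("atp_adp", "amp_atp"):
            rows.append(
                {"condition": condition, "biomarker": col, "time": t,
                 "value": float(ratios[col].iloc[i])}
            )
    return pd.DataFrame(rows)
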