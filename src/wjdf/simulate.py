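"""ODE simulation of a WJMSC batch culture.

State vector: cell density X (10^6 cells/mL) followed by every species
concentration in network order.  Balances:

* biomass                dX/dt   = mu * X
* intracellular species  dc_i/dt = sum_r nu_ri * v_r  -  mu * c_i
  (specific fluxes, with dilution of the intracellular content by growth)
* extracellular species  dc_e/dt = 1000 * X * sum_r nu_re * v_r
  (mmol/1e6 cells/h times 1e6 cells/mL needs the mL -> L factor of 1000
  to come out in mM/h)

The growth reaction's "flux" is mu itself (1/h); its stoichiometric
coefficients are the biomass precursor demands in mmol per 10^6 cells.
Concentrations are clipped at zero inside the right-hand side, which keeps
the integrator robust for the exploratory parameter vectors the optimizer
tries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    MetabolicNetwork,
    ParameterSet,
    growth_rate,
    reaction_flux,
)

__all__ = [
    "CultureState",
    "Scenario",
    "SolverSettings",
    "Trajectory",
    "SimulationError",
    "default_initial_state",
    "ode_rhs",
    "simulate",
    "specific_growth_rate_series",
]

#: Inoculation density reported for both passages, 10^6 cells/mL.
INOCULUM = 0.0375

#: Default starting medium (mM): glucose/amino-acid levels of an
#: alpha-MEM + 20% FBS formulation.  Fixture values, freely overridable.
DEFAULT_MEDIUM = {
    "EGLC": 5.5,
    "ELAC": 0.5,
    "EGLN": 2.0,
    "EGLU": 0.05,
    "EALA": 0.05,
    "ESER": 0.25,
    "EGLY": 0.25,
    "EASN": 0.05,
    "EASP": 0.03,
    "EILE": 0.3,
    "ELEU": 0.3,
    "ELYS": 0.4,
    "ETYR": 0.2,
    "EVAL": 0.4,
    "EHIS": 0.2,
    "EARG": 0.6,
    "ETRP": 0.049,
    "EUREA": 0.0,
    "ENO": 0.0,
    "EKYN": 0.0,
}

#: Default intracellular pools (mmol/1e6 cells), set at the measured or
#: simulated concentration scales of the study system.
DEFAULT_POOLS = {
    "G6P": 3.0e-7,
    "F6P": 2.0e-7,
    "GAP": 1.0e-7,
    "PEP": 2.0e-7,
    "PYR": 2.0e-7,
    "R5P": 5.0e-7,
    "ACCOA": 1.0e-7,
    "CIT": 2.0e-7,
    "AKG": 8.6e-8,
    "SCOA": 1.0e-7,
    "SUC": 3.3e-7,
    "FUM": 1.5e-7,
    "MAL": 3.0e-7,
    "OXA": 5.0e-8,
    "ATP": 2.5e-6,
    "ADP": 8.0e-7,
    "AMP": 5.0e-7,
    "NAD": 1.0e-6,
    "NADH": 2.0e-7,
    "NADP": 5.0e-7,
    "NADPH": 5.0e-7,
    "CR": 1.0e-6,
    "PCR": 1.0e-6,
    "GLN": 1.0e-6,
    "GLU": 2.0e-6,
    "ALA": 5.0e-7,
    "SER": 5.0e-7,
    "GLY": 5.0e-7,
    "ASN": 2.0e-7,
    "ASP": 5.0e-7,
    "ARG": 3.0e-7,
    "ORN": 2.0e-7,
    "CTR": 1.0e-7,
    "ASUC": 5.0e-8,
}


class SimulationError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class CultureState:
    """Cell density plus all concentrations at one time."""

    t: float
    X: float
    c_ext: dict[str, float]
    c_int: dict[str, float]

    def concentrations(self) -> dict[str, float]:
        return {**self.c_ext, **self.c_int}

    def copy(self) -> "CultureState":
        return CultureState(self.t, self.X, dict(self.c_ext), dict(self.c_int))


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-6
    atol: float = 1e-12
    method: str = "LSODA"
    max_step: float = np.inf


@dataclass
class Scenario:
    """Initial state, horizon and output grid for one culture simulation."""

    initial: CultureState
    t_end: float = 72.0
    t_eval: Sequence[float] | None = None
    solver: SolverSettings = field(default_factory=SolverSettings)


def default_initial_state(
    network: MetabolicNetwork,
    inoculum: float = INOCULUM,
    medium: Mapping[str, float] | None = None,
    pools: Mapping[str, float] | None = None,
) -> CultureState:
    """Inoculated default scenario start: fresh medium, reference pools."""
    med = dict(DEFAULT_MEDIUM)
    med.update(medium or {})
    pool = dict(DEFAULT_POOLS)
    pool.update(pools or {})
    c_ext, c_int = {}, {}
    for s in network.species:
        if s.compartment == "extracellular":
            c_ext[s.id] = float(med.get(s.id, 0.0))
        elif s.compartment == "intracellular":
            c_int[s.id] = float(pool.get(s.id, 0.0))
    return CultureState(t=0.0, X=inoculum, c_ext=c_ext, c_int=c_int)


# ---------------------------------------------------------------------------
# compiled network: index arrays for a vectorized right-hand side
# ---------------------------------------------------------------------------


class _Compiled:
    """Network + parameters flattened to numpy arrays.

    Fluxes for all reactions are evaluated in one vectorized sweep: every
    (substrate, Km) term of every reaction lives in one flat array, and
    ``np.multiply.reduceat`` folds the saturation terms back per reaction.
    """

    def __init__(self, network: MetabolicNetwork, params: ParameterSet):
        self.network = network
        self.species_index = {s.id: i for i, s in enumerate(network.species)}
        n_spec = len(network.species)
        n_rxn = len(network.reactions)

        term_species: list[int] = []
        term_km: list[float] = []
        offsets: list[int] = []
        vmax = np.empty(n_rxn)
        reg = []  # (rxn index, alpha, beta)
        growth_idx = -1
        S = np.zeros((n_spec, n_rxn))
        n_terms_total = sum(
            len(r.rate_law.substrate_terms) for r in network.reactions
        )
        for j, r in enumerate(network.reactions):
            # substrate-free rate laws read the sentinel slot appended in
            # :meth:`fluxes`
            offsets.append(
                len(term_species)
                if r.rate_law.substrate_terms
                else n_terms_total
            )
            law = r.rate_law
            vmax[j] = params[law.vmax]
            for sid, km_name in law.substrate_terms:
                term_species.append(self.species_index[sid])
                term_km.append(params[km_name])
            if law.regulation is not None:
                reg.append((j, params[law.regulation[0]], params[law.regulation[1]]))
            if law.kind == "growth":
                growth_idx = j
            for sid, coeff in r.resolved_stoichiometry(params).items():
                S[self.species_index[sid], j] = coeff

        self.term_species = np.asarray(term_species, dtype=np.intp)
        self.term_km = np.asarray(term_km)
        self.offsets = np.asarray(offsets, dtype=np.intp)
        self.vmax = vmax
        self.reg = reg
        self.growth_idx = growth_idx
        if growth_idx < 0:
            raise ValueError("network has no growth reaction")

        bio = self.species_index[network.biomass_species.id]
        self.bio_idx = bio
        ext = np.array(
            [s.compartment == "extracellular" for s in network.species]
        )
        intra = np.array(
            [s.compartment == "intracellular" for s in network.species]
        )
        self.ext_mask = ext
        self.int_mask = intra
        self.S = S
        self.amp_idx = self.species_index.get("AMP", -1)
        self.atp_idx = self.species_index.get("ATP", -1)

    def fluxes(self, conc: np.ndarray) -> np.ndarray:
        """Specific fluxes of every reaction at one concentration vector."""
        terms = conc[self.term_species]
        terms = terms / (self.term_km + terms)
        # trailing sentinel 1.0: reactions without substrate terms (a
        # substrate-free growth law) point their offset here and reduce to 1
        terms = np.append(terms, 1.0)
        v = self.vmax * np.multiply.reduceat(terms, self.offsets)
        for j, alpha, beta in self.reg:
            atp = conc[self.atp_idx]
            if atp <= 0.0:
                v[j] = 0.0
                continue
            r = conc[self.amp_idx] / atp
            v[j] *= (1.0 + r / alpha) / (1.0 + r / beta)
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        y = np.maximum(y, 0.0)
        x = y[self.bio_idx]
        v = self.fluxes(y)
        mu = v[self.growth_idx]
        dy = self.S @ v
        dy[self.ext_mask] *= 1000.0 * x
        dy[self.int_mask] -= mu * y[self.int_mask]
        dy[self.bio_idx] = mu * x
        return dy


def _state_to_vector(comp: _Compiled, state: CultureState) -> np.ndarray:
    y = np.zeros(len(comp.network.species))
    y[comp.bio_idx] = state.X
    for sid, c in state.concentrations().items():
        y[comp.species_index[sid]] = c
    return y


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def ode_rhs(
    state: CultureState,
    network: MetabolicNetwork,
    params: ParameterSet,
) -> dict[str, float]:
    """Time derivatives of cell density and every concentration.

    Reference (dictionary) form of the system right-hand side; the
    integrator uses the equivalent vectorized path internally.
    """
    conc = {k: max(c, 0.0) for k, c in state.concentrations().items()}
    mu = growth_rate(conc, params, network)
    x = max(state.X, 0.0)
    deriv: dict[str, float] = {s.id: 0.0 for s in network.species}
    for r in network.reactions:
        v = reaction_flux(network, r.id, conc, params)
        for sid, coeff in r.resolved_stoichiometry(params).items():
            deriv[sid] += coeff * v
    bio = network.biomass_species.id
    for s in network.species:
        if s.compartment == "extracellular":
            deriv[s.id] *= 1000.0 * x
        elif s.compartment == "intracellular":
            deriv[s.id] -= mu * conc[s.id]
    deriv[bio] = mu * x
    return deriv


@dataclass
class Trajectory:
    """One simulation: states, specific fluxes and growth rate over time."""

    time: np.ndarray
    states: pd.DataFrame  # index time, columns X + species
    fluxes: pd.DataFrame  # index time, columns reaction ids
    mu: pd.Series  # specific growth rate, 1/h
    diagnostics: dict = field(default_factory=dict)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.fluxes.columns)

    def state_at(self, t: float) -> CultureState:
        network: MetabolicNetwork = self.diagnostics["network"]
        i = int(np.argmin(np.abs(self.time - t)))
        row = self.states.iloc[i]
        c_ext = {
            s.id: float(row[s.id])
            for s in network.species
            if s.compartment == "extracellular"
        }
        c_int = {
            s.id: float(row[s.id])
            for s in network.species
            if s.compartment == "intracellular"
        }
        return CultureState(
            t=float(self.time[i]), X=float(row["X"]), c_ext=c_ext, c_int=c_int
        )

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (time, variable, value, kind) table for writers."""
        frames = []
        st = self.states.reset_index().melt(id_vars="time", var_name="variable")
        st["kind"] = "state"
        frames.append(st)
        fl = self.fluxes.reset_index().melt(id_vars="time", var_name="variable")
        fl["kind"] = "flux"
        frames.append(fl)
        mu = pd.DataFrame(
            {"time": self.time, "variable": "mu", "value": self.mu.values,
             "kind": "mu"}
        )
        frames.append(mu)
        return pd.concat(frames, ignore_index=True)


def simulate(
    network: MetabolicNetwork,
    params: ParameterSet,
    initial: CultureState | None = None,
    t_end: float = 72.0,
    t_eval: Sequence[float] | None = None,
    solver: SolverSettings | None = None,
) -> Trajectory:
    """Integrate the culture ODE system and return the full trajectory.

    Deterministic: identical inputs and solver settings give identical
    trajectories.  Raises :class:`SimulationError` on integrator failure.
    """
    if initial is None:
        initial = default_initial_state(network)
    solver = solver or SolverSettings()
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 145)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size and t_end < t_eval.max():
        raise ValueError("t_end must cover the evaluation grid")

    comp = _Compiled(network, params)
    y0 = _state_to_vector(comp, initial)
    sol = solve_ivp(
        comp.rhs,
        (0.0, float(t_end)),
        y0,
        method=solver.method,
        t_eval=t_eval,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else None
        raise SimulationError(
            f"ODE solver failed: {sol.message} (last time {last})", last
        )

    y = np.maximum(sol.y, 0.0)  # solver contract: concentrations >= 0
    cols = [s.id for s in network.species]
    states = pd.DataFrame(y.T, columns=cols)
    states.insert(0, "X", states.pop(network.biomass_species.id))
    states.index = pd.Index(sol.t, name="time")

    flux = np.empty((len(sol.t), len(network.reactions)))
    for i in range(len(sol.t)):
        flux[i] = comp.fluxes(y[:, i])
    fluxes = pd.DataFrame(
        flux, columns=list(network.reaction_ids), index=states.index
    )
    mu = fluxes[network.growth_reaction.id].rename("mu")

    return Trajectory(
        time=sol.t,
        states=states,
        fluxes=fluxes,
        mu=mu,
        diagnostics={
            "network": network,
            "n_rhs_evals": int(sol.nfev),
            "solver": solver,
            "condition": params.condition,
        },
    )


def specific_growth_rate_series(traj: Trajectory) -> pd.Series:
    """mu(t) along a trajectory (1/h), as stored at simulation time."""
    return traj.mu
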