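"""Kinetic metabolic network for Wharton's Jelly MSC cultures.

The model describes central carbon metabolism (glycolysis, pentose phosphate
pathway, TCA cycle), cell energetics (oxidative phosphorylation, adenylate
kinase, creatine kinase, NAD(P) synthesis), the urea cycle, tryptophan/IDO
catabolism and lumped amino-acid reactions, plus one biomass (growth)
reaction.  The network itself is data: species, reactions with signed
stoichiometry, and a rate-law specification per reaction.  Rate laws are
irreversible multiplicative Michaelis-Menten terms, optionally scaled by a
dimensionless AMP/ATP regulation factor (hexokinase and lactate
dehydrogenase carry one).

Unit conventions (used consistently across the package):

* extracellular concentrations      mM
* intracellular concentrations      mmol per 10^6 cells
* cell density                      10^6 cells per mL
* specific reaction fluxes          mmol per 10^6 cells per h
* specific growth rate              1/h
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Species",
    "RateLawSpec",
    "Reaction",
    "MetabolicNetwork",
    "ParameterValue",
    "ParameterSet",
    "NetworkValidationError",
    "build_wjmsc_network",
    "default_network_path",
    "mm_term",
    "regulation_factor",
    "reaction_flux",
    "growth_rate",
]

COMPARTMENTS = ("extracellular", "intracellular", "biomass")

COMPARTMENT_UNITS = {
    "extracellular": "mM",
    "intracellular": "mmol/1e6 cells",
    "biomass": "1e6 cells/mL",
}

PATHWAY_TAGS = (
    "glycolysis",
    "ppp",
    "tca",
    "urea",
    "trp",
    "aa",
    "energetics",
    "transport",
    "growth",
)

RATE_LAW_KINDS = (
    "multi_substrate_mm",
    "mm_with_amp_atp_regulation",
    "growth",
    "respiration",
)

#: Biomass molar weight, gDW per 10^6 cells.
BIOMASS_MOLAR_WEIGHT = 3.15e-4
#: Mean protein residue weight, g/mol.
PROTEIN_RESIDUE_WEIGHT = 107.5

#: Biosynthetic precursor of each macromolecule class.
PRECURSOR_MAP = {"glycogen": "G6P", "lipids": "CIT", "nucleotides": "R5P"}


class NetworkValidationError(ValueError):
    """Raised when a network file violates the schema or its invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    """One chemical species (or the biomass pseudo-species)."""

    id: str
    compartment: str
    measured: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkValidationError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}"
            )

    @property
    def units(self) -> str:
        return COMPARTMENT_UNITS[self.compartment]


@dataclass(frozen=True)
class RateLawSpec:
    """Kinetic form of one reaction.

    ``substrate_terms`` pairs a species id with the name of its
    half-saturation (Km) parameter; the flux is the product of one saturation
    term per pair, times ``vmax``, times the AMP/ATP regulation factor when
    ``regulation`` names an (alpha, beta) parameter pair.
    """

    kind: str
    vmax: str
    substrate_terms: tuple[tuple[str, str], ...] = ()
    regulation: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in RATE_LAW_KINDS:
            raise NetworkValidationError(f"unknown rate-law kind {self.kind!r}")
        if self.kind != "growth" and not self.substrate_terms:
            raise NetworkValidationError(
                "non-growth rate law needs at least one substrate term"
            )

    def parameter_names(self) -> tuple[str, ...]:
        names = [self.vmax] + [km for _, km in self.substrate_terms]
        if self.regulation is not None:
            names.extend(self.regulation)
        return tuple(names)


@dataclass(frozen=True)
class Reaction:
    """One reaction: signed stoichiometry plus a rate law and a pathway tag.

    Stoichiometric coefficients are floats, except that a coefficient may be
    the name of a parameter (optionally prefixed with ``-``), in which case it
    is resolved against the :class:`ParameterSet` in use; the growth
    reaction's ATP cost (``vgrowthATP``/``vgrowthADP``) uses this.
    """

    id: str
    stoichiometry: Mapping[str, float | str]
    rate_law: RateLawSpec
    pathway_tag: str

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.pathway_tag not in PATHWAY_TAGS:
            raise NetworkValidationError(
                f"reaction {self.id!r}: unknown pathway tag {self.pathway_tag!r}"
            )

    def stoich_parameter_names(self) -> tuple[str, ...]:
        return tuple(
            str(v).lstrip("+-")
            for v in self.stoichiometry.values()
            if isinstance(v, str)
        )

    def resolved_stoichiometry(self, params: "ParameterSet") -> dict[str, float]:
        out: dict[str, float] = {}
        for sid, coeff in self.stoichiometry.items():
            if isinstance(coeff, str):
                sign = -1.0 if coeff.startswith("-") else 1.0
                out[sid] = sign * params[coeff.lstrip("+-")]
            else:
                out[sid] = float(coeff)
        return out


@dataclass(frozen=True)
class ParameterValue:
    value: float
    units: str = ""
    lower: float = 0.0
    upper: float = math.inf
    sensitive: bool = False


class ParameterSet:
    """Named kinetic constants for one condition (P4, P9 or combined).

    Behaves as a read-only mapping from parameter name to value;
    :meth:`with_values` returns an updated copy (parameter sets are treated
    as immutable by the calibration code).
    """

    def __init__(
        self,
        values: Mapping[str, ParameterValue],
        condition: str = "combined",
    ) -> None:
        self.condition = condition
        self._values = dict(values)
        for name, pv in self._values.items():
            if not (pv.lower <= pv.value <= pv.upper):
                raise ValueError(
                    f"parameter {name!r}: value {pv.value} outside bounds "
                    f"[{pv.lower}, {pv.upper}]"
                )

    # -- mapping protocol ---------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._values[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ParameterSet)
            and self.condition == other.condition
            and self._values == other._values
        )

    @property
    def names(self) -> list[str]:
        return list(self._values)

    def record(self, name: str) -> ParameterValue:
        return self._values[name]

    def bounds(self, name: str) -> tuple[float, float]:
        pv = self._values[name]
        return pv.lower, pv.upper

    def sensitive_names(self) -> list[str]:
        return [n for n, pv in self._values.items() if pv.sensitive]

    def with_values(
        self, updates: Mapping[str, float], condition: str | None = None
    ) -> "ParameterSet":
        values = dict(self._values)
        for name, value in updates.items():
            if name not in values:
                raise KeyError(f"unknown parameter {name!r}")
            values[name] = replace(values[name], value=float(value))
        return ParameterSet(values, condition or self.condition)

    def with_condition(self, condition: str) -> "ParameterSet":
        return ParameterSet(self._values, condition)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": n,
                "units": pv.units,
                "value": pv.value,
                "lower": pv.lower,
                "upper": pv.upper,
                "sensitive": pv.sensitive,
            }
            for n, pv in self._values.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MetabolicNetwork:
    """Validated reaction network plus biomass constants."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    biomass_molar_weight: float = BIOMASS_MOLAR_WEIGHT
    protein_residue_weight: float = PROTEIN_RESIDUE_WEIGHT
    precursor_map: Mapping[str, str] = field(
        default_factory=lambda: dict(PRECURSOR_MAP)
    )

    # -- lookups ------------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(f"unknown species {sid!r}")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    def reactions_by_pathway(self, tag: str) -> list[Reaction]:
        return [r for r in self.reactions if r.pathway_tag == tag]

    @property
    def growth_reaction(self) -> Reaction:
        for r in self.reactions:
            if r.rate_law.kind == "growth":
                return r
        raise NetworkValidationError("network has no growth reaction")

    @property
    def biomass_species(self) -> Species:
        bio = [s for s in self.species if s.compartment == "biomass"]
        if len(bio) != 1:
            raise NetworkValidationError("network must have exactly one biomass species")
        return bio[0]

    def measured_species(self) -> list[str]:
        return [s.id for s in self.species if s.measured]

    def parameter_names(self) -> list[str]:
        """All parameter names referenced by rate laws and stoichiometry."""
        names: list[str] = []
        for r in self.reactions:
            names.extend(r.rate_law.parameter_names())
            names.extend(r.stoich_parameter_names())
        return names

    def stoichiometric_matrix(self, params: ParameterSet) -> pd.DataFrame:
        """Species x reaction matrix with parametric coefficients resolved."""
        mat = pd.DataFrame(
            0.0, index=self.species_ids, columns=self.reaction_ids
        )
        for r in self.reactions:
            for sid, coeff in r.resolved_stoichiometry(params).items():
                mat.loc[sid, r.id] = coeff
        return mat

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        sids = self.species_ids
        if len(set(sids)) != len(sids):
            dupes = sorted({s for s in sids if sids.count(s) > 1})
            raise NetworkValidationError(f"duplicate species ids: {dupes}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise NetworkValidationError(f"duplicate reaction ids: {dupes}")
        self.biomass_species
        known = set(sids)
        for r in self.reactions:
            for sid in r.stoichiometry:
                if sid not in known:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references undeclared species {sid!r}"
                    )
            for sid, _ in r.rate_law.substrate_terms:
                if sid not in known:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} rate law references undeclared "
                        f"species {sid!r}"
                    )
        self.growth_reaction
        self._check_connectivity()

    def _check_connectivity(self) -> None:
        """EGLC must reach ELAC and a TCA intermediate through reactions."""
        if "EGLC" not in self.species_ids:
            return  # toy networks are exempt from the connectivity audit
        adjacency: dict[str, set[str]] = {}
        for r in self.reactions:
            signs = {
                s: (-1.0 if str(c).startswith("-") else 1.0)
                for s, c in r.stoichiometry.items()
            }
            consumed = [s for s, sign in signs.items() if sign < 0]
            produced = [s for s, sign in signs.items() if sign > 0]
            for src in consumed:
                adjacency.setdefault(src, set()).update(produced)
        seen = {"EGLC"}
        stack = ["EGLC"]
        while stack:
            for nxt in adjacency.get(stack.pop(), ()):  # pragma: no branch
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        tca = {"CIT", "AKG", "SCOA", "SUC", "FUM", "MAL", "OXA"}
        if "ELAC" not in seen or not (tca & seen):
            raise NetworkValidationError(
                "network is not connected from EGLC to ELAC and the TCA cycle"
            )

    def audit_parameters(self, params: ParameterSet) -> None:
        """Check the one-to-one map between parameters and rate laws.

        Every parameter must be referenced by exactly one reaction, and every
        referenced name must exist in ``params``.
        """
        owner: dict[str, str] = {}
        for r in self.reactions:
            for name in (*r.rate_law.parameter_names(), *r.stoich_parameter_names()):
                if name in owner and owner[name] != r.id:
                    raise NetworkValidationError(
                        f"parameter {name!r} referenced by both "
                        f"{owner[name]!r} and {r.id!r}"
                    )
                owner[name] = r.id
        missing = sorted(set(owner) - set(params.names))
        if missing:
            raise NetworkValidationError(
                f"parameters referenced but not defined: {missing}"
            )
        unreferenced = sorted(set(params.names) - set(owner))
        if unreferenced:
            raise NetworkValidationError(
                f"parameters defined but referenced by no reaction: {unreferenced}"
            )


# ---------------------------------------------------------------------------
# rate-law primitives
# ---------------------------------------------------------------------------


def mm_term(concentration: float, km: float) -> float:
    """Michaelis-Menten saturation factor c/(Km + c), in [0, 1)."""
    if km <= 0:
        raise ValueError(f"Km must be positive, got {km}")
    if concentration < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration}")
    return concentration / (km + concentration)


def regulation_factor(amp: float, atp: float, alpha: float, beta: float) -> float:
    """AMP/ATP energy-state regulation multiplier (1 + r/alpha)/(1 + r/beta).

    ``r = AMP/ATP``.  Neutral (``1.0``) when ``alpha == beta`` or ``r == 0``;
    activating when ``beta > alpha`` and inhibitory when ``beta < alpha``,
    bounded between ``min(1, beta/alpha)`` and ``max(1, beta/alpha)``.
    """
    if atp <= 0:
        raise ValueError("ATP concentration must be positive for AMP/ATP regulation")
    if amp < 0:
        raise ValueError("AMP concentration must be non-negative")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    r = amp / atp
    return (1.0 + r / alpha) / (1.0 + r / beta)


def _rate(reaction: Reaction, state: Mapping[str, float], params: ParameterSet) -> float:
    law = reaction.rate_law
    v = params[law.vmax]
    for sid, km_name in law.substrate_terms:
        if sid not in state:
            raise KeyError(
                f"reaction {reaction.id!r}: substrate {sid!r} missing from state"
            )
        v *= mm_term(max(state[sid], 0.0), params[km_name])
    if law.regulation is not None:
        alpha_name, beta_name = law.regulation
        v *= regulation_factor(
            max(state["AMP"], 0.0), state["ATP"], params[alpha_name], params[beta_name]
        )
    return v


def reaction_flux(
    network: MetabolicNetwork,
    reaction_id: str,
    state: Mapping[str, float],
    params: ParameterSet,
) -> float:
    """Specific flux of one reaction at a given concentration state.

    Units: mmol per 10^6 cells per h (the growth reaction returns the
    specific growth rate in 1/h instead).
    """
    return _rate(network.reaction(reaction_id), state, params)


def growth_rate(
    state: Mapping[str, float],
    params: ParameterSet,
    network: MetabolicNetwork,
) -> float:
    """Specific growth rate mu = vmaxgrowth * prod of precursor saturations.

    The growth precursors (the substrate terms of the growth rate law)
    include tryptophan, so mu -> 0 on tryptophan exhaustion.
    """
    return _rate(network.growth_reaction, state, params)


# ---------------------------------------------------------------------------
# network file loading
# ---------------------------------------------------------------------------


def default_network_path() -> Path:
    return Path(__file__).parent / "data" / "wjmsc_network.yaml"


def _parse_rate_law(rid: str, spec: Mapping) -> RateLawSpec:
    try:
        kind = spec["kind"]
        vmax = spec["vmax"]
    except KeyError as exc:
        raise NetworkValidationError(f"reaction {rid!r}: rate law missing {exc}") from exc
    terms = tuple(
        (t["species"], t["km"]) for t in spec.get("substrate_terms", ())
    )
    reg = spec.get("regulation")
    if reg is not None:
        reg = (reg["alpha"], reg["beta"])
    return RateLawSpec(kind=kind, vmax=vmax, substrate_terms=terms, regulation=reg)


def build_wjmsc_network(network_file: str | Path | None = None) -> MetabolicNetwork:
    """Load and validate a metabolic network description.

    With no argument, loads the packaged WJMSC network (49 enzymatic
    reactions plus one growth reaction).
    """
    path = Path(network_file) if network_file is not None else default_network_path()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "species" not in doc or "reactions" not in doc:
        raise NetworkValidationError(
            f"{path}: network file must define 'species' and 'reactions'"
        )
    species = tuple(
        Species(
            id=s["id"],
            compartment=s["compartment"],
            measured=bool(s.get("measured", False)),
        )
        for s in doc["species"]
    )
    reactions = tuple(
        Reaction(
            id=r["id"],
            stoichiometry=dict(r["stoichiometry"]),
            rate_law=_parse_rate_law(r["id"], r["rate_law"]),
            pathway_tag=r["pathway_tag"],
        )
        for r in doc["reactions"]
    )
    constants = doc.get("biomass_constants", {})
    net = MetabolicNetwork(
        species=species,
        reactions=reactions,
        biomass_molar_weight=float(
            constants.get("biomass_molar_weight", BIOMASS_MOLAR_WEIGHT)
        ),
        protein_residue_weight=float(
            constants.get("protein_residue_weight", PROTEIN_RESIDUE_WEIGHT)
        ),
        precursor_map=doc.get("precursor_map", dict(PRECURSOR_MAP)),
    )
    net.validate()
    return net
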