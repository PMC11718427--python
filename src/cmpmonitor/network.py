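"""Stoichiometric metabolic networks: data model, validation, JSON I/O.

A network is a list of internal (balanced) metabolites and an ordered list
of reactions; the stoichiometric matrix S (rows = metabolites, columns =
reactions in stored order) is reconstructed exactly from the reaction
stoichiometries.  Exchange reactions move a single internal metabolite
across the system boundary; by convention a positive exchange flux is
secretion into the medium, so measured transport rates transfer onto
exchange bounds without sign flips.

The bundled :func:`builtin_toy_network` is a small lumped central-carbon
network (glycolysis, lactate branch, TCA/oxidative phosphorylation, ATP
maintenance, biomass) intended as a reviewable stand-in for a literature
CHO model; ATP and all internal carbon carriers are balanced even where
lumped reactions are elementally incomplete.

JSON schema::

    {"metabolites": ["glc", ...],
     "reactions": [{"id": "HK", "stoich": {"glc": -1, ...},
                    "lb": 0.0, "ub": null, "exchange": false,
                    "linked": null}, ...],
     "biomass_id": "BIOMASS", "atp_name": "atp"}

``null`` bounds mean unbounded in that direction; ``linked`` names the
measured metabolite whose transport rate constrains an exchange.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

INF = math.inf


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]   # metabolite -> coefficient (neg = consumed)
    lower_bound: float = -INF         # pmol/cell/h
    upper_bound: float = INF
    is_exchange: bool = False
    linked_metabolite: str | None = None

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class MetabolicNetwork:
    metabolites: list[str]
    reactions: list[Reaction]
    biomass_id: str
    atp_name: str = "atp"

    # -- structure ---------------------------------------------------------
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction with id {rid!r}")

    def stoichiometric_matrix(self) -> np.ndarray:
        """S with rows in ``metabolites`` order, columns in reaction order."""
        index = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry.items():
                S[index[met], j] = coeff
        return S

    def exchange_for(self, metabolite: str) -> Reaction:
        for r in self.reactions:
            if r.is_exchange and r.linked_metabolite == metabolite:
                return r
        raise KeyError(f"no exchange reaction linked to measured metabolite {metabolite!r}")

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass_id=self.biomass_id,
            atp_name=self.atp_name,
        )


def validate_network(net: MetabolicNetwork) -> ValidationReport:
    """Invariant checks; dead-end metabolites are warnings, the rest errors."""
    rep = ValidationReport()
    ids = net.reaction_ids()
    seen = set()
    for rid in ids:
        if rid in seen:
            rep.errors.append(f"duplicate reaction id {rid!r}")
        seen.add(rid)
    if net.biomass_id not in seen:
        rep.errors.append(f"biomass_id {net.biomass_id!r} not among reactions")
    if net.atp_name not in net.metabolites:
        rep.errors.append(f"atp_name {net.atp_name!r} not among metabolites")

    met_set = set(net.metabolites)
    linked = set()
    for rxn in net.reactions:
        if not rxn.stoichiometry:
            rep.errors.append(f"{rxn.id}: empty stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            rep.errors.append(
                f"{rxn.id}: lower_bound {rxn.lower_bound} > upper_bound {rxn.upper_bound}")
        unknown = set(rxn.stoichiometry) - met_set
        if unknown:
            rep.errors.append(f"{rxn.id}: unknown metabolites {sorted(unknown)}")
        if rxn.is_exchange and len(rxn.stoichiometry) != 1:
            rep.errors.append(
                f"{rxn.id}: exchange reactions must touch exactly one internal metabolite")
        if rxn.linked_metabolite is not None:
            if not rxn.is_exchange:
                rep.errors.append(f"{rxn.id}: linked_metabolite set on a non-exchange reaction")
            if rxn.linked_metabolite in linked:
                rep.errors.append(
                    f"{rxn.id}: measured metabolite {rxn.linked_metabolite!r} "
                    "linked to more than one exchange")
            linked.add(rxn.linked_metabolite)

    counts: dict[str, int] = {m: 0 for m in net.metabolites}
    for rxn in net.reactions:
        for met in rxn.stoichiometry:
            if met in counts:
                counts[met] += 1
    for met, n in counts.items():
        if n == 1:
            rep.warnings.append(f"dead-end metabolite {met!r} (appears in exactly one reaction)")
        elif n == 0:
            rep.warnings.append(f"orphan metabolite {met!r} (appears in no reaction)")
    return rep


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _bound_to_json(b: float):
    return None if math.isinf(b) else b


def _bound_from_json(b, sign: int) -> float:
    return sign * INF if b is None else float(b)


def network_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "metabolites": list(net.metabolites),
        "reactions": [
            {
                "id": r.id,
                "stoich": {m: c for m, c in r.stoichiometry.items()},
                "lb": _bound_to_json(r.lower_bound),
                "ub": _bound_to_json(r.upper_bound),
                "exchange": r.is_exchange,
                "linked": r.linked_metabolite,
            }
            for r in net.reactions
        ],
        "biomass_id": net.biomass_id,
        "atp_name": net.atp_name,
    }


def network_from_dict(data: dict) -> MetabolicNetwork:
    required = {"metabolites", "reactions", "biomass_id"}
    missing = required - set(data)
    if missing:
        raise ValueError(f"network JSON missing keys: {sorted(missing)}")
    reactions = []
    for entry in data["reactions"]:
        for key in ("id", "stoich"):
            if key not in entry:
                raise ValueError(f"reaction entry missing {key!r}: {entry}")
        reactions.append(Reaction(
            id=str(entry["id"]),
            stoichiometry={str(m): float(c) for m, c in entry["stoich"].items()},
            lower_bound=_bound_from_json(entry.get("lb"), -1),
            upper_bound=_bound_from_json(entry.get("ub"), +1),
            is_exchange=bool(entry.get("exchange", False)),
            linked_metabolite=entry.get("linked"),
        ))
    net = MetabolicNetwork(
        metabolites=[str(m) for m in data["metabolites"]],
        reactions=reactions,
        biomass_id=str(data["biomass_id"]),
        atp_name=str(data.get("atp_name", "atp")),
    )
    rep = validate_network(net)
    if not rep.ok:
        raise ValueError("invalid network: " + "; ".join(rep.errors))
    return net


def load_network(path) -> MetabolicNetwork:
    """Load and validate a network JSON file; reaction order = file order."""
    with open(path) as fh:
        data = json.load(fh)
    return network_from_dict(data)


def save_network(net: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Bundled toy central-carbon network
# ---------------------------------------------------------------------------

#: default ATP maintenance demand, pmol/cell/h (scaled to toy magnitudes)
ATP_MAINTENANCE = 0.02

#: default cap on glucose uptake when no measured constraint is applied
DEFAULT_GLC_UPTAKE = 10.0


def builtin_toy_network() -> MetabolicNetwork:
    """Lumped central-carbon network for CHO-like energy metabolism.

    Carbon enters as glucose, leaves as lactate or CO2; redox is carried by
    a single lumped NAD(P)H pool and oxidative phosphorylation yields an
    effective 1.5 ATP per carrier (NADH and FADH2 are pooled and proton
    leak is folded in), giving ~22 ATP per fully respired glucose.  Biomass
    drains a pyruvate/G6P-derived precursor plus ATP.  At this yield growth
    is ATP-limited over the whole span of physiological lactate:glucose
    flux ratios, so the optimal basis does not flip between carbon- and
    ATP-limited regimes as measured rates fluctuate.
    """
    r = Reaction
    reactions = [
        # exchanges (flux > 0 = secretion into medium)
        r("EX_glc", {"glc": -1}, lower_bound=-DEFAULT_GLC_UPTAKE, upper_bound=0.0,
          is_exchange=True, linked_metabolite="glucose"),
        r("EX_lac", {"lac": -1}, lower_bound=0.0, upper_bound=INF,
          is_exchange=True, linked_metabolite="lactate"),
        r("EX_o2", {"o2": -1}, lower_bound=-INF, upper_bound=0.0, is_exchange=True),
        r("EX_co2", {"co2": -1}, lower_bound=0.0, upper_bound=INF, is_exchange=True),
        # glycolysis (lumped in four steps; net glc + 2 ADP -> 2 pyr + 2 ATP + 2 NADH)
        r("HK", {"glc": -1, "atp": -1, "g6p": 1}, lower_bound=0.0),
        r("PGI", {"g6p": -1, "f6p": 1}),
        r("PFK", {"f6p": -1, "atp": -1, "fdp": 1}, lower_bound=0.0),
        r("EMP_low", {"fdp": -1, "pyr": 2, "atp": 4, "nadh": 2}, lower_bound=0.0),
        # lactate branch (reversible: overflow or lactate re-consumption)
        r("LDH", {"pyr": -1, "nadh": -1, "lac": 1}),
        # pyruvate oxidation and TCA (lumped, FADH2 folded into the NADH pool)
        r("PDH", {"pyr": -1, "accoa": 1, "co2": 1, "nadh": 1}, lower_bound=0.0),
        r("TCA", {"accoa": -1, "co2": 2, "nadh": 4, "atp": 1}, lower_bound=0.0),
        # oxidative phosphorylation; effective P/O of 1.5 for the pooled
        # NADH/FADH2 carrier (leak-inclusive), ~22 ATP per respired glucose
        r("OXPHOS", {"nadh": -1, "o2": -0.5, "atp": 1.5}, lower_bound=0.0),
        # non-growth-associated ATP maintenance (fixed demand)
        r("ATPM", {"atp": -1}, lower_bound=ATP_MAINTENANCE),
        # biomass precursor pool and growth
        r("PREC_SYN", {"g6p": -0.2, "pyr": -0.8, "atp": -2, "prec": 1}, lower_bound=0.0),
        r("BIOMASS", {"prec": -1, "atp": -1.5}, lower_bound=0.0),
    ]
    net = MetabolicNetwork(
        metabolites=["glc", "g6p", "f6p", "fdp", "pyr", "accoa", "lac",
                     "atp", "nadh", "o2", "co2", "prec"],
        reactions=reactions,
        biomass_id="BIOMASS",
        atp_name="atp",
    )
    rep = validate_network(net)
    assert rep.ok, rep.errors
    return net
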