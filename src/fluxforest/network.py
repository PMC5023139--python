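"""Metabolic network model: reactions, stoichiometry, and carbon atom maps.

A network is written in a small line-oriented text dialect::

    # comment
    @substrate glc.ext
    @symmetric suc fum
    upt: glc.ext (abcdef) -> g6p (abcdef)
    pgi: g6p (abcdef) <-> f6p (abcdef)
    fba: fbp (abcdef) <-> dhap (cba) + g3p (def)
    out_co2: co2 (a) ->

Each metabolite occurrence carries its carbon skeleton as a string of
letters (``a`` = carbon 1, biochemical numbering).  Within one reaction a
letter identifies one physical carbon atom: it must occur exactly once on
each side, which encodes the full atom transition map and enforces carbon
conservation.  Reactions with an empty right-hand side are sinks (outputs):
their carbons leave the system.  ``@substrate`` marks unbalanced input
metabolites that do not take part in the stoichiometric equation system.
``@symmetric`` declares rotationally symmetric molecules (e.g. succinate,
fumarate) whose carbon chain is equivalent to its reversal; the simulator
averages the stated and carbon-reversed atom maps with weight 1/2 each.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import NetworkError

__all__ = [
    "Occurrence",
    "Reaction",
    "MetabolicNetwork",
    "parse_network",
    "serialize_network",
    "validate_carbon_balance",
]


@dataclass(frozen=True)
class Occurrence:
    """One metabolite instance on one side of a reaction.

    ``atoms`` is the letter string naming the carbons of this instance;
    its length is the metabolite's carbon count.
    """

    metabolite: str
    atoms: str


@dataclass
class Reaction:
    """A (possibly reversible) reaction with its carbon atom transitions."""

    id: str
    reactants: list[Occurrence]
    products: list[Occurrence]
    reversible: bool = False

    @property
    def is_sink(self) -> bool:
        return len(self.products) == 0

    @property
    def stoichiometry(self) -> dict[str, int]:
        """Net signed coefficients (products positive)."""
        coeff: dict[str, int] = {}
        for occ in self.reactants:
            coeff[occ.metabolite] = coeff.get(occ.metabolite, 0) - 1
        for occ in self.products:
            coeff[occ.metabolite] = coeff.get(occ.metabolite, 0) + 1
        return {m: c for m, c in coeff.items() if c != 0}

    @property
    def atom_map(self) -> dict[tuple[int, int], tuple[int, int]]:
        """Map (product instance, product carbon) -> (reactant instance, carbon).

        All indices 0-based.  Only meaningful after validation.
        """
        origin: dict[str, tuple[int, int]] = {}
        for ri, occ in enumerate(self.reactants):
            for pos, letter in enumerate(occ.atoms):
                origin[letter] = (ri, pos)
        amap: dict[tuple[int, int], tuple[int, int]] = {}
        for pi, occ in enumerate(self.products):
            for pos, letter in enumerate(occ.atoms):
                amap[(pi, pos)] = origin[letter]
        return amap

    def validate(self) -> None:
        if not self.reactants:
            raise NetworkError(f"reaction '{self.id}': no reactants")
        seen_r: set[str] = set()
        for occ in self.reactants:
            if not occ.atoms:
                raise NetworkError(
                    f"reaction '{self.id}': empty atom string for {occ.metabolite}"
                )
            for letter in occ.atoms:
                if letter in seen_r:
                    raise NetworkError(
                        f"reaction '{self.id}': reactant carbon letter "
                        f"'{letter}' used twice"
                    )
                seen_r.add(letter)
        seen_p: set[str] = set()
        for occ in self.products:
            for pos, letter in enumerate(occ.atoms):
                if letter in seen_p:
                    raise NetworkError(
                        f"reaction '{self.id}': product carbon letter "
                        f"'{letter}' used twice"
                    )
                seen_p.add(letter)
                if letter not in seen_r:
                    raise NetworkError(
                        f"reaction '{self.id}': product {occ.metabolite} carbon "
                        f"{pos + 1} ('{letter}') maps to no reactant carbon"
                    )
        if self.products and seen_p != seen_r:
            lost = sorted(seen_r - seen_p)
            raise NetworkError(
                f"reaction '{self.id}': reactant carbons {lost} do not appear "
                "in any product (carbon not conserved)"
            )
        if self.reversible and self.is_sink:
            raise NetworkError(f"reaction '{self.id}': sink cannot be reversible")


@dataclass
class MetabolicNetwork:
    """A validated network: reactions plus metabolite/substrate declarations."""

    reactions: list[Reaction]
    substrates: set[str]
    symmetric_metabolites: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._index) != len(self.reactions):
            dup = [r.id for r in self.reactions
                   if sum(x.id == r.id for x in self.reactions) > 1]
            raise NetworkError(f"duplicate reaction id(s): {sorted(set(dup))}")

    # -- basic accessors ----------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._index[rid]]
        except KeyError:
            raise NetworkError(f"unknown reaction id '{rid}'") from None

    def reaction_index(self, rid: str) -> int:
        if rid not in self._index:
            raise NetworkError(f"unknown reaction id '{rid}'")
        return self._index[rid]

    @property
    def metabolites(self) -> dict[str, int]:
        """All metabolites with their carbon counts."""
        carbons: dict[str, int] = {}
        for r in self.reactions:
            for occ in r.reactants + r.products:
                n = len(occ.atoms)
                if carbons.setdefault(occ.metabolite, n) != n:
                    raise NetworkError(
                        f"metabolite '{occ.metabolite}' has inconsistent carbon "
                        f"counts ({carbons[occ.metabolite]} vs {n} in "
                        f"reaction '{r.id}')"
                    )
        return carbons

    @property
    def balanced_metabolites(self) -> list[str]:
        """Metabolites subject to mass balance, in stable order."""
        return [m for m in self.metabolites if m not in self.substrates]

    @property
    def outputs(self) -> list[str]:
        """Sink reaction ids (one output flux per secreted/biomass precursor)."""
        return [r.id for r in self.reactions if r.is_sink]

    @property
    def reversible_mask(self):
        import numpy as np

        return np.array([r.reversible for r in self.reactions], dtype=bool)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for r in self.reactions:
            r.validate()
        carbons = self.metabolites
        for m in self.substrates:
            if m not in carbons:
                raise NetworkError(f"declared substrate '{m}' never occurs")
        for m in self.symmetric_metabolites:
            if m not in carbons:
                raise NetworkError(f"declared symmetric metabolite '{m}' never occurs")
        produced: set[str] = set()
        consumed: set[str] = set()
        for r in self.reactions:
            for occ in r.reactants:
                consumed.add(occ.metabolite)
                if r.reversible:
                    produced.add(occ.metabolite)
            for occ in r.products:
                produced.add(occ.metabolite)
                if r.reversible:
                    consumed.add(occ.metabolite)
        for m in self.balanced_metabolites:
            if m not in produced:
                raise NetworkError(f"balanced metabolite '{m}' has no producer")
            if m not in consumed:
                raise NetworkError(f"balanced metabolite '{m}' has no consumer")

    def stoichiometric_matrix(self):
        """S over balanced metabolites x reactions (net flux convention)."""
        import numpy as np

        rows = {m: i for i, m in enumerate(self.balanced_metabolites)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                if m in rows:
                    S[rows[m], j] += c
        return S


# ---------------------------------------------------------------------------
# Parsing / serialization

_OCC_RE = re.compile(r"^\s*(\S+?)\s*\(([A-Za-z]+)\)\s*$")


def _parse_side(text: str, rid: str) -> list[Occurrence]:
    text = text.strip()
    if not text:
        return []
    occs = []
    for part in text.split("+"):
        m = _OCC_RE.match(part)
        if not m:
            raise NetworkError(
                f"reaction '{rid}': cannot parse metabolite term '{part.strip()}'"
            )
        occs.append(Occurrence(m.group(1), m.group(2)))
    return occs


def parse_network(text: str) -> MetabolicNetwork:
    """Parse the network dialect and return a validated network."""
    substrates: set[str] = set()
    symmetric: set[str] = set()
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@"):
            parts = line.split()
            directive, names = parts[0], parts[1:]
            if directive == "@substrate":
                substrates.update(names)
            elif directive == "@symmetric":
                symmetric.update(names)
            else:
                raise NetworkError(f"line {lineno}: unknown directive '{directive}'")
            continue
        if ":" not in line:
            raise NetworkError(f"line {lineno}: expected 'id: equation', got '{line}'")
        rid, eqn = line.split(":", 1)
        rid = rid.strip()
        if "<->" in eqn:
            lhs, rhs = eqn.split("<->", 1)
            reversible = True
        elif "->" in eqn:
            lhs, rhs = eqn.split("->", 1)
            reversible = False
        else:
            raise NetworkError(f"reaction '{rid}': missing '->' or '<->'")
        reactions.append(
            Reaction(
                id=rid,
                reactants=_parse_side(lhs, rid),
                products=_parse_side(rhs, rid),
                reversible=reversible,
            )
        )
    net = MetabolicNetwork(reactions, substrates, symmetric)
    net.validate()
    return net


def serialize_network(network: MetabolicNetwork) -> str:
    """Write a network back to the text dialect (parse/serialize round-trips)."""
    lines = []
    if network.substrates:
        lines.append("@substrate " + " ".join(sorted(network.substrates)))
    if network.symmetric_metabolites:
        lines.append("@symmetric " + " ".join(sorted(network.symmetric_metabolites)))
    for r in network.reactions:
        arrow = "<->" if r.reversible else "->"
        lhs = " + ".join(f"{o.metabolite} ({o.atoms})" for o in r.reactants)
        rhs = " + ".join(f"{o.metabolite} ({o.atoms})" for o in r.products)
        lines.append(f"{r.id}: {lhs} {arrow} {rhs}".rstrip())
    return "\n".join(lines) + "\n"


def validate_carbon_balance(network: MetabolicNetwork) -> dict:
    """Report per-reaction carbon conservation (report-only; never raises)."""
    per_reaction: dict[str, bool] = {}
    for r in network.reactions:
        try:
            r.validate()
            per_reaction[r.id] = True
        except NetworkError:
            per_reaction[r.id] = False
    return {
        "per_reaction": per_reaction,
        "ok": all(per_reaction.values()),
        "failed": sorted(rid for rid, ok in per_reaction.items() if not ok),
    }
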