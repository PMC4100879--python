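"""Data model for constraint-based metabolic networks.

The central objects are :class:`Metabolite`, :class:`Reaction` and
:class:`MetabolicNetwork`.  A network is a stoichiometric system
``S @ v = 0`` with per-reaction flux bounds; metabolites live in named
compartments (``c`` cytosol, ``e`` extracellular by convention) and both
metabolites and reactions may carry a *tissue tag* once a network has been
expanded to a multi-tissue system with a shared extracellular compartment.

Tissue tags are metadata: the conventional serialized spelling (reaction
prefix ``A:``, metabolite suffix ``[Adp]``) is applied only when writing the
native tab-separated table format and parsed back on read.

Sign conventions
----------------
Exchange reactions are boundary pseudo-reactions touching a single
extracellular metabolite.  Written in sink orientation (``1 A[e] ->``)
positive flux is secretion: the metabolite leaves the system, so an increase
in positive exchange flux reads as an increase in extracellular
concentration.  Source orientation (``-> 1 A[e]``) is also legal and means
positive flux supplies the metabolite (e.g. dietary input).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ConfidenceTiers",
    "TissueTag",
    "ParseError",
    "NetworkIntegrityError",
    "read_network",
    "write_network",
    "read_native_table",
    "write_native_table",
    "read_sbml",
    "remove_dead_ends",
    "expand_to_tissues",
]

DEFAULT_LOWER = -1000.0
DEFAULT_UPPER = 1000.0


class ParseError(ValueError):
    """Malformed input file; message names the offending line/element."""


class NetworkIntegrityError(ValueError):
    """A reaction references a metabolite that is not declared."""


@dataclass(frozen=True)
class TissueTag:
    """A tissue labelling pair: reaction ID prefix and metabolite suffix.

    E.g. ``TissueTag("A:", "Adp")`` for adipose.
    """

    prefix: str
    suffix: str


@dataclass(frozen=True)
class Metabolite:
    species: str
    compartment: str
    tissue: str | None = None  # metabolite suffix tag, e.g. "Adp"

    @property
    def id(self) -> str:
        base = f"{self.species}[{self.compartment}]"
        return base + (f"[{self.tissue}]" if self.tissue else "")


@dataclass
class Reaction:
    name: str
    stoichiometry: dict[str, float]  # metabolite full-id -> signed coefficient
    lower_bound: float = DEFAULT_LOWER
    upper_bound: float = DEFAULT_UPPER
    gpr: str = ""
    subsystem: str = ""
    tissue: str | None = None  # reaction prefix tag, e.g. "A:"

    @property
    def id(self) -> str:
        return (self.tissue or "") + self.name

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


_MET_RE = re.compile(r"^(.*?)\[([^\[\]]+)\](?:\[([^\[\]]+)\])?$")


def parse_metabolite_id(token: str) -> Metabolite:
    m = _MET_RE.match(token)
    if not m:
        raise ParseError(f"cannot parse metabolite token {token!r}")
    species, comp, tissue = m.groups()
    return Metabolite(species=species, compartment=comp, tissue=tissue)


class MetabolicNetwork:
    """A stoichiometric metabolic network.

    Metabolites and reactions are kept in insertion order; IDs are unique.
    """

    def __init__(self, name: str = "", extracellular: str = "e"):
        self.name = name
        self.extracellular = extracellular
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        existing = self.metabolites.get(met.id)
        if existing is not None:
            return existing
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction, declare_metabolites: bool = False) -> Reaction:
        if rxn.id in self.reactions:
            raise NetworkIntegrityError(f"duplicate reaction id {rxn.id!r}")
        if rxn.lower_bound > rxn.upper_bound:
            raise NetworkIntegrityError(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                if declare_metabolites:
                    self.add_metabolite(parse_metabolite_id(mid))
                else:
                    raise NetworkIntegrityError(
                        f"reaction {rxn.id!r} references undeclared metabolite {mid!r}"
                    )
        self.reactions[rxn.id] = rxn
        return rxn

    # -- queries ----------------------------------------------------------
    def is_extracellular(self, met_id: str) -> bool:
        return self.metabolites[met_id].compartment == self.extracellular

    def is_exchange(self, rxn_id: str) -> bool:
        """True for boundary pseudo-reactions: one metabolite, extracellular."""
        stoich = self.reactions[rxn_id].stoichiometry
        return len(stoich) == 1 and all(self.is_extracellular(m) for m in stoich)

    def transported_species(self, rxn_id: str) -> set[str]:
        """Species moved between a non-extracellular compartment and the
        extracellular compartment by this reaction (empty if none)."""
        stoich = self.reactions[rxn_id].stoichiometry
        moved: set[str] = set()
        by_species: dict[str, list[tuple[bool, float]]] = {}
        for mid, coef in stoich.items():
            met = self.metabolites[mid]
            by_species.setdefault(met.species, []).append(
                (self.is_extracellular(mid), coef)
            )
        for species, entries in by_species.items():
            sides = {ext for ext, _ in entries}
            if sides == {True, False}:
                moved.add(species)
        return moved

    def is_transport(self, rxn_id: str) -> bool:
        return bool(self.transported_species(rxn_id)) and not self.is_exchange(rxn_id)

    def exchange_ids(self) -> list[str]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def stoichiometric_matrix(self):
        """Dense S matrix plus row (metabolite) and column (reaction) orders."""
        import numpy as np

        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rxn_ids = list(self.reactions)
        S = np.zeros((len(met_index), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[mid], j] = coef
        return S, list(self.metabolites), rxn_ids

    # -- derived networks -------------------------------------------------
    def copy(self) -> "MetabolicNetwork":
        net = MetabolicNetwork(self.name, self.extracellular)
        net.metabolites = dict(self.metabolites)
        for rid, rxn in self.reactions.items():
            net.reactions[rid] = rxn.copy()
        return net

    def subnetwork(self, rxn_ids, name: str | None = None) -> "MetabolicNetwork":
        """Subnetwork induced by a reaction subset plus its metabolites."""
        keep = set(rxn_ids)
        missing = keep - set(self.reactions)
        if missing:
            raise KeyError(f"unknown reactions: {sorted(missing)}")
        net = MetabolicNetwork(name or self.name, self.extracellular)
        used = [r for r in self.reactions if r in keep]
        met_ids = {m for r in used for m in self.reactions[r].stoichiometry}
        for mid, met in self.metabolites.items():
            if mid in met_ids:
                net.metabolites[mid] = met
        for rid in used:
            net.reactions[rid] = self.reactions[rid].copy()
        return net

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<MetabolicNetwork {self.name!r}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


@dataclass
class ConfidenceTiers:
    """The reaction-ID partition driving model extraction.

    ``high`` reactions must all appear in the extracted model; ``medium``
    reactions are rewarded (+1 each) and ``low`` reactions penalised (-0.5
    each, by default) in the extraction objective.  ``low`` is conventionally
    the complement of ``high | medium``.
    """

    high: set[str] = field(default_factory=set)
    medium: set[str] = field(default_factory=set)
    low: set[str] = field(default_factory=set)

    def __post_init__(self):
        overlap = (self.high & self.medium) | (self.high & self.low) | (
            self.medium & self.low
        )
        if overlap:
            raise ValueError(f"tiers must be disjoint; shared ids: {sorted(overlap)}")

    @classmethod
    def from_assignment(
        cls, net: MetabolicNetwork, high=(), medium=(), low=()
    ) -> "ConfidenceTiers":
        """Build tiers for a network; unassigned reactions go to ``low``."""
        high, medium, low = set(high), set(medium), set(low)
        known = set(net.reactions)
        unknown = (high | medium | low) - known
        if unknown:
            raise KeyError(f"tier lists mention unknown reactions: {sorted(unknown)}")
        low |= known - high - medium
        return cls(high=high, medium=medium, low=low)

    @classmethod
    def from_files(cls, net, high_path, medium_path, low_path=None):
        def load(path):
            if path is None:
                return set()
            with open(path) as fh:
                return {line.strip() for line in fh if line.strip()}

        return cls.from_assignment(
            net, high=load(high_path), medium=load(medium_path), low=load(low_path)
        )

    def restrict(self, rxn_ids) -> "ConfidenceTiers":
        keep = set(rxn_ids)
        return ConfidenceTiers(
            high=self.high & keep, medium=self.medium & keep, low=self.low & keep
        )


# ---------------------------------------------------------------------------
# Native tab-separated reaction-table format
# ---------------------------------------------------------------------------

_NATIVE_COLUMNS = [
    "reaction_id",
    "equation",
    "lower_bound",
    "upper_bound",
    "gpr",
    "subsystem",
]


def _format_coef(coef: float) -> str:
    return format(coef, "g")


def _format_side(net: MetabolicNetwork, terms: list[tuple[str, float]]) -> str:
    return " + ".join(f"{_format_coef(c)} {mid}" for mid, c in terms)


def format_equation(net: MetabolicNetwork, rxn: Reaction) -> str:
    left = [(m, -c) for m, c in rxn.stoichiometry.items() if c < 0]
    right = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if rxn.reversible else "->"
    return f"{_format_side(net, left)} {arrow} {_format_side(net, right)}".strip()


def _parse_terms(side: str, lineno: int) -> list[tuple[str, float]]:
    side = side.strip()
    if not side:
        return []
    terms = []
    for chunk in re.split(r"\s+\+\s+", side):
        parts = chunk.split()
        if len(parts) == 1:
            coef, token = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: bad stoichiometric coefficient in {chunk!r}"
                ) from exc
            token = parts[1]
        else:
            raise ParseError(f"line {lineno}: cannot parse term {chunk!r}")
        terms.append((token, coef))
    return terms


def parse_equation(equation: str, lineno: int = 0) -> dict[str, float]:
    m = re.search(r"(<=>|<->|->)", equation)
    if not m:
        raise ParseError(f"line {lineno}: no reaction arrow in {equation!r}")
    left, right = equation[: m.start()], equation[m.end():]
    stoich: dict[str, float] = {}
    for token, coef in _parse_terms(left, lineno):
        stoich[token] = stoich.get(token, 0.0) - coef
    for token, coef in _parse_terms(right, lineno):
        stoich[token] = stoich.get(token, 0.0) + coef
    if not stoich:
        raise ParseError(f"line {lineno}: empty reaction equation")
    return stoich


def _split_reaction_id(rid: str) -> tuple[str | None, str]:
    if ":" in rid:
        prefix, name = rid.split(":", 1)
        return prefix + ":", name
    return None, rid


def read_native_table(path, name: str | None = None) -> MetabolicNetwork:
    """Read a network from the native tab-separated reaction table.

    Columns: reaction_id, equation, lower_bound, upper_bound, gpr, subsystem.
    Metabolites are declared implicitly through equations; a bare metabolite
    column is unnecessary because compartments (and tissue tags) are encoded
    as bracketed suffixes, e.g. ``glc[c]``, ``glc[c][Adp]``, ``glc[e]``.
    """
    net = MetabolicNetwork(name=name or str(path))
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_NATIVE_COLUMNS)] != _NATIVE_COLUMNS:
            raise ParseError(
                f"{path}: expected header {_NATIVE_COLUMNS}, found {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"line {lineno}: expected >=4 tab-separated fields")
            fields += [""] * (len(_NATIVE_COLUMNS) - len(fields))
            rid, equation, lb, ub, gpr, subsystem = fields[:6]
            try:
                lb, ub = float(lb), float(ub)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad bounds for {rid!r}") from exc
            stoich_tokens = parse_equation(equation, lineno)
            stoich: dict[str, float] = {}
            for token, coef in stoich_tokens.items():
                met = net.add_metabolite(parse_metabolite_id(token))
                stoich[met.id] = coef
            tissue, base = _split_reaction_id(rid)
            rxn = Reaction(
                name=base,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=subsystem,
                tissue=tissue,
            )
            net.add_reaction(rxn)
    return net


def write_native_table(net: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_NATIVE_COLUMNS) + "\n")
        for rxn in net.reactions.values():
            fh.write(
                "\t".join(
                    [
                        rxn.id,
                        format_equation(net, rxn),
                        repr(rxn.lower_bound),
                        repr(rxn.upper_bound),
                        rxn.gpr,
                        rxn.subsystem,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SBML (via cobrapy, which wraps libsbml)
# ---------------------------------------------------------------------------

_EXTRACELLULAR_NAMES = {"e", "e_b", "extracellular", "extracellular space"}


def read_sbml(path, extracellular: str | None = None) -> MetabolicNetwork:
    """Read an SBML model (Recon1-style, e.g. from BiGG) into a network.

    Delegates parsing to cobrapy/libsbml and converts the result.  The
    extracellular compartment is auto-detected among conventional names
    unless given explicitly.
    """
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    comps = set(model.compartments)
    if extracellular is None:
        hits = {c for c in comps if c.lower() in _EXTRACELLULAR_NAMES}
        extracellular = next(iter(hits)) if hits else "e"
    net = MetabolicNetwork(name=model.id or str(path), extracellular=extracellular)
    for met in model.metabolites:
        species = met.id
        suffix = f"_{met.compartment}"
        if species.endswith(suffix):
            species = species[: -len(suffix)]
        net.add_metabolite(Metabolite(species=species, compartment=met.compartment))
    id_map = {}
    for met in model.metabolites:
        species = met.id
        suffix = f"_{met.compartment}"
        if species.endswith(suffix):
            species = species[: -len(suffix)]
        id_map[met.id] = Metabolite(species=species, compartment=met.compartment).id
    for rxn in model.reactions:
        stoich = {id_map[m.id]: float(c) for m, c in rxn.metabolites.items()}
        net.add_reaction(
            Reaction(
                name=rxn.id,
                stoichiometry=stoich,
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gpr=str(rxn.gpr) if rxn.gpr else "",
                subsystem=rxn.subsystem or "",
            )
        )
    return net


def read_network(path, format: str = "native-table", **kw) -> MetabolicNetwork:
    """Read a network from ``sbml`` or ``native-table`` format."""
    if format == "sbml":
        return read_sbml(path, **kw)
    if format in ("native-table", "native"):
        return read_native_table(path, **kw)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: MetabolicNetwork, path) -> None:
    write_native_table(net, path)


# ---------------------------------------------------------------------------
# Dead-end pruning and multi-tissue expansion
# ---------------------------------------------------------------------------

def _producible_consumable(net: MetabolicNetwork):
    """For every metabolite: can any reaction produce it, can any consume it.

    A reversible reaction counts as both producer and consumer of each of its
    metabolites (operating direction is unconstrained a priori); an
    irreversible reaction produces its products and consumes its substrates.
    """
    producible = {m: False for m in net.metabolites}
    consumable = {m: False for m in net.metabolites}
    for rxn in net.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for mid, coef in rxn.stoichiometry.items():
            if coef > 0:
                producible[mid] |= fwd
                consumable[mid] |= rev
            elif coef < 0:
                consumable[mid] |= fwd
                producible[mid] |= rev
    return producible, consumable


def remove_dead_ends(net: MetabolicNetwork) -> MetabolicNetwork:
    """Iteratively remove dead-end metabolites and the reactions touching them.

    A dead-end metabolite can only be produced or only consumed, so at steady
    state no reaction touching it can carry flux.  Removal cascades until a
    fixed point; the result is a (possibly empty) subnetwork of the input.
    Metabolites left untouched by any reaction are dropped as well.
    """
    net = net.copy()
    while True:
        producible, consumable = _producible_consumable(net)
        touched = {m for r in net.reactions.values() for m in r.stoichiometry}
        dead = {
            m
            for m in net.metabolites
            if m not in touched or not (producible[m] and consumable[m])
        }
        if not dead:
            return net
        net.metabolites = {
            m: met for m, met in net.metabolites.items() if m not in dead
        }
        net.reactions = {
            rid: rxn
            for rid, rxn in net.reactions.items()
            if not (set(rxn.stoichiometry) & dead)
        }


def expand_to_tissues(
    net: MetabolicNetwork, tissue_tags: list[TissueTag]
) -> MetabolicNetwork:
    """Replicate a network once per tissue with a shared extracellular space.

    Every reaction touching at least one non-extracellular metabolite is
    copied per tissue (reaction gains the tissue prefix tag, its internal
    metabolites the tissue suffix tag).  Reactions over extracellular
    metabolites only -- including all exchange reactions -- are kept exactly
    once and shared, as are all extracellular metabolites.
    """
    if not tissue_tags:
        raise ValueError("tissue_tags must be non-empty")
    if not any(
        net.is_extracellular(m) for m in net.metabolites
    ):
        raise ValueError("network has no extracellular compartment to share")
    out = MetabolicNetwork(name=f"{net.name}[{len(tissue_tags)}-tissue]",
                           extracellular=net.extracellular)
    for mid, met in net.metabolites.items():
        if net.is_extracellular(mid):
            out.add_metabolite(met)
        else:
            for tag in tissue_tags:
                out.add_metabolite(replace(met, tissue=tag.suffix))
    for rxn in net.reactions.values():
        ext_only = all(net.is_extracellular(m) for m in rxn.stoichiometry)
        if ext_only:
            if rxn.id in out.reactions:
                raise NetworkIntegrityError(f"naming collision for {rxn.id!r}")
            out.add_reaction(rxn.copy())
            continue
        for tag in tissue_tags:
            stoich = {}
            for mid, coef in rxn.stoichiometry.items():
                met = net.metabolites[mid]
                key = mid if net.is_extracellular(mid) else replace(
                    met, tissue=tag.suffix
                ).id
                stoich[key] = coef
            copy = replace(rxn, stoichiometry=stoich, tissue=tag.prefix)
            if copy.id in out.reactions:
                raise NetworkIntegrityError(f"naming collision for {copy.id!r}")
            out.add_reaction(copy)
    return out
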