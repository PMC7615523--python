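"""Residue classification and the connected-driver allosteric network.

Crossing pharmacological importance (the mutation impairs Gs signaling) with
structural relevance (the residue participates in at least one
active-state-specific contact) yields four classes:

=================  =================  ===============
pharm. important   active-specific    class
=================  =================  ===============
yes                yes                driver
yes                no                 modulator
no                 yes                passenger
no                 no                 bystander
=================  =================  ===============

Drivers split further: a *connected* driver forms an active-state-specific
contact to another driver with a matching effect type (both impair potency,
or both impair efficacy; a mutation abolishing signal entirely counts for
either), all other drivers are *disconnected*.  Residues excluded for low
surface abundance, or unresolved in either structure, are unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .contacts import ContactPartition
from .pharmacology import IMPORTANT_CALLS

__all__ = [
    "ResidueClassRecord",
    "AllostericNetwork",
    "effect_type",
    "classify_residues",
    "build_network",
    "annotate_roles",
]

#: call -> effect type used for the connected-driver matching rule
_EFFECTS = {
    "efficacy_reduced": frozenset({"efficacy"}),
    "potency_reduced": frozenset({"potency"}),
    "both_reduced": frozenset({"efficacy", "potency"}),
    # total loss of signal implies both parameters are affected
    "no_signal": frozenset({"efficacy", "potency"}),
}


def effect_type(call: str) -> frozenset:
    return _EFFECTS.get(call, frozenset())


@dataclass
class ResidueClassRecord:
    residue_key: str
    call: str
    pharm_important: bool
    active_specific: bool
    residue_class: str  # connected_driver|disconnected_driver|modulator|passenger|bystander|unclassified
    reason: str = ""
    tags: set[str] = field(default_factory=set)


@dataclass
class AllostericNetwork:
    """Graph over connected drivers: nodes carry effect types, edges are
    effect-matched active-state-specific contacts weighted by the number of
    atom-atom contacts."""

    graph: nx.Graph

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def connected_drivers(self) -> set[str]:
        return {n for n, d in self.graph.degree if d >= 1}

    @property
    def n_atom_contacts(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def classify_residues(
    calls: dict[str, str],
    partition: ContactPartition,
    resolved_active: set[str],
    resolved_inactive: set[str],
) -> dict[str, ResidueClassRecord]:
    """Classify every residue with a pharmacology call.

    ``calls`` maps residue key -> pharmacology call.  Drivers are provisionally
    labelled ``disconnected_driver``; :func:`build_network` promotes those with
    an effect-matched active-specific contact to ``connected_driver``.
    Gain-of-function mutants are treated as not impairing signaling.
    """
    active_residues = partition.residues_in("active_only")
    records: dict[str, ResidueClassRecord] = {}
    for key in sorted(calls):
        call = calls[key]
        important = call in IMPORTANT_CALLS
        specific = key in active_residues
        if call == "excluded_low_abundance":
            cls, reason = "unclassified", "excluded_low_abundance"
        elif key not in resolved_active or key not in resolved_inactive:
            cls, reason = "unclassified", "unresolved_in_structure"
        elif important and specific:
            cls, reason = "disconnected_driver", ""
        elif important:
            cls, reason = "modulator", ""
        elif specific:
            cls, reason = "passenger", ""
        else:
            cls, reason = "bystander", ""
        records[key] = ResidueClassRecord(
            residue_key=key,
            call=call,
            pharm_important=important,
            active_specific=specific,
            residue_class=cls,
            reason=reason,
        )
    return records


def build_network(
    records: dict[str, ResidueClassRecord],
    partition: ContactPartition,
) -> AllostericNetwork:
    """Build the allosteric network and promote connected drivers in place.

    Edges are active-state-specific contacts between two drivers whose effect
    types overlap (a driver affecting both parameters matches either partner);
    an effect mismatch (potency-only vs efficacy-only) yields no edge.  Edge
    weight is the atom-contact multiplicity of the underlying contact.
    """
    g = nx.Graph()
    drivers = {
        k
        for k, r in records.items()
        if r.residue_class in ("disconnected_driver", "connected_driver")
    }
    for node in sorted(drivers):
        g.add_node(node, effects="+".join(sorted(effect_type(records[node].call))))
    for pair, contact in partition.active_only.items():
        a, b = pair
        if a in drivers and b in drivers:
            if effect_type(records[a].call) & effect_type(records[b].call):
                g.add_edge(a, b, weight=contact.n_atom_contacts)
    # drop isolated driver nodes from the network view; they stay disconnected
    connected = {n for n, d in g.degree if d >= 1}
    g.remove_nodes_from(drivers - connected)
    for k in drivers:
        records[k].residue_class = (
            "connected_driver" if k in connected else "disconnected_driver"
        )
    return AllostericNetwork(graph=g)


def annotate_roles(
    records: dict[str, ResidueClassRecord],
    network: AllostericNetwork,
    partition: ContactPartition,
    ligand_site: set[str] | None = None,
    gprot_site: set[str] | None = None,
    motif_residues: set[str] | None = None,
    x50_residues: set[str] | None = None,
    relative_asa: dict[str, float] | None = None,
    surface_threshold: float = 0.25,
) -> dict[str, ResidueClassRecord]:
    """Tag pharmacologically important residues with known functional roles.

    Tags: ligand_site, gprot_site, motif, x50, network_member,
    network_modifier (touches a driver through any filtered contact),
    surface_exposed (relative ASA above threshold); residues collecting no
    tag are tagged 'unexplained'.
    """
    ligand_site = ligand_site or set()
    gprot_site = gprot_site or set()
    motif_residues = motif_residues or set()
    x50_residues = x50_residues or set()
    relative_asa = relative_asa or {}
    drivers = {
        k
        for k, r in records.items()
        if r.residue_class in ("connected_driver", "disconnected_driver")
    }
    touches_driver = set()
    for part in (partition.active_only, partition.inactive_only, partition.shared):
        for a, b in part:
            if b in drivers:
                touches_driver.add(a)
            if a in drivers:
                touches_driver.add(b)

    for k, rec in records.items():
        if not rec.pharm_important:
            continue
        tags = set()
        if k in ligand_site:
            tags.add("ligand_site")
        if k in gprot_site:
            tags.add("gprot_site")
        if k in motif_residues:
            tags.add("motif")
        if k in x50_residues:
            tags.add("x50")
        if k in network.connected_drivers:
            tags.add("network_member")
        elif k in touches_driver:
            tags.add("network_modifier")
        if relative_asa.get(k, 0.0) > surface_threshold:
            tags.add("surface_exposed")
        rec.tags = tags or {"unexplained"}
    return records
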