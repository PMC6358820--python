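"""Drug-combination analysis: composite ADRs, configuration modes, CRMs.

Given a set of co-administered drugs D, the combination subgraph is the
union of the directed second-order neighbourhoods of each drug — every
GO term some drug in D may perturb and every ADR those terms may
manifest.  Within that subgraph:

* a *composite ADR* (cADR) is an ADR reachable from at least two drugs
  of D — the reaction cannot be pinned on a single drug;
* a GO parent g of an ADR is in *mode 1* when two or more drugs of D
  perturb g itself (shared-function risk), and in *mode 2* when only one
  drug perturbs g but some other parent of the same ADR contributes a
  different drug (different drugs, different functions, same reaction);
* a *composite risk module* (CRM) is a maximal set of cADRs and their GO
  parents that remain connected once the drug nodes are removed —
  reactions in one CRM can only be explained by perturbations of GO
  terms in the same CRM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .graph import NodeKind, TripartiteNetwork

__all__ = [
    "CombinationSubgraph",
    "AdrModeProfile",
    "CRM",
    "CombinationReport",
    "combination_subgraph",
    "composite_adrs",
    "mode_profile",
    "risk_modules",
    "report",
]


@dataclass(frozen=True)
class CombinationSubgraph:
    """The directed second-order neighbourhood of a drug combination."""

    drugs: frozenset[str]
    network: TripartiteNetwork
    #: GO term -> drugs of the combination that may perturb it
    drugs_of_go: Mapping[str, frozenset[str]]
    #: ADR -> its GO parents within the subgraph
    go_parents: Mapping[str, frozenset[str]]

    @property
    def go_terms(self) -> frozenset[str]:
        return self.network.go_terms

    @property
    def adrs(self) -> frozenset[str]:
        return self.network.adrs

    def drug_sources(self, adr: str) -> frozenset[str]:
        """Drugs of the combination with a directed path to ``adr``."""
        parents = self.go_parents.get(adr)
        if parents is None:
            raise KeyError(f"ADR {adr!r} is not in this combination subgraph")
        out: set[str] = set()
        for g in parents:
            out |= self.drugs_of_go[g]
        return frozenset(out)


def combination_subgraph(
    net: TripartiteNetwork, drugs: Iterable[str]
) -> CombinationSubgraph:
    """Extract the combination subgraph for a drug set.

    Contains the drugs, all their GO successors, all ADR successors of
    those GO terms, and only the edges incident to the drug set's paths.
    """
    drug_set = frozenset(str(d) for d in drugs)
    missing = sorted(d for d in drug_set if d not in net or net.kind(d) is not NodeKind.DRUG)
    if missing:
        raise KeyError(f"unknown drug node(s): {', '.join(missing)}")

    sub = TripartiteNetwork()
    drugs_of_go: dict[str, set[str]] = {}
    for d in sorted(drug_set):
        sub.add_node(d, NodeKind.DRUG)
        for g in net.successors(d):
            drugs_of_go.setdefault(g, set()).add(d)
    go_parents: dict[str, set[str]] = {}
    for g in sorted(drugs_of_go):
        sub.add_node(g, NodeKind.GO)
        for a in net.successors(g):
            go_parents.setdefault(a, set()).add(g)
    for a in sorted(go_parents):
        sub.add_node(a, NodeKind.ADR)
    for g, ds in drugs_of_go.items():
        for d in ds:
            sub.add_edge(d, g, net.edge_weight(d, g))
    for a, gs in go_parents.items():
        for g in gs:
            sub.add_edge(g, a, net.edge_weight(g, a))

    return CombinationSubgraph(
        drugs=drug_set,
        network=sub,
        drugs_of_go={g: frozenset(v) for g, v in drugs_of_go.items()},
        go_parents={a: frozenset(v) for a, v in go_parents.items()},
    )


def composite_adrs(sub: CombinationSubgraph) -> frozenset[str]:
    """ADRs reachable from two or more drugs of the combination."""
    return frozenset(
        a for a in sub.adrs if len(sub.drug_sources(a)) >= 2
    )


@dataclass(frozen=True)
class AdrModeProfile:
    """How the drugs of a combination reach one ADR."""

    adr: str
    drug_sources: frozenset[str]
    mode1_go: frozenset[str]
    mode2_go: frozenset[str]

    @property
    def composite(self) -> bool:
        return len(self.drug_sources) >= 2


def mode_profile(sub: CombinationSubgraph, adr: str) -> AdrModeProfile:
    """Classify each GO parent of ``adr`` as mode 1, mode 2, or neither.

    A parent g is mode 1 when ≥2 combination drugs perturb it; mode 2
    when exactly one drug perturbs it and the other parents of the ADR
    jointly contribute at least one different drug.  For a composite ADR
    the two classes partition its GO parents.
    """
    if adr not in sub.go_parents:
        raise KeyError(f"ADR {adr!r} is not in this combination subgraph")
    parents = sub.go_parents[adr]
    mode1, mode2 = set(), set()
    for g in parents:
        dg = sub.drugs_of_go[g]
        if len(dg) >= 2:
            mode1.add(g)
        else:
            others: set[str] = set()
            for h in parents:
                if h != g:
                    others |= sub.drugs_of_go[h]
            if others - dg:
                mode2.add(g)
    return AdrModeProfile(
        adr=adr,
        drug_sources=sub.drug_sources(adr),
        mode1_go=frozenset(mode1),
        mode2_go=frozenset(mode2),
    )


@dataclass(frozen=True)
class CRM:
    """A composite risk module: connected cADRs plus their GO parents."""

    adrs: frozenset[str]
    go_terms: frozenset[str]

    @property
    def n_adrs(self) -> int:
        return len(self.adrs)

    @property
    def n_go(self) -> int:
        return len(self.go_terms)

    @property
    def size(self) -> int:
        return self.n_adrs + self.n_go

    def as_dict(self) -> dict:
        return {
            "adrs": sorted(self.adrs),
            "go_terms": sorted(self.go_terms),
            "n_adrs": self.n_adrs,
            "n_go": self.n_go,
            "size": self.size,
        }


def risk_modules(
    sub: CombinationSubgraph, all_adrs: bool = False
) -> list[CRM]:
    """Connected components of the drug-removed GO/ADR association graph.

    Restricted to composite ADRs and their GO parents (pass
    ``all_adrs=True`` to include every ADR of the subgraph); edge
    direction is ignored, since modules are association sets.  Sorted
    descending by (ADR count, GO count), ties broken by smallest member.
    """
    adrs = sub.adrs if all_adrs else composite_adrs(sub)
    g = nx.Graph()
    g.add_nodes_from(adrs)
    for a in adrs:
        for parent in sub.go_parents[a]:
            g.add_edge(parent, a)
    modules = []
    for comp in nx.connected_components(g):
        mod_adrs = frozenset(comp & adrs)
        modules.append(CRM(adrs=mod_adrs, go_terms=frozenset(comp - mod_adrs)))
    modules.sort(key=lambda m: (-m.n_adrs, -m.n_go, min(m.adrs | m.go_terms)))
    return modules


@dataclass
class CombinationReport:
    """All combination-level metrics for one drug set."""

    drugs: tuple[str, ...]
    n_go: int
    n_adrs: int
    cadrs: tuple[str, ...]
    mode1_go: tuple[str, ...]
    mode2_go: tuple[str, ...]
    crms: list[CRM] = field(default_factory=list)

    @property
    def n_cadrs(self) -> int:
        return len(self.cadrs)

    @property
    def n_mode1_go(self) -> int:
        return len(self.mode1_go)

    @property
    def n_mode2_go(self) -> int:
        return len(self.mode2_go)

    @property
    def n_crms(self) -> int:
        return len(self.crms)

    @property
    def largest_crm(self) -> CRM | None:
        return self.crms[0] if self.crms else None

    def as_dict(self) -> dict:
        largest = self.largest_crm
        return {
            "schema_version": 1,
            "drugs": list(self.drugs),
            "go_terms": self.n_go,
            "adrs": self.n_adrs,
            "cadrs": list(self.cadrs),
            "n_cadrs": self.n_cadrs,
            "mode1_go": list(self.mode1_go),
            "mode2_go": list(self.mode2_go),
            "n_mode1_go": self.n_mode1_go,
            "n_mode2_go": self.n_mode2_go,
            "n_crms": self.n_crms,
            "largest_crm": largest.as_dict() if largest else None,
            "crms": [m.as_dict() for m in self.crms],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.as_dict(), indent=indent, sort_keys=False)

    def to_tsv(self) -> str:
        """Flat key/value TSV view of the scalar metrics."""
        largest = self.largest_crm
        rows = [
            ("drugs", ",".join(self.drugs)),
            ("go_terms", self.n_go),
            ("adrs", self.n_adrs),
            ("cadrs", self.n_cadrs),
            ("mode1_go_nodes", self.n_mode1_go),
            ("mode2_go_nodes", self.n_mode2_go),
            ("crms", self.n_crms),
            (
                "largest_crm",
                f"{largest.size} ({largest.n_adrs}/{largest.n_go})"
                if largest
                else "0 (0/0)",
            ),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def report(
    net: TripartiteNetwork, drugs: Iterable[str], all_adrs: bool = False
) -> CombinationReport:
    """Full combination analysis of a drug set against a network."""
    sub = combination_subgraph(net, drugs)
    cadrs = composite_adrs(sub)
    mode1: set[str] = set()
    mode2: set[str] = set()
    for a in cadrs:
        prof = mode_profile(sub, a)
        mode1 |= prof.mode1_go
        mode2 |= prof.mode2_go
    return CombinationReport(
        drugs=tuple(sorted(sub.drugs)),
        n_go=len(sub.go_terms),
        n_adrs=len(sub.adrs),
        cadrs=tuple(sorted(cadrs)),
        mode1_go=tuple(sorted(mode1)),
        mode2_go=tuple(sorted(mode2)),
        crms=risk_modules(sub, all_adrs=all_adrs),
    )
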