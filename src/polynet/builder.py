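"""Assemble the tripartite network from its two bipartite layers.

The drug→GO layer is derived from a perturbation table by running a
per-drug selector (ABC analysis by default); the GO→ADR layer is an
externally supplied association edge list.  Merging orients all edges
drug→GO→ADR and, unless disabled, prunes GO terms that lack either an
incoming drug edge or an outgoing ADR edge — such terms carry no
drug-to-reaction path and are uninformative.  Pruning cascades to drugs
and ADRs left isolated by the GO removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .abc_analysis import (
    AbcError,
    PerturbationTable,
    make_selector,
    to_importance,
)
from .graph import EdgeTable, NodeKind, TripartiteNetwork, ValidationError

__all__ = [
    "BuildConfig",
    "NetworkSummary",
    "build_drug_go",
    "merge_tripartite",
    "prune",
    "summary",
]


@dataclass
class BuildConfig:
    """How to turn a perturbation table into drug→GO edges.

    ``selector``/``selector_params`` choose the per-drug GO-term filter;
    ``weight_policy`` is ``"binary"`` (all edges weight 1.0 — the default
    "may perturb" semantics) or ``"importance"`` (edge weight = the
    transformed importance of the selected term).  ``prune`` applies the
    merge-time GO pruning.
    """

    selector: str = "abc"
    selector_params: dict = field(default_factory=dict)
    weight_policy: str = "binary"
    prune: bool = True

    def __post_init__(self) -> None:
        if self.weight_policy not in ("binary", "importance"):
            raise ValueError(
                f"weight_policy must be 'binary' or 'importance', "
                f"got {self.weight_policy!r}"
            )
        # fail early on bad selector parameters
        make_selector(self.selector, **dict(self.selector_params))


def build_drug_go(
    table: PerturbationTable, cfg: BuildConfig | None = None
) -> EdgeTable:
    """One drug→GO edge per (drug, selected GO term).

    Drugs whose rows carry no usable signal are skipped; their
    identifiers are collected on the returned table's
    ``skipped_sources`` and reported in a warning.
    """
    cfg = cfg or BuildConfig()
    selector = make_selector(cfg.selector, **dict(cfg.selector_params))
    rows: list[tuple[str, str, float]] = []
    skipped: list[str] = []
    for drug in table.drugs:
        sig = table.row(drug)
        if sig.empty:
            skipped.append(drug)
            continue
        try:
            selected = selector(sig, table.value_kind)
        except AbcError:
            skipped.append(drug)
            continue
        if cfg.weight_policy == "importance":
            imp = dict(
                zip(
                    sig.index.astype(str),
                    to_importance(sig.to_numpy(), table.value_kind),
                )
            )
            rows.extend((drug, go, imp[go]) for go in sorted(selected))
        else:
            rows.extend((drug, go, 1.0) for go in sorted(selected))
    if skipped:
        warnings.warn(
            f"{len(skipped)} drug(s) skipped for lack of signal: "
            + ", ".join(skipped[:5])
            + ("..." if len(skipped) > 5 else ""),
            stacklevel=2,
        )
    import pandas as pd

    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    return EdgeTable(df, (NodeKind.DRUG, NodeKind.GO), skipped_sources=skipped)


def merge_tripartite(
    drug_go: EdgeTable, go_adr: EdgeTable, prune_network: bool = True
) -> TripartiteNetwork:
    """Merge the two bipartite layers into one directed tripartite network.

    Raises :class:`ValidationError` if an identifier appears in two
    different layers (case-insensitively).  With ``prune_network`` on,
    GO terms not linked to at least one drug and one ADR are removed,
    then drugs/ADRs left without edges.
    """
    if drug_go.layer != (NodeKind.DRUG, NodeKind.GO):
        raise ValidationError("first table must be the drug->go layer")
    if go_adr.layer != (NodeKind.GO, NodeKind.ADR):
        raise ValidationError("second table must be the go->adr layer")

    layer_members = {
        NodeKind.DRUG: drug_go.sources,
        NodeKind.GO: drug_go.targets | go_adr.sources,
        NodeKind.ADR: go_adr.targets,
    }
    seen: dict[str, tuple[str, NodeKind]] = {}
    for kind, members in layer_members.items():
        for m in members:
            key = m.casefold()
            if key in seen and seen[key][1] is not kind:
                other, other_kind = seen[key]
                raise ValidationError(
                    f"identifier {m!r} appears in layer {kind.value} and as "
                    f"{other!r} in layer {other_kind.value}"
                )
            seen.setdefault(key, (m, kind))

    net = TripartiteNetwork()
    for kind, members in layer_members.items():
        for m in sorted(members):
            net.add_node(m, kind)
    for u, v, w in drug_go.rows():
        net.add_edge(u, v, w)
    for u, v, w in go_adr.rows():
        net.add_edge(u, v, w)

    if prune_network:
        net = prune(net)
        if net.n_nodes == 0:
            warnings.warn(
                "network is empty after pruning: the two layers share no "
                "informative GO terms",
                stacklevel=2,
            )
    return net


def prune(net: TripartiteNetwork) -> TripartiteNetwork:
    """Remove uninformative GO terms, then isolated drugs and ADRs.

    A GO term is uninformative when it lacks an incoming drug edge or an
    outgoing ADR edge.  Idempotent.
    """
    net = net.copy()
    for go in sorted(net.go_terms):
        if not net.predecessors(go) or not net.successors(go):
            net.remove_node(go)
    for outer in sorted(net.drugs | net.adrs):
        if not net.predecessors(outer) and not net.successors(outer):
            net.remove_node(outer)
    return net


@dataclass(frozen=True)
class NetworkSummary:
    """Layer and edge counts of a tripartite network."""

    n_drugs: int
    n_go: int
    n_adrs: int
    n_drug_go_edges: int
    n_go_adr_edges: int

    def as_dict(self) -> dict[str, int]:
        return {
            "drug_nodes": self.n_drugs,
            "go_nodes": self.n_go,
            "adr_nodes": self.n_adrs,
            "drug_go_edges": self.n_drug_go_edges,
            "go_adr_edges": self.n_go_adr_edges,
        }


def summary(net: TripartiteNetwork) -> NetworkSummary:
    """Count nodes per layer and edges per layer pair."""
    n_dg = n_ga = 0
    for u, _v, _w in net.edges():
        if net.kind(u) is NodeKind.DRUG:
            n_dg += 1
        else:
            n_ga += 1
    return NetworkSummary(
        n_drugs=len(net.drugs),
        n_go=len(net.go_terms),
        n_adrs=len(net.adrs),
        n_drug_go_edges=n_dg,
        n_go_adr_edges=n_ga,
    )
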