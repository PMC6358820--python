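"""Typed tripartite drug–function–ADR network container and GML/TSV I/O.

The central object is :class:`TripartiteNetwork`, a directed acyclic graph
with three node layers — drugs, Gene Ontology (GO) terms standing in for
biological functions, and adverse drug reactions (ADRs) — in which every
edge points either drug→GO ("the drug may perturb this function") or
GO→ADR ("perturbing this function may manifest this reaction").  Every
maximal directed path therefore has length exactly two, and each such path
is one candidate mechanism by which a drug may produce an adverse reaction.

The container wraps :class:`networkx.DiGraph`; node identity is the label
string (case preserved, matched case-insensitively on read), edges carry a
non-negative ``weight`` defaulting to 1.0 (binary "may perturb"/"may
manifest" semantics).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

__all__ = [
    "NodeKind",
    "TripartiteNetwork",
    "EdgeTable",
    "ValidationError",
    "read_gml",
    "write_gml",
    "read_edge_table",
    "write_edge_table",
    "validate",
]


class ValidationError(ValueError):
    """A network or edge table violates the tripartite model's invariants."""


class NodeKind(enum.Enum):
    """The three node layers of the tripartite network."""

    DRUG = "drug"
    GO = "go"
    ADR = "adr"

    @classmethod
    def parse(cls, value: "str | NodeKind") -> "NodeKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown node kind {value!r}; expected one of drug/go/adr"
            ) from None


#: permitted (source kind, target kind) pairs
_ALLOWED_LAYERS = {
    (NodeKind.DRUG, NodeKind.GO),
    (NodeKind.GO, NodeKind.ADR),
}


class TripartiteNetwork:
    """Directed acyclic drug→GO→ADR network with typed layers.

    Nodes are identified by their label string.  Labels are matched
    case-insensitively: adding ``"Aspirin"`` and ``"aspirin"`` as distinct
    nodes raises :class:`ValidationError`.  Adding an edge twice collapses
    the duplicates by summing weights (the model has no multi-edge
    semantics) and emits a warning.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()
        self._casefold: dict[str, str] = {}

    # -- construction ---------------------------------------------------

    def add_node(self, node_id: str, kind: "NodeKind | str") -> None:
        kind = NodeKind.parse(kind)
        node_id = str(node_id)
        key = node_id.casefold()
        existing = self._casefold.get(key)
        if existing is not None:
            if existing != node_id:
                raise ValidationError(
                    f"node label {node_id!r} collides case-insensitively "
                    f"with existing node {existing!r}"
                )
            if self.kind(existing) is not kind:
                raise ValidationError(
                    f"node {node_id!r} already present with kind "
                    f"{self.kind(existing).value!r}, cannot re-add as {kind.value!r}"
                )
            return
        self._casefold[key] = node_id
        self._g.add_node(node_id, kind=kind)

    def add_edge(self, source: str, target: str, weight: float = 1.0) -> None:
        source, target = str(source), str(target)
        for n in (source, target):
            if n not in self._g:
                raise ValidationError(f"edge endpoint {n!r} is not a node")
        pair = (self.kind(source), self.kind(target))
        if pair not in _ALLOWED_LAYERS:
            raise ValidationError(
                f"edge {source!r}->{target!r} connects layers "
                f"{pair[0].value}->{pair[1].value}; only drug->go and "
                "go->adr edges are permitted"
            )
        weight = float(weight)
        if weight < 0:
            raise ValidationError(
                f"edge {source!r}->{target!r} has negative weight {weight}"
            )
        if self._g.has_edge(source, target):
            warnings.warn(
                f"duplicate edge {source!r}->{target!r}: weights summed",
                stacklevel=2,
            )
            self._g[source][target]["weight"] += weight
        else:
            self._g.add_edge(source, target, weight=weight)

    def remove_node(self, node_id: str) -> None:
        self._casefold.pop(str(node_id).casefold(), None)
        self._g.remove_node(node_id)

    def copy(self) -> "TripartiteNetwork":
        new = TripartiteNetwork()
        new._g = self._g.copy()
        new._casefold = dict(self._casefold)
        return new

    # -- inspection -----------------------------------------------------

    def kind(self, node_id: str) -> NodeKind:
        try:
            return self._g.nodes[node_id]["kind"]
        except KeyError:
            raise KeyError(f"unknown node {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def nodes_of_kind(self, kind: "NodeKind | str") -> frozenset[str]:
        kind = NodeKind.parse(kind)
        return frozenset(
            n for n, d in self._g.nodes(data="kind") if d is kind
        )

    @property
    def drugs(self) -> frozenset[str]:
        return self.nodes_of_kind(NodeKind.DRUG)

    @property
    def go_terms(self) -> frozenset[str]:
        return self.nodes_of_kind(NodeKind.GO)

    @property
    def adrs(self) -> frozenset[str]:
        return self.nodes_of_kind(NodeKind.ADR)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def successors(self, node_id: str) -> frozenset[str]:
        return frozenset(self._g.successors(node_id))

    def predecessors(self, node_id: str) -> frozenset[str]:
        return frozenset(self._g.predecessors(node_id))

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, w in self._g.edges(data="weight", default=1.0):
            yield u, v, w

    def edge_weight(self, source: str, target: str) -> float:
        return self._g[source][target]["weight"]

    def has_edge(self, source: str, target: str) -> bool:
        return self._g.has_edge(source, target)

    def to_networkx(self) -> nx.DiGraph:
        """A copy as a plain DiGraph (node attr ``kind`` as NodeKind)."""
        return self._g.copy()

    # -- comparison (used heavily by round-trip tests) ------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripartiteNetwork):
            return NotImplemented
        mine = {(n, self.kind(n)) for n in self._g}
        theirs = {(n, other.kind(n)) for n in other._g}
        return mine == theirs and set(self.edges()) == set(other.edges())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<TripartiteNetwork {len(self.drugs)} drugs, "
            f"{len(self.go_terms)} GO, {len(self.adrs)} ADRs, "
            f"{self.n_edges} edges>"
        )

    # -- bulk constructor ------------------------------------------------

    @classmethod
    def from_edge_lists(
        cls,
        drug_go: Iterable[tuple[str, str] | tuple[str, str, float]],
        go_adr: Iterable[tuple[str, str] | tuple[str, str, float]],
    ) -> "TripartiteNetwork":
        net = cls()
        for rows, (ka, kb) in (
            (drug_go, (NodeKind.DRUG, NodeKind.GO)),
            (go_adr, (NodeKind.GO, NodeKind.ADR)),
        ):
            for row in rows:
                u, v, *rest = row
                w = float(rest[0]) if rest else 1.0
                net.add_node(u, ka)
                net.add_node(v, kb)
                net.add_edge(u, v, w)
        return net


# ---------------------------------------------------------------------------
# Edge tables
# ---------------------------------------------------------------------------


@dataclass
class EdgeTable:
    """A single bipartite layer as a (source, target, weight) table."""

    data: pd.DataFrame
    layer: tuple[NodeKind, NodeKind]
    skipped_sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"source", "target"}
        if not required.issubset(self.data.columns):
            raise ValidationError(
                f"edge table needs columns {sorted(required)}, "
                f"got {list(self.data.columns)}"
            )
        layer = (NodeKind.parse(self.layer[0]), NodeKind.parse(self.layer[1]))
        if layer not in _ALLOWED_LAYERS:
            raise ValidationError(
                f"layer pair {layer[0].value}->{layer[1].value} is not "
                "drug->go or go->adr"
            )
        self.layer = layer
        df = self.data.copy()
        df["source"] = df["source"].astype(str)
        df["target"] = df["target"].astype(str)
        if "weight" not in df.columns:
            df["weight"] = 1.0
        df["weight"] = df["weight"].astype(float)
        if (df["weight"] < 0).any():
            bad = df.loc[df["weight"] < 0, ["source", "target"]]
            raise ValidationError(
                "negative weights on pairs: "
                + ", ".join(f"{r.source}->{r.target}" for r in bad.itertuples())
            )
        dup = df.duplicated(subset=["source", "target"], keep=False)
        if dup.any():
            pairs = sorted(
                set(map(tuple, df.loc[dup, ["source", "target"]].values))
            )
            raise ValidationError(
                "duplicate (source, target) pairs: "
                + ", ".join(f"{u}->{v}" for u, v in pairs)
            )
        self.data = df[["source", "target", "weight"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(self.data["source"])

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self.data["target"])

    def rows(self) -> Iterator[tuple[str, str, float]]:
        for r in self.data.itertuples(index=False):
            yield r.source, r.target, r.weight

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str] | tuple[str, str, float]],
        layer: tuple["NodeKind | str", "NodeKind | str"],
    ) -> "EdgeTable":
        recs = []
        for row in pairs:
            u, v, *rest = row
            recs.append((u, v, float(rest[0]) if rest else 1.0))
        df = pd.DataFrame(recs, columns=["source", "target", "weight"])
        return cls(df, tuple(NodeKind.parse(k) for k in layer))


def read_edge_table(
    path: "str | Path", layer: tuple["NodeKind | str", "NodeKind | str"]
) -> EdgeTable:
    """Read one bipartite layer from a TSV/CSV file.

    The file must have a header row with ``source`` and ``target`` columns
    and optionally ``weight`` (missing ⇒ all weights 1.0).  ``.csv`` files
    are comma-delimited, everything else tab-delimited.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"source": str, "target": str})
    return EdgeTable(df, tuple(NodeKind.parse(k) for k in layer))


def write_edge_table(table: EdgeTable, path: "str | Path") -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# GML I/O
# ---------------------------------------------------------------------------

_KIND_ATTR = "type"  # GML node attribute naming the layer


def write_gml(net: TripartiteNetwork, path: "str | Path") -> None:
    """Write a network as directed GML with byte-reproducible node order.

    Nodes are emitted drugs first, then GO terms, then ADRs, each block
    lexicographically sorted; node attributes are ``id``, ``label`` and
    ``type`` ("drug"/"go"/"adr").
    """
    g = nx.DiGraph()
    for kind in (NodeKind.DRUG, NodeKind.GO, NodeKind.ADR):
        for n in sorted(net.nodes_of_kind(kind)):
            g.add_node(n, **{_KIND_ATTR: kind.value})
    for u, v, w in sorted(net.edges()):
        g.add_edge(u, v, weight=float(w))
    nx.write_gml(g, str(path))


def _infer_kinds_structurally(g: nx.DiGraph) -> dict[str, NodeKind]:
    kinds: dict[str, NodeKind] = {}
    for n in g:
        has_in = g.in_degree(n) > 0
        has_out = g.out_degree(n) > 0
        if has_in and has_out:
            kinds[n] = NodeKind.GO
        elif has_out:
            kinds[n] = NodeKind.DRUG
        elif has_in:
            kinds[n] = NodeKind.ADR
        else:
            raise ValidationError(
                f"node {n!r} is isolated and carries no layer attribute; "
                "cannot assign it to a layer"
            )
    return kinds


def read_gml(path: "str | Path") -> TripartiteNetwork:
    """Read a directed GML file into a validated :class:`TripartiteNetwork`.

    Node layers come from the per-node ``type`` attribute
    ("drug"/"go"/"adr", any case).  Nodes lacking the attribute are
    assigned structurally (only outgoing edges ⇒ drug, only incoming ⇒
    ADR, both ⇒ GO) with a warning.  Unknown extra attributes are
    tolerated and ignored.
    """
    try:
        g = nx.read_gml(str(path), label="label")
    except Exception as exc:  # networkx raises several parse error types
        raise ValidationError(f"cannot parse GML file {path}: {exc}") from exc
    if not g.is_directed():
        raise ValidationError(f"GML file {path} is not a directed graph")
    g = nx.DiGraph(g)  # collapse any multigraph

    missing = [n for n, d in g.nodes(data=True) if _KIND_ATTR not in d]
    structural: dict[str, NodeKind] = {}
    if missing:
        warnings.warn(
            f"{len(missing)} node(s) lack a {_KIND_ATTR!r} attribute; "
            "layers inferred from edge direction",
            stacklevel=2,
        )
        structural = _infer_kinds_structurally(g)

    net = TripartiteNetwork()
    for n, d in g.nodes(data=True):
        kind = (
            NodeKind.parse(d[_KIND_ATTR]) if _KIND_ATTR in d else structural[n]
        )
        net.add_node(str(n), kind)
    for u, v, d in g.edges(data=True):
        net.add_edge(str(u), str(v), float(d.get("weight", 1.0)))

    problems = validate(net)
    if problems:
        raise ValidationError(
            f"GML file {path} violates the tripartite model: "
            + "; ".join(problems)
        )
    return net


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate(net: TripartiteNetwork, strict: bool = False) -> list[str]:
    """Check the tripartite invariants; return a list of violations.

    Always checked: edges connect only drug→GO or GO→ADR; the graph is
    acyclic (hence every maximal path has length ≤ 2).  With
    ``strict=True`` the post-pruning invariants are also enforced: every
    GO node must have at least one incoming drug edge and one outgoing
    ADR edge, and no drug or ADR node may be isolated.
    """
    g = net._g
    violations: list[str] = []
    for u, v in g.edges():
        pair = (net.kind(u), net.kind(v))
        if pair not in _ALLOWED_LAYERS:
            violations.append(
                f"edge {u!r}->{v!r} connects {pair[0].value}->{pair[1].value}"
            )
    if not nx.is_directed_acyclic_graph(g):
        violations.append("graph contains a directed cycle")
    if strict:
        for n in sorted(net.go_terms):
            if g.in_degree(n) == 0:
                violations.append(f"GO node {n!r} has no incoming drug edge")
            if g.out_degree(n) == 0:
                violations.append(f"GO node {n!r} has no outgoing ADR edge")
        for n in sorted(net.drugs):
            if g.out_degree(n) == 0:
                violations.append(f"drug node {n!r} is isolated")
        for n in sorted(net.adrs):
            if g.in_degree(n) == 0:
                violations.append(f"ADR node {n!r} is isolated")
    return violations
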