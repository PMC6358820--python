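"""Additive ADR-activity scores for drug combinations.

For a combination D and a reaction a, the activity is the weighted sum
over the GO parents g of a inside the combination subgraph:

    Activity(a) = Σ_g Activity(a|g) · Σ_{d ∈ D(g)} Perturbation(g|d)

where D(g) are the combination drugs perturbing g.  This general form
contains the two pure configurations as special cases — a single shared
pathway (mode 1) and disjoint per-drug pathways (mode 2).  With unit
weights (the default, since the underlying network is unweighted) the
activity is exactly the number of distinct drug→GO→ADR paths from the
combination to the reaction, an interpretable relative-risk proxy.

Weights can be supplied separately from the graph so experimentally
derived perturbation/activity values can be explored without rebuilding
the network; an absent key falls back to the stored edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .combination import CombinationSubgraph, combination_subgraph
from .graph import TripartiteNetwork

__all__ = ["ActivityWeights", "adr_activity", "activity_table"]


@dataclass
class ActivityWeights:
    """Optional overrides for edge weights in the activity model.

    ``perturbation`` maps (drug, GO term) to Perturbation(GO|drug);
    ``activity`` maps (GO term, ADR) to Activity(ADR|GO).  Any pair not
    present falls back to the weight stored on the network edge
    (default 1.0).  All values must be non-negative.
    """

    perturbation: Mapping[tuple[str, str], float] = field(default_factory=dict)
    activity: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mapping in (
            ("perturbation", self.perturbation),
            ("activity", self.activity),
        ):
            for key, w in mapping.items():
                if float(w) < 0:
                    raise ValueError(
                        f"{name} weight for {key} is negative ({w})"
                    )

    @classmethod
    def from_tsv(cls, path: "str | Path") -> "ActivityWeights":
        """Read weights from a TSV with columns layer (dg|ga), source, target, weight."""
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        needed = {"layer", "source", "target", "weight"}
        if not needed.issubset(df.columns):
            raise ValueError(
                f"weights file needs columns {sorted(needed)}, got "
                f"{list(df.columns)}"
            )
        pert: dict[tuple[str, str], float] = {}
        act: dict[tuple[str, str], float] = {}
        for r in df.itertuples(index=False):
            layer = str(r.layer).lower()
            if layer == "dg":
                pert[(r.source, r.target)] = float(r.weight)
            elif layer == "ga":
                act[(r.source, r.target)] = float(r.weight)
            else:
                raise ValueError(f"unknown layer {r.layer!r}; expected dg or ga")
        return cls(perturbation=pert, activity=act)


def _resolve(
    weights: ActivityWeights | None,
    which: str,
    pair: tuple[str, str],
    stored: float,
) -> float:
    if weights is None:
        return stored
    mapping = weights.perturbation if which == "perturbation" else weights.activity
    return float(mapping.get(pair, stored))


def adr_activity(
    net: TripartiteNetwork,
    drugs: Iterable[str],
    adr: str,
    weights: ActivityWeights | None = None,
    _sub: CombinationSubgraph | None = None,
) -> float:
    """Additive activity of one ADR under a drug combination.

    Zero when no combination drug has a path to the ADR.  With all-unit
    weights this equals the number of distinct drug→GO→ADR paths.
    """
    sub = _sub if _sub is not None else combination_subgraph(net, drugs)
    adr = str(adr)
    if adr not in net.adrs:
        raise KeyError(f"unknown ADR node {adr!r}")
    parents = sub.go_parents.get(adr, frozenset())
    total = 0.0
    for g in parents:
        act = _resolve(weights, "activity", (g, adr), sub.network.edge_weight(g, adr))
        pert_sum = sum(
            _resolve(
                weights, "perturbation", (d, g), sub.network.edge_weight(d, g)
            )
            for d in sub.drugs_of_go[g]
        )
        total += act * pert_sum
    return total


def activity_table(
    net: TripartiteNetwork,
    drugs: Iterable[str],
    weights: ActivityWeights | None = None,
) -> pd.Series:
    """Activity of every ADR in the combination subgraph.

    Returns a Series indexed by ADR, sorted by descending activity then
    ascending identifier.  Empty drug set ⇒ empty table.
    """
    drugs = list(drugs)
    if not drugs:
        return pd.Series(dtype=float, name="activity")
    sub = combination_subgraph(net, drugs)
    values = {
        a: adr_activity(net, drugs, a, weights=weights, _sub=sub)
        for a in sub.adrs
    }
    s = pd.Series(values, name="activity", dtype=float)
    order = sorted(s.index, key=lambda a: (-s[a], a))
    return s.loc[order]
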