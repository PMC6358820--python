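"""Synthetic tripartite networks and perturbation tables with known truth.

Generators for the two inputs of the pipeline, at configurable scale and
with planted structure, so every stage is testable without external
downloads:

* :func:`synth_network` draws the two bipartite layers as independent
  Bernoulli edges and optionally plants dense drug/GO/ADR modules
  (complete blocks).  Default layer densities are scaled from the
  published full network (≈0.23 for drug→GO, ≈0.012 for GO→ADR); the
  default CI-friendly scale is 100 drugs × 50 GO terms × 30 ADRs, with
  the full study scale available by passing the corresponding sizes.
* :func:`synth_perturbation_table` gives each drug a designated signal
  GO subset with small p-values (log-uniform over [1e-12, 1e-4] by
  default) against a uniform(0.05, 1) background.  The default signal
  size is 20% of the GO vocabulary, matching the selected-terms fraction
  implied by the full network's edge counts (≈75 of 323 terms per drug).

Every generator is driven by a single :class:`numpy.random.Generator`
stream seeded from ``cfg.seed`` (PCG64), so one seed reproduces networks
and tables byte-for-byte.  Ground-truth records accompany each output:
planted memberships, expected risk-module structure (recomputed by a
direct component search on the realised edges, independent of the
analysis code path), and per-drug signal sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .abc_analysis import PerturbationTable
from .builder import merge_tripartite
from .graph import EdgeTable, NodeKind, TripartiteNetwork

__all__ = ["PlantedModule", "SynthConfig", "synth_network", "synth_perturbation_table"]


@dataclass(frozen=True)
class PlantedModule:
    """A dense block: n_drugs × n_go complete + n_go × n_adr complete."""

    n_drugs: int
    n_go: int
    n_adr: int

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_go, self.n_adr) < 1:
            raise ValueError("planted module sizes must be positive")


@dataclass
class SynthConfig:
    """Scale, densities and noise model of the synthetic generators."""

    seed: int = 0
    n_drugs: int = 100
    n_go: int = 50
    n_adr: int = 30
    p_dg: float = 0.23
    p_ga: float = 0.012
    planted: tuple[PlantedModule, ...] = ()
    #: per-drug signal set size; None ⇒ round(0.2 * n_go), min 1
    n_signal: int | None = None
    signal_p: tuple[float, float] = (1e-12, 1e-4)
    background_p: tuple[float, float] = (0.05, 1.0)

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_go, self.n_adr) < 1:
            raise ValueError("layer sizes must be positive")
        for name, p in (("p_dg", self.p_dg), ("p_ga", self.p_ga)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        self.planted = tuple(self.planted)
        if sum(m.n_drugs for m in self.planted) > self.n_drugs:
            raise ValueError("planted drug blocks exceed n_drugs")
        if sum(m.n_go for m in self.planted) > self.n_go:
            raise ValueError("planted GO blocks exceed n_go")
        if sum(m.n_adr for m in self.planted) > self.n_adr:
            raise ValueError("planted ADR blocks exceed n_adr")
        if self.n_signal is not None and not 0 <= self.n_signal <= self.n_go:
            raise ValueError("n_signal must be within [0, n_go]")
        for name, (lo, hi) in (
            ("signal_p", self.signal_p),
            ("background_p", self.background_p),
        ):
            if not (0 < lo <= hi <= 1):
                raise ValueError(f"{name} bounds must satisfy 0 < lo <= hi <= 1")

    @property
    def resolved_n_signal(self) -> int:
        if self.n_signal is not None:
            return self.n_signal
        return max(1, round(0.2 * self.n_go))

    def drug_names(self) -> list[str]:
        return [f"drug{i:04d}" for i in range(self.n_drugs)]

    def go_names(self) -> list[str]:
        return [f"GO:{i + 1:07d}" for i in range(self.n_go)]

    def adr_names(self) -> list[str]:
        return [f"adr{i:03d}" for i in range(self.n_adr)]


# ---------------------------------------------------------------------------
# Network generator
# ---------------------------------------------------------------------------


def _brute_components_after_drug_removal(
    dg: np.ndarray, ga: np.ndarray, drug_idx: Sequence[int]
) -> list[tuple[frozenset[int], frozenset[int]]]:
    """Composite-ADR risk modules by direct search on adjacency matrices.

    Deliberately written against the raw boolean matrices (not the graph
    classes) so generator ground truth does not share code with the
    analysis path.  Returns (adr index set, go index set) per module,
    sorted by size descending.
    """
    drug_idx = list(drug_idx)
    go_reached = {g for d in drug_idx for g in np.nonzero(dg[d])[0]}
    adr_drugs: dict[int, set[int]] = {}
    adr_gos: dict[int, set[int]] = {}
    for g in go_reached:
        drugs_here = {d for d in drug_idx if dg[d, g]}
        for a in np.nonzero(ga[g])[0]:
            adr_drugs.setdefault(a, set()).update(drugs_here)
            adr_gos.setdefault(a, set()).add(g)
    cadrs = {a for a, ds in adr_drugs.items() if len(ds) >= 2}
    # union-find over cADRs and their GO parents
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for a in cadrs:
        parent.setdefault(("adr", a), ("adr", a))
        for g in adr_gos[a]:
            union(("adr", a), ("go", g))
    groups: dict[tuple[str, int], tuple[set[int], set[int]]] = {}
    for node in parent:
        root = find(node)
        adrs, gos = groups.setdefault(root, (set(), set()))
        (adrs if node[0] == "adr" else gos).add(node[1])
    modules = [
        (frozenset(adrs), frozenset(gos)) for adrs, gos in groups.values()
    ]
    modules.sort(key=lambda m: (-len(m[0]), -len(m[1]), sorted(m[0] | m[1])))
    return modules


def synth_network(cfg: SynthConfig) -> tuple[TripartiteNetwork, dict]:
    """Draw a random tripartite network plus its ground-truth record.

    Planted modules occupy consecutive index blocks from the start of
    each layer and are complete within themselves on both layers, on top
    of the Bernoulli background.  The returned network is merged with
    pruning, so it satisfies the strict tripartite invariants.  The
    truth record carries the generator config, planted memberships, and
    the exact risk-module structure for the combination of all planted
    drugs, recomputed by brute force on the realised adjacency matrices.
    """
    rng = np.random.default_rng(cfg.seed)
    dg = rng.random((cfg.n_drugs, cfg.n_go)) < cfg.p_dg
    ga = rng.random((cfg.n_go, cfg.n_adr)) < cfg.p_ga

    planted_records = []
    d0 = g0 = a0 = 0
    for mod in cfg.planted:
        ds = range(d0, d0 + mod.n_drugs)
        gs = range(g0, g0 + mod.n_go)
        as_ = range(a0, a0 + mod.n_adr)
        dg[np.ix_(list(ds), list(gs))] = True
        ga[np.ix_(list(gs), list(as_))] = True
        planted_records.append(
            {"drugs": list(ds), "go": list(gs), "adrs": list(as_)}
        )
        d0 += mod.n_drugs
        g0 += mod.n_go
        a0 += mod.n_adr

    drug_names = cfg.drug_names()
    go_names = cfg.go_names()
    adr_names = cfg.adr_names()
    dg_pairs = [
        (drug_names[d], go_names[g]) for d, g in zip(*np.nonzero(dg))
    ]
    ga_pairs = [(go_names[g], adr_names[a]) for g, a in zip(*np.nonzero(ga))]

    if dg_pairs and ga_pairs:
        net = merge_tripartite(
            EdgeTable.from_pairs(dg_pairs, (NodeKind.DRUG, NodeKind.GO)),
            EdgeTable.from_pairs(ga_pairs, (NodeKind.GO, NodeKind.ADR)),
            prune_network=True,
        )
    else:
        net = TripartiteNetwork()  # nothing survives pruning anyway

    truth: dict = {
        "generator": "numpy.random.Generator(PCG64)",
        "seed": cfg.seed,
        "n_drugs": cfg.n_drugs,
        "n_go": cfg.n_go,
        "n_adr": cfg.n_adr,
        "p_dg": cfg.p_dg,
        "p_ga": cfg.p_ga,
        "n_dg_edges": int(dg.sum()),
        "n_ga_edges": int(ga.sum()),
        "planted": [
            {
                "drugs": [drug_names[i] for i in rec["drugs"]],
                "go": [go_names[i] for i in rec["go"]],
                "adrs": [adr_names[i] for i in rec["adrs"]],
            }
            for rec in planted_records
        ],
    }
    if planted_records:
        all_planted_drugs = [i for rec in planted_records for i in rec["drugs"]]
        modules = _brute_components_after_drug_removal(dg, ga, all_planted_drugs)
        truth["expected_crms"] = [
            {
                "adrs": sorted(adr_names[i] for i in adrs),
                "go_terms": sorted(go_names[i] for i in gos),
            }
            for adrs, gos in modules
        ]
    return net, truth


# ---------------------------------------------------------------------------
# Perturbation-table generator
# ---------------------------------------------------------------------------


def synth_perturbation_table(
    cfg: SynthConfig,
) -> tuple[PerturbationTable, dict]:
    """Draw a drug × GO p-value table with planted per-drug signal sets.

    Each drug gets ``cfg.resolved_n_signal`` signal terms (chosen
    uniformly without replacement) whose p-values are log-uniform over
    ``cfg.signal_p``; all other terms draw from
    uniform(``cfg.background_p``).  The truth record maps each drug to
    its signal set.
    """
    rng = np.random.default_rng(cfg.seed)
    drug_names = cfg.drug_names()
    go_names = np.array(cfg.go_names())
    k = cfg.resolved_n_signal
    lo, hi = np.log10(cfg.signal_p[0]), np.log10(cfg.signal_p[1])

    values = rng.uniform(
        cfg.background_p[0], cfg.background_p[1], size=(cfg.n_drugs, cfg.n_go)
    )
    signals: dict[str, list[str]] = {}
    for i, drug in enumerate(drug_names):
        idx = rng.choice(cfg.n_go, size=k, replace=False) if k else np.array([], int)
        values[i, idx] = 10.0 ** rng.uniform(lo, hi, size=k)
        signals[drug] = sorted(go_names[idx])

    table = PerturbationTable(
        pd.DataFrame(values, index=drug_names, columns=go_names),
        value_kind="pvalue",
    )
    truth = {
        "generator": "numpy.random.Generator(PCG64)",
        "seed": cfg.seed,
        "n_signal": k,
        "signal_p": list(cfg.signal_p),
        "background_p": list(cfg.background_p),
        "signals": signals,
    }
    return table, truth
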