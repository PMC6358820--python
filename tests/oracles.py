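"""Independent brute-force oracles used to cross-check the package.

Everything here is written with plain loops over raw edge lists and
prefix points — deliberately sharing no code with the package's
implementation — so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence


# ---------------------------------------------------------------------------
# ABC partition by exhaustive boundary search
# ---------------------------------------------------------------------------


def brute_abc_boundaries(
    importances: Sequence[float], items: Sequence[str]
) -> tuple[int, int, list[str]]:
    """(iab, ibc, ranked items) by evaluating every candidate boundary.

    Ranks descending by importance with identifier tie-break, then scans
    all n prefix points for the minimum distance to (0, 1) and the last
    break-even slope.
    """
    pairs = sorted(zip(importances, items), key=lambda t: (-t[0], t[1]))
    ranked = [p[1] for p in pairs]
    vals = [p[0] for p in pairs]
    n = len(vals)
    total = sum(vals)
    assert total > 0, "oracle needs positive total importance"
    best_i, best_d = None, None
    cum = 0.0
    for i in range(1, n + 1):
        cum += vals[i - 1]
        x = i / n
        y = cum / total
        d = math.hypot(x, 1.0 - y)
        if best_d is None or d < best_d - 1e-15:
            best_i, best_d = i, d
    ibc = 0
    for i in range(1, n + 1):
        slope = (vals[i - 1] / total) / (1.0 / n)
        if slope >= 1.0:
            ibc = i
    if ibc < best_i:
        ibc = best_i
    return best_i, ibc, ranked


# ---------------------------------------------------------------------------
# Combination analysis by exhaustive path enumeration
# ---------------------------------------------------------------------------


def enumerate_paths(
    dg_edges: Iterable[tuple[str, str]],
    ga_edges: Iterable[tuple[str, str]],
    drugs: Iterable[str],
) -> list[tuple[str, str, str]]:
    """All drug→GO→ADR paths starting from the given drug set."""
    drugs = set(drugs)
    dg = [(d, g) for d, g in dg_edges if d in drugs]
    paths = []
    for d, g in dg:
        for g2, a in ga_edges:
            if g2 == g:
                paths.append((d, g, a))
    return paths


def brute_combination(
    dg_edges: Sequence[tuple[str, str]],
    ga_edges: Sequence[tuple[str, str]],
    drugs: Iterable[str],
) -> dict:
    """cADRs, per-ADR mode sets, CRM partition and path-count activities."""
    drugs = set(drugs)
    paths = enumerate_paths(dg_edges, ga_edges, drugs)

    sub_go = {g for _d, g in dg_edges if _d in drugs}
    sub_adrs = {a for _d, _g, a in paths}
    adr_drugs: dict[str, set[str]] = {}
    adr_parents: dict[str, set[str]] = {}
    go_drugs: dict[str, set[str]] = {}
    for d, g, a in paths:
        adr_drugs.setdefault(a, set()).add(d)
        adr_parents.setdefault(a, set()).add(g)
        go_drugs.setdefault(g, set()).add(d)

    cadrs = {a for a, ds in adr_drugs.items() if len(ds) >= 2}

    mode1: dict[str, set[str]] = {}
    mode2: dict[str, set[str]] = {}
    for a in sub_adrs:
        m1, m2 = set(), set()
        for g in adr_parents[a]:
            if len(go_drugs[g]) >= 2:
                m1.add(g)
            else:
                other_drugs = set()
                for h in adr_parents[a]:
                    if h != g:
                        other_drugs |= go_drugs[h]
                if other_drugs - go_drugs[g]:
                    m2.add(g)
        mode1[a], mode2[a] = m1, m2

    # CRM partition: BFS over the undirected cADR/GO-parent graph
    members = set(cadrs) | {g for a in cadrs for g in adr_parents[a]}
    adj: dict[str, set[str]] = {m: set() for m in members}
    for a in cadrs:
        for g in adr_parents[a]:
            adj[a].add(g)
            adj[g].add(a)
    seen: set[str] = set()
    crms = set()
    for start in members:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        crms.add(
            (frozenset(comp & cadrs), frozenset(comp - cadrs))
        )

    activities = {a: 0 for a in sub_adrs}
    for _d, _g, a in paths:
        activities[a] += 1

    return {
        "go_terms": sub_go,
        "adrs": sub_adrs,
        "cadrs": cadrs,
        "mode1": mode1,
        "mode2": mode2,
        "crms": crms,
        "activities": activities,
        "adr_drugs": adr_drugs,
    }


# ---------------------------------------------------------------------------
# Random edge-list generator for oracle comparisons
# ---------------------------------------------------------------------------


def random_edge_lists(rng, n_drugs=5, n_go=12, n_adr=8, p_dg=0.35, p_ga=0.25):
    """Small random bipartite layers as plain edge lists."""
    drugs = [f"d{i}" for i in range(n_drugs)]
    gos = [f"g{i}" for i in range(n_go)]
    adrs = [f"a{i}" for i in range(n_adr)]
    dg = [(d, g) for d in drugs for g in gos if rng.random() < p_dg]
    ga = [(g, a) for g in gos for a in adrs if rng.random() < p_ga]
    return drugs, gos, adrs, dg, ga
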