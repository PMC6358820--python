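"""Computed ABC analysis for selecting each drug's most perturbed GO terms.

Each drug comes with a vector of per-GO-term perturbation significances
(e.g. PAEA p-values).  ABC analysis ranks the terms by importance, draws
the cumulative-contribution curve (effort x_i = i/n against yield
y_i = cumulative importance share), and splits the ranking into the
"vital few" set A, an intermediate set B and the "trivial many" set C:

* the A|B boundary is the curve point closest (Euclidean) to the ideal
  point (0, 1) — maximal yield for minimal effort;
* the B|C boundary is the break-even point, the last rank at which the
  discrete slope of the curve is still ≥ 1 (the item still contributes
  at least an average share).

Set A defines the drug→GO edges of the tripartite network.  P-values are
mapped to importances by −log10(p); pre-computed importances pass
through unchanged.  All boundaries operate on the discrete per-item
curve points (no interpolation) and ties in importance are broken by
item identifier, so a given table always yields the same selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbcError",
    "AbcPartition",
    "PerturbationTable",
    "to_importance",
    "abc_curve",
    "abc_partition",
    "select_go_terms",
    "make_selector",
    "load_perturbation_table",
]

VALUE_KINDS = ("pvalue", "importance")


class AbcError(ValueError):
    """Raised when ABC analysis is impossible (e.g. no signal)."""


# ---------------------------------------------------------------------------
# Perturbation table
# ---------------------------------------------------------------------------


@dataclass
class PerturbationTable:
    """Drug × GO-term significance matrix.

    ``data`` holds drugs as the row index and GO identifiers as columns.
    ``value_kind`` declares the cell convention: ``"pvalue"`` (values in
    (0, 1]; smaller = more significant) or ``"importance"`` (non-negative;
    larger = more significant).  NaN cells mean "not perturbed / not
    measured" and are excluded from selection.
    """

    data: pd.DataFrame
    value_kind: str = "pvalue"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        df = self.data
        vals = df.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if self.value_kind == "pvalue":
            if ((finite <= 0) | (finite > 1)).any():
                raise ValueError("p-values must lie in (0, 1]")
        elif (finite < 0).any():
            raise ValueError("importances must be non-negative")
        self.data = df.astype(float)

    @property
    def drugs(self) -> list[str]:
        return [str(d) for d in self.data.index]

    @property
    def go_terms(self) -> list[str]:
        return [str(g) for g in self.data.columns]

    def row(self, drug: str) -> pd.Series:
        """The non-missing significance values for one drug."""
        if drug not in self.data.index:
            raise KeyError(f"unknown drug {drug!r}")
        return self.data.loc[drug].dropna()


def load_perturbation_table(
    path: "str | Path", value_kind: str = "pvalue"
) -> PerturbationTable:
    """Load a table from wide (matrix) or long (drug, go, value) TSV/CSV.

    Wide format: first column = drug id, header row = GO ids.  Long
    format is detected by exactly three columns named drug/go/value (any
    order of synonyms source/target/weight is not accepted here to avoid
    ambiguity with edge tables).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3 and set(cols) == {"drug", "go", "value"}:
        df.columns = cols
        wide = df.pivot(index="drug", columns="go", values="value")
        return PerturbationTable(wide, value_kind)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return PerturbationTable(df, value_kind)


# ---------------------------------------------------------------------------
# Importance transform
# ---------------------------------------------------------------------------


def to_importance(
    values: Sequence[float] | np.ndarray, value_kind: str = "pvalue"
) -> np.ndarray:
    """Map significance values to non-negative importances, order preserved.

    P-values become −log10(p) (p = 1 ⇒ importance 0); importances pass
    through.  p = 0, which −log10 cannot represent, is clipped to the
    smallest positive float with a warning.
    """
    if value_kind not in VALUE_KINDS:
        raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
    arr = np.asarray(values, dtype=float)
    if value_kind == "importance":
        if (arr < 0).any():
            raise ValueError("importances must be non-negative")
        return arr.copy()
    if (arr > 1).any() or (arr < 0).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (arr == 0).any():
        tiny = np.nextafter(0.0, 1.0)
        warnings.warn(
            f"p-value 0 clipped to {tiny:g} before log transform",
            stacklevel=2,
        )
        arr = np.where(arr == 0, tiny, arr)
    return -np.log10(arr)


# ---------------------------------------------------------------------------
# ABC curve and partition
# ---------------------------------------------------------------------------


def _ranked(
    importances: np.ndarray, items: Sequence[str] | None
) -> tuple[list[str], np.ndarray]:
    n = len(importances)
    if items is None:
        items = [str(i) for i in range(n)]
    items = [str(it) for it in items]
    if len(items) != n:
        raise ValueError("items and importances differ in length")
    order = sorted(range(n), key=lambda i: (-importances[i], items[i]))
    return [items[i] for i in order], importances[np.array(order, dtype=int)]


def abc_curve(
    importances: Sequence[float] | np.ndarray,
    items: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Rank items and build the cumulative ABC curve.

    Returns ``(ranked_items, x, y)`` where ``x[i] = (i+1)/n`` is the
    effort and ``y[i]`` the cumulative importance share of the top
    ``i+1`` items.  Ties in importance are broken by item identifier
    (ascending).  Raises :class:`AbcError` if no importance is positive.
    """
    imp = np.asarray(importances, dtype=float)
    if imp.size == 0:
        raise AbcError("no signal: empty importance vector")
    if (imp < 0).any():
        raise ValueError("importances must be non-negative")
    total = imp.sum()
    if total <= 0:
        raise AbcError("no signal: all importances are zero")
    ranked_items, ranked = _ranked(imp, items)
    n = imp.size
    x = np.arange(1, n + 1) / n
    y = np.cumsum(ranked) / total
    return ranked_items, x, y


@dataclass(frozen=True)
class AbcPartition:
    """Result of an ABC split: ranked items and the two boundary ranks.

    ``iab`` and ``ibc`` are 1-based inclusive end ranks of sets A and B.
    """

    items: tuple[str, ...]
    importances: tuple[float, ...]
    iab: int
    ibc: int

    @property
    def a(self) -> frozenset[str]:
        return frozenset(self.items[: self.iab])

    @property
    def b(self) -> frozenset[str]:
        return frozenset(self.items[self.iab : self.ibc])

    @property
    def c(self) -> frozenset[str]:
        return frozenset(self.items[self.ibc :])


def abc_partition(
    importances: Sequence[float] | np.ndarray,
    items: Sequence[str] | None = None,
) -> AbcPartition:
    """Split ranked items into sets A, B and C.

    A|B boundary: the rank whose curve point (x_i, y_i) minimises the
    Euclidean distance to (0, 1); the smallest rank wins ties.  B|C
    boundary: the largest rank whose discrete slope
    (y_i − y_{i−1}) / (x_i − x_{i−1}) = n·imp_i / total is still ≥ 1;
    forced up to the A|B boundary if it would fall below it.
    """
    ranked_items, x, y = abc_curve(importances, items)
    ranked = np.asarray(
        sorted(np.asarray(importances, dtype=float), reverse=True)
    )
    d2 = x**2 + (1.0 - y) ** 2
    iab = int(np.argmin(d2)) + 1
    n = len(ranked_items)
    total = ranked.sum()
    slopes = n * ranked / total
    at_least_avg = np.nonzero(slopes >= 1.0)[0]
    ibc = int(at_least_avg[-1]) + 1 if at_least_avg.size else 0
    if ibc < iab:
        ibc = iab
    imp_sorted = np.asarray(importances, dtype=float)
    order = sorted(
        range(len(imp_sorted)),
        key=lambda i: (
            -imp_sorted[i],
            str(items[i]) if items is not None else str(i),
        ),
    )
    return AbcPartition(
        items=tuple(ranked_items),
        importances=tuple(imp_sorted[order]),
        iab=iab,
        ibc=ibc,
    )


# ---------------------------------------------------------------------------
# Selectors
# ---------------------------------------------------------------------------

Selector = Callable[[pd.Series, str], frozenset]


def _abc_selector(row: pd.Series, value_kind: str) -> frozenset:
    imp = to_importance(row.to_numpy(), value_kind)
    part = abc_partition(imp, list(row.index.astype(str)))
    return part.a


def _top_k_selector(k: int) -> Selector:
    if k < 1:
        raise ValueError("top-k selector needs k >= 1")

    def select(row: pd.Series, value_kind: str) -> frozenset:
        imp = to_importance(row.to_numpy(), value_kind)
        if imp.sum() <= 0:
            raise AbcError("no signal: all importances are zero")
        ranked, _, _ = abc_curve(imp, list(row.index.astype(str)))
        return frozenset(ranked[: min(k, len(ranked))])

    return select


def _p_threshold_selector(alpha: float) -> Selector:
    if not 0 < alpha <= 1:
        raise ValueError("p-threshold selector needs 0 < alpha <= 1")

    def select(row: pd.Series, value_kind: str) -> frozenset:
        if value_kind != "pvalue":
            raise ValueError("p-threshold selector requires p-values")
        return frozenset(row.index[row.to_numpy(dtype=float) <= alpha].astype(str))

    return select


def make_selector(name: str = "abc", **params) -> Selector:
    """Build a per-drug GO-term selector.

    ``"abc"`` (default, no parameters), ``"top_k"`` (``k``), or
    ``"p_threshold"`` (``alpha``).  A selector maps a drug's significance
    row plus the table's value kind to the selected GO identifier set.
    """
    if name == "abc":
        if params:
            raise ValueError("abc selector takes no parameters")
        return _abc_selector
    if name in ("top_k", "top-k", "topk"):
        return _top_k_selector(int(params.pop("k")))
    if name in ("p_threshold", "p-threshold"):
        return _p_threshold_selector(float(params.pop("alpha")))
    raise ValueError(f"unknown selector {name!r}")


def select_go_terms(
    table: PerturbationTable,
    drug: str,
    selector: "str | Selector" = "abc",
    **params,
) -> frozenset:
    """The GO terms most significantly perturbed by ``drug`` (set A)."""
    if isinstance(selector, str):
        selector = make_selector(selector, **params)
    row = table.row(drug)
    if row.empty:
        raise AbcError(f"no signal: drug {drug!r} has no measured GO terms")
    return selector(row, table.value_kind)
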