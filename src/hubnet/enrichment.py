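"""Hypergeometric over-representation analysis of gene sets.

A query gene list is tested against each category of a user-supplied GMT
collection with the one-sided (upper tail) hypergeometric test; p-values are
Benjamini-Hochberg adjusted across the tested categories. Categories
overlapping the query in fewer than ``min_overlap`` genes are excluded
*before* adjustment, the behaviour of mainstream over-representation web
tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeometric_test",
    "bh_adjust",
    "enrich",
    "EnrichmentModel",
    "EnrichmentResults",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene categories plus the background (reference) gene universe."""

    categories: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for cid, (_, genes) in self.categories.items():
            if not genes:
                raise ValueError(f"category {cid!r} is empty")
            if not genes <= self.background:
                extra = sorted(genes - self.background)[:5]
                raise ValueError(
                    f"category {cid!r} has genes outside the background: {extra}"
                )

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        background: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        cats = {cid: (cid, frozenset(genes)) for cid, genes in sets.items()}
        if background is None:
            bg: set[str] = set()
            for _, genes in cats.values():
                bg |= genes
        else:
            bg = set(background)
        return cls(categories=cats, background=frozenset(bg))


def read_gmt(
    path: str | Path, background: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read a GMT file (category, description, member genes...).

    Without an explicit background the union of all category genes is used.
    """
    cats: dict[str, tuple[str, frozenset[str]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT row needs >=3 fields")
            cid, desc, genes = parts[0], parts[1], frozenset(
                g for g in parts[2:] if g
            )
            cats[cid] = (desc or cid, genes)
    union: set[str] = set()
    for _, genes in cats.values():
        union |= genes
    bg = union if background is None else set(background) | union
    return GeneSetCollection(categories=cats, background=frozenset(bg))


def hypergeometric_test(
    query: frozenset[str] | set[str],
    category: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
    *,
    strict: bool = True,
) -> float:
    """Upper-tail hypergeometric p-value P(X >= |query ∩ category|).

    X ~ Hypergeom(N=|background|, K=|category|, n=|query|). With
    ``strict=False`` genes outside the background are silently dropped from
    query and category instead of raising.
    """
    query, category, background = set(query), set(category), set(background)
    if strict:
        if not query <= background:
            raise ValueError("query genes outside the background")
        if not category <= background:
            raise ValueError("category genes outside the background")
    else:
        query &= background
        category &= background
    overlap = len(query & category)
    # sf(k-1) = P(X >= k); scipy evaluates the exact tail sum
    return float(stats.hypergeom.sf(overlap - 1, len(background), len(category), len(query)))


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    min_overlap: int = 2,
    *,
    strict: bool = True,
    alpha_on_raw: bool = False,
) -> pd.DataFrame:
    """Over-representation test of ``query`` against every category.

    Categories overlapping the query in fewer than ``min_overlap`` genes are
    dropped before BH adjustment. ``significant`` flags adjusted_p <= alpha
    (raw p with ``alpha_on_raw``). Rows are sorted by (adjusted_p, category).
    """
    query = set(query)
    if not strict:
        query &= set(collection.background)
    if not query:
        warnings.warn("empty query gene list: no enrichment computed")
        return _empty_frame()
    rows = []
    for cid in sorted(collection.categories):
        name, genes = collection.categories[cid]
        overlap = len(query & genes)
        if overlap < min_overlap:
            continue
        p = hypergeometric_test(query, genes, collection.background, strict=strict)
        rows.append(
            {
                "category": cid,
                "name": name,
                "n_query": len(query),
                "n_category": len(genes),
                "n_overlap": overlap,
                "n_background": len(collection.background),
                "p_value": p,
            }
        )
    if not rows:
        return _empty_frame()
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bh_adjust(df["p_value"])
    df["significant"] = (df["p_value"] if alpha_on_raw else df["adjusted_p"]) <= alpha
    df = df.sort_values(["adjusted_p", "category"], kind="mergesort").reset_index(
        drop=True
    )
    return df


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "category",
            "name",
            "n_query",
            "n_category",
            "n_overlap",
            "n_background",
            "p_value",
            "adjusted_p",
            "significant",
        ]
    )


class EnrichmentModel:
    """Over-representation model: a query list against a gene-set collection."""

    def __init__(
        self,
        query: Iterable[str],
        collection: GeneSetCollection,
        *,
        alpha: float = 0.05,
        min_overlap: int = 2,
        strict: bool = True,
        alpha_on_raw: bool = False,
    ):
        self.query = frozenset(query)
        self.collection = collection
        self.alpha = alpha
        self.min_overlap = min_overlap
        self.strict = strict
        self.alpha_on_raw = alpha_on_raw

    def fit(self) -> "EnrichmentResults":
        table = enrich(
            self.query,
            self.collection,
            alpha=self.alpha,
            min_overlap=self.min_overlap,
            strict=self.strict,
            alpha_on_raw=self.alpha_on_raw,
        )
        return EnrichmentResults(self, table)


class EnrichmentResults:
    def __init__(self, model: EnrichmentModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            "Enrichment summary",
            "==================",
            f"query genes       {len(self.model.query)}",
            f"categories tested {len(self.table)}",
            f"significant (alpha={self.model.alpha}) {int(self.table['significant'].sum()) if len(self.table) else 0}",
        ]
        if len(self.table):
            top = self.table.head(10)[
                ["category", "n_overlap", "n_category", "p_value", "adjusted_p"]
            ]
            lines += ["", top.to_string(index=False)]
        return "\n".join(lines)
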