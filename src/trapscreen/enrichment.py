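"""Gene-set over-representation of pooled hit lists against the screen
background, with count filters applied before FDR adjustment.

The background is the set of genes actually assayed in the screen
(386 in the original study), not the genome: a term's "population" size
K counts only its members present in the background.  For a hit list of
size n, a term with K background members and k hit members is scored by
the one-sided hypergeometric tail

    p = P(X ≥ k),   X ~ Hypergeom(N, K, n),

and terms are kept only if K ≥ 3 and k ≥ 2 (tiny or single-gene overlaps
carry no set-level signal).  Benjamini–Hochberg q-values are computed
over the surviving terms only, so the adjusted family size equals the
number of terms actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .screen_data import GeneSetCollection
from .viability_stats import HitCalls

#: categories in which per-dose hits are pooled before enrichment
POOL_CATEGORIES = (
    "incr_viability",
    "decr_viability",
    "incr_expression",
    "decr_expression",
)

_ADJUST_METHODS = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}


def pool_hits(
    viability: HitCalls, expression: HitCalls, category: str
) -> frozenset[str]:
    """Union of a category's hit genes across dose contrasts.

    ``category`` is one of :data:`POOL_CATEGORIES`; e.g. ``incr_viability``
    pools the increased-viability genes of every dose contrast.
    """
    if category not in POOL_CATEGORIES:
        raise ValidationError(
            f"unknown pooling category {category!r}; expected one of {POOL_CATEGORIES}"
        )
    direction = "increased" if category.startswith("incr") else "decreased"
    calls = viability if category.endswith("viability") else expression
    pooled: set[str] = set()
    for (dose, part_dir), genes in calls.partitions.items():
        if part_dir == direction:
            pooled.update(genes)
    return frozenset(pooled)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided over-representation tail P(X ≥ k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    hits: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    min_population: int = 3,
    min_hit_genes: int = 2,
    method: str = "bh",
) -> pd.DataFrame:
    """Over-representation of *hits* within *background* for each gene set.

    Annotations are matched case-insensitively and intersected with the
    background before K is counted.  Terms with K < ``min_population`` or
    k < ``min_hit_genes`` are excluded *before* multiple-testing
    adjustment.  Results are sorted by q then p.
    """
    background = frozenset(background)
    hits = frozenset(hits)
    bg_fold = {g.casefold() for g in background}
    strays = sorted(g for g in hits if g.casefold() not in bg_fold)
    if strays:
        raise ValidationError(f"hit genes absent from the background: {strays}")
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")

    restricted = sets.restricted_to(background)
    hits_fold = {g.casefold() for g in hits}
    N = len(background)
    n = len(hits)
    rows = []
    for term in restricted:
        K = len(term.member_genes)
        overlap = sorted(g for g in term.member_genes if g.casefold() in hits_fold)
        k = len(overlap)
        if K < min_population or k < min_hit_genes:
            continue
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "hit_genes_in_term": ",".join(overlap),
                "k": k,
                "K": K,
                "n_hits": n,
                "background_size": N,
                "p": hypergeom_tail(k, N, K, n),
            }
        )
    columns = ["term_id", "term_name", "hit_genes_in_term", "k", "K", "n_hits",
               "background_size", "p", "q"]
    if not rows:
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method=_ADJUST_METHODS[method])[1]
    out = out.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)
    return out[columns]


@dataclass(frozen=True)
class GeneSummary:
    """Per-partition counts plus union/intersection across labels."""

    counts: dict[str, int]
    union: frozenset[str]
    intersection: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.union)


def unique_gene_summary(partitions: Mapping[str, Iterable[str]]) -> GeneSummary:
    """Deduplicated gene accounting over labelled partitions.

    A gene listed in several partitions (e.g. a hit at both doses) counts
    once in the union; the intersection collects genes present in every
    partition.
    """
    sets = {label: frozenset(genes) for label, genes in partitions.items()}
    union: frozenset[str] = frozenset().union(*sets.values()) if sets else frozenset()
    if sets:
        inter = frozenset.intersection(*sets.values())
    else:
        inter = frozenset()
    return GeneSummary(
        counts={label: len(s) for label, s in sets.items()},
        union=union,
        intersection=inter,
    )
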