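"""Essential genes and minimal synthetic-lethal gene sets (orders 1–4).

A gene set is lethal when its knockout reduces the context model's growth by
strictly more than the lethality threshold (default 50%) relative to that
model's own wild type.  A synthetic-lethal (SL) set is a *minimal* lethal
set: every proper nonempty subset stays at or below the threshold.

The enumeration prunes the subset lattice with two sound rules:

* a lethal set is never extended (its supersets cannot be minimal);
* a non-lethal mutant is only extended by genes associated with reactions
  carrying nonzero flux in a minimum-ℓ1-norm optimal flux distribution of
  that mutant — deleting any gene set disjoint from this support leaves the
  current optimal flux vector feasible, so the optimum (and hence lethality)
  cannot change.  Because any lethal extension must contain at least one
  support gene and the support is recomputed at every node, the recursion
  reaches every minimal lethal set.

Lethality and minimality are always decided by a full knockout LP, never by
support membership, so the output provably equals brute force; the brute
force enumerator is provided alongside as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .context_build import ContextModel
from .errors import ConfigurationError
from .model_core import GROWTH_TOL, knockout_growth, min_l1_support_genes

__all__ = [
    "SLSet",
    "KnockoutEvaluator",
    "essential_genes",
    "enumerate_sl",
    "brute_force_sl",
    "verify_minimality",
    "sl_table",
]

#: Hard cap on model gene count for exhaustive subset enumeration.
BRUTE_FORCE_GENE_LIMIT = 30

DEFAULT_LETHAL_THRESHOLD = 0.5


@dataclass(frozen=True, order=True)
class SLSet:
    """A minimal lethal gene set with its mutant growth and reduction."""

    genes: tuple[str, ...]  # sorted gene ids
    mutant_growth: float
    reduction_fraction: float
    minimal: bool = True

    @property
    def order(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


class KnockoutEvaluator:
    """Memoized knockout-growth evaluation against one context model."""

    def __init__(self, model: ContextModel, lethal_threshold: float = DEFAULT_LETHAL_THRESHOLD):
        if model.wild_type_growth <= 0:
            raise ConfigurationError(
                f"context {model.label!r} has non-positive wild-type growth"
            )
        self.model = model
        self.lethal_threshold = float(lethal_threshold)
        self._growth: dict[frozenset[str], float] = {}

    def growth(self, genes: frozenset[str]) -> float:
        if genes not in self._growth:
            self._growth[genes] = knockout_growth(self.model.network, genes)
        return self._growth[genes]

    def reduction(self, genes: frozenset[str]) -> float:
        return self.model.reduction_fraction(self.growth(genes))

    def is_lethal(self, genes: frozenset[str]) -> bool:
        # strict "> threshold", stabilized against LP round-off
        return self.reduction(genes) > self.lethal_threshold + GROWTH_TOL

    def is_minimal_lethal(self, genes: frozenset[str]) -> bool:
        if not self.is_lethal(genes):
            return False
        return all(
            not self.is_lethal(frozenset(sub))
            for size in range(1, len(genes))
            for sub in combinations(sorted(genes), size)
        )

    def as_slset(self, genes: frozenset[str]) -> SLSet:
        growth = self.growth(genes)
        return SLSet(
            genes=tuple(sorted(genes)),
            mutant_growth=growth,
            reduction_fraction=self.model.reduction_fraction(growth),
            minimal=True,
        )


def essential_genes(
    model: ContextModel, lethal_threshold: float = DEFAULT_LETHAL_THRESHOLD
) -> list[SLSet]:
    """Order-1 lethal sets: genes whose single knockout crosses the threshold."""
    ev = KnockoutEvaluator(model, lethal_threshold)
    return sorted(
        ev.as_slset(frozenset({g}))
        for g in model.gene_ids
        if ev.is_lethal(frozenset({g}))
    )


def enumerate_sl(
    model: ContextModel,
    max_order: int,
    lethal_threshold: float = DEFAULT_LETHAL_THRESHOLD,
    *,
    _evaluator: KnockoutEvaluator | None = None,
) -> list[SLSet]:
    """Minimal SL sets of orders 2..max_order via the pruned lattice search.

    Output is deduplicated, canonically sorted, and independent of the gene
    ordering of the input model.
    """
    if max_order not in (2, 3, 4):
        raise ConfigurationError(f"max_order must be 2, 3 or 4, got {max_order}")
    ev = _evaluator or KnockoutEvaluator(model, lethal_threshold)
    found: set[frozenset[str]] = set()
    visited: set[frozenset[str]] = set()

    def extend(current: frozenset[str]) -> None:
        if current in visited:
            return
        visited.add(current)
        if current and ev.is_lethal(current):
            # prune rule (a): never extend a lethal set
            if ev.is_minimal_lethal(current) and len(current) >= 2:
                found.add(current)
            return
        if len(current) >= max_order:
            return
        # prune rule (b): only support genes of the current mutant can matter
        support = min_l1_support_genes(model.network, current)
        for gene in sorted(support - current):
            extend(current | {gene})

    extend(frozenset())
    return sorted(ev.as_slset(genes) for genes in found)


def brute_force_sl(
    model: ContextModel,
    max_order: int,
    lethal_threshold: float = DEFAULT_LETHAL_THRESHOLD,
    min_order: int = 1,
) -> list[SLSet]:
    """Exhaustive minimal-lethal-set enumeration — the search oracle.

    Evaluates every gene subset of size ≤ max_order by full knockout LP and
    applies the same lethality and minimality definitions as the pruned
    search.  Refuses models with more than 30 genes.
    """
    genes = model.gene_ids
    if len(genes) > BRUTE_FORCE_GENE_LIMIT:
        raise ConfigurationError(
            f"brute force refused: {len(genes)} genes exceeds the "
            f"{BRUTE_FORCE_GENE_LIMIT}-gene guard"
        )
    if max_order < 1:
        raise ConfigurationError("max_order must be ≥ 1")
    ev = KnockoutEvaluator(model, lethal_threshold)
    results: list[SLSet] = []
    lethal_seen: list[frozenset[str]] = []
    # sizes below min_order are still evaluated so minimality stays correct
    for size in range(1, max_order + 1):
        for combo in combinations(genes, size):
            candidate = frozenset(combo)
            if any(prev <= candidate for prev in lethal_seen):
                continue  # a lethal subset exists -> not minimal
            if ev.is_lethal(candidate):
                lethal_seen.append(candidate)
                if size >= min_order:
                    results.append(ev.as_slset(candidate))
    return sorted(results)


def verify_minimality(
    candidate: SLSet | Iterable[str],
    model: ContextModel,
    lethal_threshold: float = DEFAULT_LETHAL_THRESHOLD,
) -> bool:
    """Post-hoc audit: every proper nonempty subset must be non-lethal."""
    genes = (
        candidate.gene_set if isinstance(candidate, SLSet) else frozenset(candidate)
    )
    ev = KnockoutEvaluator(model, lethal_threshold)
    if not ev.is_lethal(genes):
        return False
    return ev.is_minimal_lethal(genes)


def sl_table(sets: Iterable[SLSet]) -> "pd.DataFrame":
    """Tabulate SL sets: order, comma-joined sorted gene ids, growth, reduction."""
    import pandas as pd

    rows = [
        {
            "order": s.order,
            "genes": ",".join(s.genes),
            "mutant_growth": s.mutant_growth,
            "reduction_fraction": s.reduction_fraction,
        }
        for s in sorted(sets)
    ]
    return pd.DataFrame(rows, columns=["order", "genes", "mutant_growth", "reduction_fraction"])
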