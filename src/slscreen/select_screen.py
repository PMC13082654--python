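"""Strict-selectivity screening of lethal candidates across protected tissues.

A candidate (essential gene or SL set, lethal in the target cancer model) is
*strictly selective* when its knockout reduces the cancer model's growth by
more than 50% while reducing every protected non-tumor model's growth by
less than 10% — both inequalities strict, each reduction measured against
that model's own wild-type growth.  Genes absent from a protected model are
no-ops there.

Besides the verdicts, this module produces the reporting surfaces of the
screen: incremental protection curves (how many candidates survive as more
tissues are protected), percentage-of-selective summaries, per-gene target
frequencies and within-set co-occurrence edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .context_build import ContextModel
from .model_core import GROWTH_TOL, knockout_growth
from .sl_enum import DEFAULT_LETHAL_THRESHOLD, SLSet

__all__ = [
    "DEFAULT_SAFE_THRESHOLD",
    "SelectivityRecord",
    "ProtectionCurve",
    "screen",
    "protection_curve",
    "percentage_selective",
    "gene_frequency",
    "cooccurrence_edges",
    "selectivity_table",
]

DEFAULT_SAFE_THRESHOLD = 0.1


@dataclass
class SelectivityRecord:
    """Per-candidate verdict: lethality in the cancer, safety everywhere else.

    ``safety`` maps every configured protected label to its reduction
    fraction; labels not evaluated (when short-circuiting) map to None.
    """

    gene_set: SLSet
    target_cancer: str
    cancer_reduction: float
    safety: dict[str, float | None]
    strictly_selective: bool
    failed_tissue: str | None = None

    @property
    def order(self) -> int:
        return self.gene_set.order


@dataclass
class ProtectionCurve:
    """Surviving-candidate counts per order as tissues are protected one by one.

    ``counts[order]`` is a list over protection steps (first k tissues
    protected); each list is non-increasing.
    """

    protected_labels: list[str]
    counts: dict[int, list[int]]

    def to_frame(self) -> pd.DataFrame:
        orders = sorted(self.counts)
        return pd.DataFrame(
            {f"order_{o}": self.counts[o] for o in orders},
            index=pd.Index(
                range(1, len(self.protected_labels) + 1), name="n_protected"
            ),
        )


def _protected_reduction(model: ContextModel, genes: frozenset[str]) -> float:
    """Reduction a knockout causes in a protected model; absent genes are no-ops."""
    present = genes & set(model.gene_ids)
    if not present:
        return 0.0
    return model.reduction_fraction(knockout_growth(model.network, present))


def screen(
    candidates: Sequence[SLSet],
    cancer: ContextModel,
    protected: Sequence[ContextModel],
    lethal_threshold: float = DEFAULT_LETHAL_THRESHOLD,
    safe_threshold: float = DEFAULT_SAFE_THRESHOLD,
    *,
    short_circuit: bool = False,
) -> list[SelectivityRecord]:
    """Evaluate every candidate in every protected model.

    With ``short_circuit`` the safety evaluation stops at the first tissue
    that disqualifies a candidate and the remaining tissues are recorded as
    unevaluated (None); verdicts are identical either way.
    """
    records: list[SelectivityRecord] = []
    for candidate in candidates:
        genes = candidate.gene_set
        cancer_growth = knockout_growth(cancer.network, genes & set(cancer.gene_ids))
        cancer_reduction = cancer.reduction_fraction(cancer_growth)
        lethal = cancer_reduction > lethal_threshold + GROWTH_TOL
        safety: dict[str, float | None] = {m.label: None for m in protected}
        failed: str | None = None
        for model in protected:
            reduction = _protected_reduction(model, genes)
            safety[model.label] = reduction
            if not reduction < safe_threshold - GROWTH_TOL:
                failed = failed or model.label
                if short_circuit:
                    break
        records.append(
            SelectivityRecord(
                gene_set=candidate,
                target_cancer=cancer.label,
                cancer_reduction=cancer_reduction,
                safety=safety,
                strictly_selective=lethal and failed is None,
                failed_tissue=failed,
            )
        )
    return records


def protection_curve(
    candidates: Sequence[SLSet],
    cancer: ContextModel,
    ordered_protected: Sequence[ContextModel],
    lethal_threshold: float = DEFAULT_LETHAL_THRESHOLD,
    safe_threshold: float = DEFAULT_SAFE_THRESHOLD,
) -> ProtectionCurve:
    """Candidates still selective after protecting the first k tissues, per order."""
    if not ordered_protected:
        raise ValueError("ordered_protected must be non-empty")
    records = screen(
        candidates, cancer, ordered_protected, lethal_threshold, safe_threshold
    )
    orders = sorted({c.order for c in candidates}) or [1]
    counts: dict[int, list[int]] = {o: [] for o in orders}
    labels = [m.label for m in ordered_protected]
    for k in range(1, len(labels) + 1):
        step_labels = labels[:k]
        for order in orders:
            surviving = sum(
                1
                for rec in records
                if rec.order == order
                and rec.cancer_reduction > lethal_threshold + GROWTH_TOL
                and all(
                    rec.safety[lab] < safe_threshold - GROWTH_TOL
                    for lab in step_labels
                )
            )
            counts[order].append(surviving)
    return ProtectionCurve(protected_labels=labels, counts=counts)


def percentage_selective(lethal_count: int, selective_count: int) -> float | None:
    """Percentage of lethal candidates that pass the selectivity check.

    100 × selective/lethal, rounded half away from zero to one decimal;
    None (not applicable) when there are no lethal candidates.
    """
    if lethal_count < 0 or selective_count < 0 or selective_count > lethal_count:
        raise ValueError(
            f"need 0 ≤ selective ≤ lethal, got {selective_count}/{lethal_count}"
        )
    if lethal_count == 0:
        return None
    percent = Decimal(100 * selective_count) / Decimal(lethal_count)
    return float(percent.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gene_frequency(records: Iterable[SelectivityRecord]) -> pd.Series:
    """How often each gene appears across all strictly-selective solutions.

    Sorted by descending count, ties broken lexicographically by gene id.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if rec.strictly_selective:
            for gene in rec.gene_set.genes:
                counts[gene] = counts.get(gene, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series(
        [c for _, c in ordered],
        index=pd.Index([g for g, _ in ordered], name="gene"),
        name="count",
        dtype=int,
    )


def cooccurrence_edges(
    records: Iterable[SelectivityRecord],
) -> list[tuple[str, str, int, str]]:
    """Within-set gene pairs of strictly-selective solutions.

    One edge (geneA, geneB, order, cancer) per unordered pair, deduplicated
    per (pair, order, cancer); singleton sets contribute no edges.
    """
    edges: set[tuple[str, str, int, str]] = set()
    for rec in records:
        if not rec.strictly_selective:
            continue
        genes = rec.gene_set.genes
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = sorted((genes[i], genes[j]))
                edges.add((a, b, rec.order, rec.target_cancer))
    return sorted(edges)


def selectivity_table(records: Sequence[SelectivityRecord]) -> pd.DataFrame:
    """Tabulate screen verdicts, one row per candidate."""
    rows = []
    for rec in records:
        row: dict = {
            "order": rec.order,
            "genes": ",".join(rec.gene_set.genes),
            "target_cancer": rec.target_cancer,
            "cancer_reduction": rec.cancer_reduction,
            "strictly_selective": rec.strictly_selective,
            "failed_tissue": rec.failed_tissue or "",
        }
        for label, reduction in rec.safety.items():
            row[f"safety_{label}"] = "" if reduction is None else reduction
        rows.append(row)
    return pd.DataFrame(rows)
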