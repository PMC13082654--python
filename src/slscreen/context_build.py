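"""Context-specific model construction from consensus gene activity scores.

Consensus gene scores (−1 inactive / 0 unknown / +1 active) are mapped onto
reactions through the GPR rules (AND → min, OR → max of the child scores),
reactions scored −1 have both flux bounds forced to zero, and reactions that
can carry no steady-state flux at all under the restricted bounds are flagged
as blocked.  The resulting context model records the wild-type growth rate
that every downstream lethality comparison divides by.

Score-0 (unknown) reactions keep their base bounds: only reactions called
inactive are constrained.  Blocked reactions are flagged and excluded from
statistics but physically retained (with zero feasible flux) so reaction
indexing stays stable across contexts.
"""

from __future__ import annotations

import ast
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from cobra.core.gene import GPR

from .errors import ContextInfeasibleError
from .model_core import GROWTH_TOL, MetabolicNetwork, fva

__all__ = ["ContextModel", "map_scores_to_reactions", "build_context"]


@dataclass
class ContextModel:
    """A tissue- and condition-specific restriction of a base network.

    ``network`` is an independent copy of the base model with the inactive
    reactions' bounds set to zero, so gene knockouts can be simulated on it
    directly.
    """

    network: MetabolicNetwork
    label: str
    condition: str  # "cancer" | "non_tumor"
    reaction_status: dict[str, str]  # id -> "active" | "inactive" | "unknown"
    deactivated_reactions: list[str]
    blocked_removed: list[str]
    wild_type_growth: float

    @property
    def gene_ids(self) -> list[str]:
        return self.network.gene_ids

    def reduction_fraction(self, mutant_growth: float) -> float:
        """1 − mutant/wild-type, clipped to [0, 1]."""
        frac = 1.0 - mutant_growth / self.wild_type_growth
        return min(max(frac, 0.0), 1.0)


def _score_tree(node, consensus: Mapping[str, int], missing: set[str]) -> int:
    if isinstance(node, ast.Name):
        if node.id not in consensus:
            missing.add(node.id)
            return 0
        return int(consensus[node.id])
    if isinstance(node, ast.BoolOp):
        child_scores = [_score_tree(v, consensus, missing) for v in node.values]
        return min(child_scores) if isinstance(node.op, ast.And) else max(child_scores)
    raise ValueError(f"unsupported GPR node {node!r}")


def map_scores_to_reactions(
    network: MetabolicNetwork, consensus: Mapping[str, int]
) -> dict[str, int]:
    """Map per-gene consensus scores onto reactions through the GPR rules.

    AND nodes (enzyme complexes) take the minimum of their children, OR
    nodes (isozymes) the maximum.  Reactions without a gene association are
    scored 0 (unknown); genes missing from the consensus are scored 0 with a
    warning.
    """
    missing: set[str] = set()
    scores: dict[str, int] = {}
    for rxn in network.cobra_model.reactions:
        rule: GPR = rxn.gpr
        if rule.body is None:
            scores[rxn.id] = 0
        else:
            scores[rxn.id] = _score_tree(rule.body, consensus, missing)
    if missing:
        warnings.warn(
            f"{len(missing)} GPR genes had no consensus score (treated as 0): "
            f"{sorted(missing)[:10]}",
            stacklevel=2,
        )
    return scores


def build_context(
    network: MetabolicNetwork,
    reaction_scores: Mapping[str, int],
    label: str,
    condition: str = "cancer",
) -> ContextModel:
    """Restrict a base network to one context given per-reaction scores.

    Reactions scored −1 get bounds (0, 0); scores 0 and +1 keep the base
    bounds.  Blocked reactions (FVA min = max = 0 with no objective floor)
    are recorded, excluding the explicitly deactivated ones.  Raises if the
    restricted model cannot sustain biomass.
    """
    restricted = network.copy()
    deactivated: list[str] = []
    status: dict[str, str] = {}
    for rid in restricted.reaction_ids:
        score = int(reaction_scores.get(rid, 0))
        status[rid] = {1: "active", 0: "unknown", -1: "inactive"}[score]
        if score == -1:
            restricted.reaction(rid).bounds = (0.0, 0.0)
            deactivated.append(rid)

    growth = restricted.cobra_model.slim_optimize()
    if growth is None or math.isnan(growth) or growth <= GROWTH_TOL:
        raise ContextInfeasibleError(
            f"context model {label!r} ({condition}) cannot sustain biomass"
        )

    ranges = fva(restricted, fraction_of_optimum=0.0)
    blocked = [
        rid
        for rid, (lo, hi) in ranges.items()
        if abs(lo) <= 1e-9 and abs(hi) <= 1e-9 and rid not in set(deactivated)
    ]
    return ContextModel(
        network=restricted,
        label=label,
        condition=condition,
        reaction_status=status,
        deactivated_reactions=deactivated,
        blocked_removed=sorted(blocked),
        wild_type_growth=float(growth),
    )
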