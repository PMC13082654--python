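"""Stoichiometric model container, flux balance analysis and gene knockouts.

This module is the simulation substrate for the whole screen: it holds the
metabolic network (stoichiometry, flux bounds, gene-protein-reaction rules,
biomass objective), solves the FBA linear program, runs flux variability
analysis, and evaluates GPR-driven gene deletions.  All flux units are
mmol·gDW⁻¹·h⁻¹ and growth rates are h⁻¹.

The heavy lifting (LP solving, SBML-FBC I/O, GPR parsing) is delegated to
COBRApy; this module pins down the contracts the rest of the pipeline relies
on — in particular that a knockout can only ever *lower* the biomass optimum
and that an infeasible mutant is reported as zero growth.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import cobra
from cobra.core.gene import GPR
from cobra.flux_analysis import flux_variability_analysis, pfba

from .errors import ConfigurationError, ModelParseError

__all__ = [
    "GROWTH_TOL",
    "FLUX_EPS",
    "FluxState",
    "MetabolicNetwork",
    "read_model",
    "write_model",
    "parse_gpr",
    "gpr_canonical",
    "evaluate_gpr",
    "fba_optimize",
    "knockout_growth",
    "fva",
    "min_l1_support_genes",
]

#: Absolute tolerance for comparing growth rates (lethality thresholds must be
#: stable against LP round-off near the 50%/10% cut points).
GROWTH_TOL = 1e-6

#: A flux below this magnitude is treated as zero (support detection).
FLUX_EPS = 1e-6


@dataclass
class FluxState:
    """An FBA solution: flux vector, objective value and solver status.

    When ``status == "optimal"`` the flux vector satisfies S·v = 0 and the
    bounds to solver tolerance, and ``objective_value`` is the flux through
    the objective (biomass) reaction.  For an infeasible model the objective
    is NaN and the flux vector is empty.
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible"

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"


class MetabolicNetwork:
    """A validated constraint-based metabolic model.

    Wraps a :class:`cobra.Model` and enforces the invariants the screen
    depends on: consistent bounds, finite nonzero stoichiometric
    coefficients, every GPR gene registered, and a declared biomass
    objective with nonempty stoichiometry.
    """

    def __init__(self, model: cobra.Model, objective_reaction: str | None = None):
        if objective_reaction is None:
            objective_reaction = _objective_reaction_id(model)
        if objective_reaction not in {r.id for r in model.reactions}:
            raise ConfigurationError(
                f"objective reaction {objective_reaction!r} not in model"
            )
        self._model = model
        self.objective_reaction = objective_reaction
        model.objective = objective_reaction
        self._validate()

    # -- container surface ------------------------------------------------

    @property
    def cobra_model(self) -> cobra.Model:
        return self._model

    @property
    def gene_ids(self) -> list[str]:
        return sorted(g.id for g in self._model.genes)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self._model.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self._model.metabolites]

    def reaction(self, rid: str) -> cobra.Reaction:
        return self._model.reactions.get_by_id(rid)

    def gpr(self, rid: str) -> GPR:
        return self._model.reactions.get_by_id(rid).gpr

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(self._model.copy(), self.objective_reaction)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicNetwork {len(self._model.reactions)} reactions, "
            f"{len(self._model.metabolites)} metabolites, "
            f"{len(self._model.genes)} genes, objective={self.objective_reaction}>"
        )

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        m = self._model
        for rxn in m.reactions:
            if not (rxn.lower_bound <= rxn.upper_bound):
                raise ConfigurationError(
                    f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            for met, coef in rxn.metabolites.items():
                if not math.isfinite(coef) or coef == 0:
                    raise ConfigurationError(
                        f"reaction {rxn.id}: stoichiometric coefficient for "
                        f"{met.id} is {coef}"
                    )
        obj = m.reactions.get_by_id(self.objective_reaction)
        if not obj.metabolites:
            raise ConfigurationError(
                f"objective reaction {self.objective_reaction!r} has empty stoichiometry"
            )
        gene_set = {g.id for g in m.genes}
        for rxn in m.reactions:
            missing = {g.id for g in rxn.genes} - gene_set
            if missing:  # pragma: no cover - cobra registers genes automatically
                raise ConfigurationError(
                    f"reaction {rxn.id} references unknown genes {sorted(missing)}"
                )


def _objective_reaction_id(model: cobra.Model) -> str:
    from cobra.util.solver import linear_reaction_coefficients

    coefs = linear_reaction_coefficients(model)
    if not coefs:
        raise ConfigurationError("model declares no objective reaction")
    if len(coefs) > 1:
        raise ConfigurationError(
            f"model declares multiple objective reactions: "
            f"{sorted(r.id for r in coefs)}"
        )
    return next(iter(coefs)).id


# ---------------------------------------------------------------------------
# I/O: SBML Level 3 + FBC, and a plain-JSON dialect for fixtures
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in {".xml", ".sbml"}:
        return "sbml"
    raise ConfigurationError(f"cannot infer model dialect from {path.name!r}")


def read_model(path: str | Path, dialect: str | None = None) -> MetabolicNetwork:
    """Read a metabolic model from SBML (Level 3 + FBC) or the JSON dialect.

    The JSON dialect is ``{"metabolites": [...], "reactions": [{"id",
    "stoich": {met: coef}, "lb", "ub", "gpr"}], "genes": [...],
    "objective": "..."}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect == "json":
        return _read_json(path)
    if dialect == "sbml":
        return _read_sbml(path)
    raise ConfigurationError(f"unknown model dialect {dialect!r}")


def _read_json(path: Path) -> MetabolicNetwork:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path.name}: invalid JSON ({exc})") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelParseError(f"{path.name}: missing top-level key {key!r}")
    if "objective" not in doc:
        raise ConfigurationError(f"{path.name}: no objective reaction declared")
    model = cobra.Model(path.stem)
    mets: dict[str, cobra.Metabolite] = {}
    for mid in doc["metabolites"]:
        compartment = mid.rsplit("_", 1)[1] if "_" in mid else "c"
        mets[mid] = cobra.Metabolite(mid, compartment=compartment)
    model.add_metabolites(list(mets.values()))
    reactions = []
    for entry in doc["reactions"]:
        for key in ("id", "stoich", "lb", "ub"):
            if key not in entry:
                raise ModelParseError(
                    f"{path.name}: reaction entry {entry.get('id', '?')!r} "
                    f"missing key {key!r}"
                )
        rxn = cobra.Reaction(entry["id"])
        reactions.append(rxn)
    model.add_reactions(reactions)
    for entry, rxn in zip(doc["reactions"], reactions):
        try:
            rxn.add_metabolites({mets[m]: float(c) for m, c in entry["stoich"].items()})
        except KeyError as exc:
            raise ModelParseError(
                f"{path.name}: reaction {entry['id']!r} references unknown "
                f"metabolite {exc.args[0]!r}"
            ) from exc
        try:
            rxn.bounds = (float(entry["lb"]), float(entry["ub"]))
        except ValueError as exc:
            raise ConfigurationError(
                f"{path.name}: reaction {entry['id']!r}: {exc}"
            ) from exc
        gpr_string = entry.get("gpr", "") or ""
        if gpr_string:
            rxn.gene_reaction_rule = gpr_string
    declared = set(doc.get("genes", []))
    present = {g.id for g in model.genes}
    if declared and not present <= declared:
        raise ModelParseError(
            f"{path.name}: GPR rules reference undeclared genes "
            f"{sorted(present - declared)}"
        )
    model.objective = _require_reaction(model, doc["objective"], path)
    return MetabolicNetwork(model, doc["objective"])


def _require_reaction(model: cobra.Model, rid: str, path: Path) -> str:
    if rid not in {r.id for r in model.reactions}:
        raise ModelParseError(f"{path.name}: objective reaction {rid!r} not defined")
    return rid


def _read_sbml(path: Path) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path.name}: SBML error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path.name}: no <model> element")
    if sbml_model.getPlugin("fbc") is None:
        raise ModelParseError(
            f"{path.name}: SBML model lacks the FBC package (no flux bounds "
            f"or gene associations)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = cobra.io.read_sbml_model(str(path))
    try:
        objective = _objective_reaction_id(model)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path.name}: {exc}") from exc
    return MetabolicNetwork(model, objective)


def write_model(network: MetabolicNetwork, path: str | Path, dialect: str | None = None) -> None:
    """Write the model as SBML-FBC or the JSON fixture dialect."""
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect == "sbml":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(network.cobra_model, str(path))
        return
    if dialect != "json":
        raise ConfigurationError(f"unknown model dialect {dialect!r}")
    doc = {
        "metabolites": network.metabolite_ids,
        "reactions": [
            {
                "id": r.id,
                "stoich": {m.id: float(c) for m, c in r.metabolites.items()},
                "lb": float(r.lower_bound),
                "ub": float(r.upper_bound),
                "gpr": r.gene_reaction_rule,
            }
            for r in network.cobra_model.reactions
        ],
        "genes": network.gene_ids,
        "objective": network.objective_reaction,
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

def parse_gpr(rule: str) -> GPR:
    """Parse a GPR string ("gA and (gB or gC)") into a boolean tree.

    Case-insensitive ``and``/``or`` with parentheses; AND binds tighter than
    OR; no negation.  The empty string parses to the empty rule.
    """
    return GPR.from_string(rule or "")


def evaluate_gpr(rule: GPR | str, deleted: Iterable[str]) -> bool:
    """Evaluate a GPR under a gene deletion: deleted leaves are false.

    An empty rule is unconditionally true — a reaction with no gene
    association is unaffected by any knockout.
    """
    if isinstance(rule, str):
        rule = parse_gpr(rule)
    if rule.body is None:
        return True
    return rule.eval(frozenset(deleted))


def gpr_canonical(rule: GPR | str):
    """Canonical form of a GPR tree, invariant under AND/OR commutativity.

    Returns nested ``("and"|"or", frozenset)`` tuples with gene leaves as
    strings; used to compare rules for semantic (not textual) equality.
    """
    import ast

    if isinstance(rule, str):
        rule = parse_gpr(rule)
    if rule.body is None:
        return None

    def walk(node):
        if isinstance(node, ast.Name):
            return node.id
        if isinstance(node, ast.BoolOp):
            op = "and" if isinstance(node.op, ast.And) else "or"
            children = frozenset(walk(v) for v in node.values)
            return (op, children)
        raise ValueError(f"unsupported GPR node {node!r}")

    body = rule.body
    if isinstance(body, ast.Expression):  # pragma: no cover - cobra internal
        body = body.body
    return walk(body)


# ---------------------------------------------------------------------------
# FBA / knockouts / FVA
# ---------------------------------------------------------------------------

def fba_optimize(network: MetabolicNetwork) -> FluxState:
    """Maximize flux through the biomass objective subject to S·v = 0 and bounds.

    The objective value is the unique LP optimum; the flux vector returned is
    one of possibly many optimal vertices and must not be used for any
    downstream decision that has to be solver-independent.
    """
    model = network.cobra_model
    solution = model.optimize()
    if solution.status != "optimal":
        return FluxState({}, float("nan"), "infeasible")
    return FluxState(
        dict(solution.fluxes), float(solution.objective_value), "optimal"
    )


def _disabled_reactions(network: MetabolicNetwork, deleted: frozenset[str]) -> list[cobra.Reaction]:
    """Reactions whose GPR evaluates false once `deleted` genes are removed.

    Only reactions touching a deleted gene can change state, so only those
    are re-evaluated.
    """
    model = network.cobra_model
    touched: set[cobra.Reaction] = set()
    for gid in deleted:
        try:
            touched.update(model.genes.get_by_id(gid).reactions)
        except KeyError:
            continue
    return [r for r in touched if not evaluate_gpr(r.gpr, deleted)]


def knockout_growth(
    network: MetabolicNetwork,
    genes: Iterable[str],
    *,
    return_infeasible_flag: bool = False,
) -> float | tuple[float, bool]:
    """Growth rate after deleting a gene set.

    Every reaction whose GPR evaluates false under the deletion has both
    bounds forced to zero; the constrained model is then re-optimized.  An
    infeasible mutant is reported as growth 0 (with a flag when requested).
    Gene ids absent from the model are tolerated with a warning and act as
    no-ops.
    """
    deleted = frozenset(genes)
    model_genes = {g.id for g in network.cobra_model.genes}
    unknown = deleted - model_genes
    if unknown:
        warnings.warn(
            f"knockout includes genes absent from the model (ignored): "
            f"{sorted(unknown)}",
            stacklevel=2,
        )
        deleted = deleted & model_genes
    model = network.cobra_model
    with model:
        for rxn in _disabled_reactions(network, deleted):
            rxn.bounds = (0.0, 0.0)
        value = model.slim_optimize()
    infeasible = value is None or math.isnan(value)
    growth = 0.0 if infeasible else max(float(value), 0.0)
    if return_infeasible_flag:
        return growth, infeasible
    return growth


def fva(
    network: MetabolicNetwork,
    reactions: Sequence[str] | None = None,
    fraction_of_optimum: float = 0.0,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: per-reaction (min, max) flux.

    Constraints: steady state, bounds, and objective ≥ fraction_of_optimum ×
    optimum.  Raises on an infeasible base model.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ConfigurationError("fraction_of_optimum must lie in [0, 1]")
    model = network.cobra_model
    base = model.slim_optimize()
    if base is None or math.isnan(base):
        raise ConfigurationError("FVA requires a feasible base model")
    reaction_list = list(reactions) if reactions is not None else None
    frame = flux_variability_analysis(
        model, reaction_list=reaction_list, fraction_of_optimum=fraction_of_optimum
    )
    return {
        rid: (float(row["minimum"]), float(row["maximum"]))
        for rid, row in frame.iterrows()
    }


def min_l1_support_genes(
    network: MetabolicNetwork, deleted: frozenset[str] = frozenset()
) -> set[str]:
    """Genes appearing in the GPR of any reaction active in a minimum-ℓ1-norm
    optimal flux distribution of the (possibly mutant) model.

    This is the candidate-narrowing set for the synthetic-lethality search:
    any gene set whose members all lie outside it leaves the current optimal
    flux vector feasible and therefore cannot lower the optimum.  The flux
    distribution is computed by parsimonious FBA at 100% of the mutant
    optimum.  Callers must re-verify candidates by full knockout evaluation;
    support membership alone never decides lethality.
    """
    model = network.cobra_model
    with model:
        for rxn in _disabled_reactions(network, deleted):
            rxn.bounds = (0.0, 0.0)
        try:
            solution = pfba(model)
        except Exception:
            return set()
    genes: set[str] = set()
    for rid, flux in solution.fluxes.items():
        if abs(flux) > FLUX_EPS:
            genes.update(g.id for g in model.reactions.get_by_id(rid).genes)
    return genes - set(deleted)
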