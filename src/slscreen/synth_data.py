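"""Synthetic study generators: toy metabolic networks and RNA-seq-like data.

The toy networks stand in for a genome-scale reconstruction at desk scale:
biomass requires one unit of every precursor metabolite, each precursor is
fed by parallel capacity-bounded paths, and each path is gated by an AND of
one or more genes (optionally sharing "core" genes across paths).  Because
growth equals the minimum over precursors of the surviving path capacity
(capped by the biomass bound), every knockout's growth is computable by pure
capacity arithmetic — which this module uses to attach a brute-force
ground-truth catalog of minimal synthetic-lethal sets to every network it
emits, independently of any LP solver.

The expression simulator draws log2-FPKM values from a two-component
Gaussian mixture (an expressed and a non-expressed component), the bimodal
structure the zFPKM discretization assumes, with extreme low draws floored
to exact zeros to emulate undetected genes.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model_core import MetabolicNetwork

__all__ = [
    "PathSpec",
    "PrecursorSpec",
    "ToyNetworkSpec",
    "ExpressionSimSpec",
    "ContextBundle",
    "analytic_growth",
    "make_toy_network",
    "ground_truth_catalog",
    "random_toy_spec",
    "simulate_expression",
    "make_paired_contexts",
]


@dataclass(frozen=True)
class PathSpec:
    """One parallel path feeding a precursor: a flux capacity gated by an
    AND over its genes."""

    capacity: float
    genes: tuple[str, ...]


@dataclass(frozen=True)
class PrecursorSpec:
    name: str
    paths: tuple[PathSpec, ...]


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Design of a toy network with known redundancy structure.

    ``core_genes`` are AND-ed into every path (a shared enzyme complex);
    ``biomass_cap`` optionally caps the growth rate below the precursor
    supply so that redundant paths can each sustain full growth alone.
    """

    precursors: tuple[PrecursorSpec, ...]
    core_genes: tuple[str, ...] = ()
    biomass_cap: float | None = None
    seed: int = 0

    @property
    def gene_ids(self) -> tuple[str, ...]:
        genes: list[str] = list(self.core_genes)
        for prec in self.precursors:
            for path in prec.paths:
                genes.extend(path.genes)
        return tuple(sorted(set(genes)))

    def validate(self) -> None:
        if not self.precursors:
            raise ConfigurationError("toy network needs at least one precursor")
        for prec in self.precursors:
            if not prec.paths:
                raise ConfigurationError(f"precursor {prec.name!r} has no paths")
            for path in prec.paths:
                if path.capacity <= 0:
                    raise ConfigurationError(
                        f"precursor {prec.name!r}: path capacity must be > 0"
                    )
        names = [p.name for p in self.precursors]
        if len(set(names)) != len(names):
            raise ConfigurationError("precursor names must be unique")


def analytic_growth(spec: ToyNetworkSpec, deleted: frozenset[str] = frozenset()) -> float:
    """Growth of the toy network under a gene deletion, by capacity arithmetic.

    A path survives iff none of its gating genes (including core genes) is
    deleted; growth is the minimum over precursors of the surviving
    capacity, capped by the biomass bound.  This evaluator involves no LP
    and serves as the independent oracle for the FBA route.
    """
    growth = float("inf")
    for prec in spec.precursors:
        capacity = sum(
            path.capacity
            for path in prec.paths
            if not (set(path.genes) | set(spec.core_genes)) & deleted
        )
        growth = min(growth, capacity)
    if spec.biomass_cap is not None:
        growth = min(growth, spec.biomass_cap)
    return growth


def make_toy_network(
    spec: ToyNetworkSpec, lethal_threshold: float = 0.5, max_order: int = 4
) -> tuple[MetabolicNetwork, dict[int, list[frozenset[str]]]]:
    """Build the stoichiometric model and its ground-truth SL catalog.

    The catalog lists, per order 1..max_order, the exact minimal lethal
    gene sets implied by the construction, found by exhaustive subset
    enumeration over the analytic capacity evaluator.
    """
    import cobra

    spec.validate()
    if analytic_growth(spec) <= 0:
        raise ConfigurationError("toy network spec yields zero wild-type growth")
    model = cobra.Model(f"toy_seed{spec.seed}")
    mets = {
        prec.name: cobra.Metabolite(f"{prec.name}_c", compartment="c")
        for prec in spec.precursors
    }
    model.add_metabolites(list(mets.values()))
    reactions = []
    rules = []
    for prec in spec.precursors:
        for j, path in enumerate(prec.paths, start=1):
            rxn = cobra.Reaction(f"P_{prec.name}_{j}")
            reactions.append(rxn)
            rules.append((rxn, prec, path))
    biomass = cobra.Reaction("BIOMASS")
    model.add_reactions(reactions + [biomass])
    for rxn, prec, path in rules:
        rxn.add_metabolites({mets[prec.name]: 1.0})
        rxn.bounds = (0.0, float(path.capacity))
        gating = tuple(path.genes) + tuple(spec.core_genes)
        if gating:
            rxn.gene_reaction_rule = " and ".join(gating)
    biomass.add_metabolites({met: -1.0 for met in mets.values()})
    biomass.bounds = (
        0.0,
        float(spec.biomass_cap) if spec.biomass_cap is not None else 1000.0,
    )
    model.objective = "BIOMASS"
    network = MetabolicNetwork(model, "BIOMASS")
    catalog = ground_truth_catalog(spec, lethal_threshold, max_order)
    return network, catalog


def ground_truth_catalog(
    spec: ToyNetworkSpec,
    lethal_threshold: float = 0.5,
    max_order: int = 4,
    inactive_genes: frozenset[str] = frozenset(),
) -> dict[int, list[frozenset[str]]]:
    """Minimal lethal sets per order, by brute force over capacity arithmetic.

    ``inactive_genes`` restricts the network to a context first (their paths
    are unavailable and they are not candidates); reductions are computed
    against the restricted wild type.
    """
    wild_type = analytic_growth(spec, inactive_genes)
    if wild_type <= 0:
        raise ConfigurationError("context has zero wild-type growth")
    genes = [g for g in spec.gene_ids if g not in inactive_genes]

    def lethal(subset: frozenset[str]) -> bool:
        growth = analytic_growth(spec, inactive_genes | subset)
        return 1.0 - growth / wild_type > lethal_threshold

    catalog: dict[int, list[frozenset[str]]] = {k: [] for k in range(1, max_order + 1)}
    lethal_seen: list[frozenset[str]] = []
    for size in range(1, max_order + 1):
        for combo in combinations(genes, size):
            subset = frozenset(combo)
            if any(prev <= subset for prev in lethal_seen):
                continue
            if lethal(subset):
                lethal_seen.append(subset)
                catalog[size].append(subset)
    for size in catalog:
        catalog[size] = sorted(catalog[size], key=sorted)
    return catalog


def random_toy_spec(
    seed: int,
    max_precursors: int = 3,
    max_paths: int = 3,
    max_genes_per_path: int = 2,
) -> ToyNetworkSpec:
    """A random toy network with designed redundancy, for the oracle suite.

    Gene sharing between paths of the same precursor (25% per path) and
    occasional shared core genes (30% of networks) create the AND/OR
    interplay that makes minimal-set enumeration nontrivial.
    """
    rng = np.random.default_rng(seed)
    counter = 0

    def new_gene() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:02d}"

    precursors = []
    for i in range(int(rng.integers(1, max_precursors + 1))):
        paths = []
        local_genes: list[str] = []
        for _ in range(int(rng.integers(1, max_paths + 1))):
            n_genes = int(rng.integers(1, max_genes_per_path + 1))
            genes: list[str] = []
            for _ in range(n_genes):
                if local_genes and rng.random() < 0.25:
                    genes.append(str(rng.choice(local_genes)))
                else:
                    gene = new_gene()
                    genes.append(gene)
                    local_genes.append(gene)
            paths.append(
                PathSpec(capacity=float(rng.integers(1, 11)), genes=tuple(dict.fromkeys(genes)))
            )
        precursors.append(PrecursorSpec(name=f"prec{i + 1}", paths=tuple(paths)))
    core: tuple[str, ...] = ()
    if rng.random() < 0.3:
        core = (new_gene(),)
    return ToyNetworkSpec(precursors=tuple(precursors), core_genes=core, seed=seed)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Two-component log2-FPKM mixture for one context.

    ``active_mask`` fixes which genes draw from the expressed component; if
    None, each gene is active independently with probability
    ``pi_expressed``.  Draws below mean_ne − 3·sd_ne (log2 scale) are
    floored to FPKM 0 to emulate undetected genes.
    """

    gene_ids: tuple[str, ...]
    n_samples: int = 30
    pi_expressed: float = 0.6
    mean_e: float = 4.0
    sd_e: float = 1.5
    mean_ne: float = -4.0
    sd_ne: float = 1.0
    active_mask: tuple[bool, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.sd_e <= 0 or self.sd_ne <= 0:
            raise ConfigurationError("mixture standard deviations must be > 0")
        if not 0 < self.pi_expressed < 1:
            raise ConfigurationError("pi_expressed must lie in (0, 1)")
        if self.mean_e <= self.mean_ne:
            raise ConfigurationError("mean_e must exceed mean_ne")
        if self.active_mask is not None and len(self.active_mask) != len(self.gene_ids):
            raise ConfigurationError("active_mask length must match gene_ids")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be ≥ 1")


def simulate_expression(spec: ExpressionSimSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Draw an FPKM matrix (genes × samples) plus the truth activity labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_genes = len(spec.gene_ids)
    if spec.active_mask is None:
        mask = rng.random(n_genes) < spec.pi_expressed
    else:
        mask = np.asarray(spec.active_mask, dtype=bool)
    means = np.where(mask, spec.mean_e, spec.mean_ne)
    sds = np.where(mask, spec.sd_e, spec.sd_ne)
    log2_fpkm = rng.normal(
        means[:, None], sds[:, None], size=(n_genes, spec.n_samples)
    )
    fpkm = np.exp2(log2_fpkm)
    floor = 2.0 ** (spec.mean_ne - 3.0 * spec.sd_ne)
    fpkm[fpkm < floor] = 0.0
    df = pd.DataFrame(
        fpkm,
        index=pd.Index(spec.gene_ids, name="gene"),
        columns=[f"s{j + 1:02d}" for j in range(spec.n_samples)],
    )
    truth = pd.Series(mask, index=df.index, name="active")
    return df, truth


# ---------------------------------------------------------------------------
# Paired cancer / non-tumor context bundles
# ---------------------------------------------------------------------------


@dataclass
class ContextBundle:
    """Everything needed to run the full pipeline on one designed study.

    ``expression`` holds one FPKM matrix per context (network genes plus
    background genes so the density fit has realistic support);
    ``ground_truth_ssdts`` lists, per order, the gene sets that are minimal
    lethal in the cancer context and reduce every non-tumor context's growth
    by less than the safety threshold — computed entirely by capacity
    arithmetic, independent of the LP pipeline under test.
    """

    spec: ToyNetworkSpec
    network: MetabolicNetwork
    catalog: dict[int, list[frozenset[str]]]
    cancer_label: str
    normal_labels: list[str]
    masks: dict[str, pd.Series]
    expression: dict[str, pd.DataFrame]
    ground_truth_ssdts: dict[int, list[frozenset[str]]]


def _ssdt_ground_truth(
    spec: ToyNetworkSpec,
    cancer_inactive: frozenset[str],
    normal_inactive: Mapping[str, frozenset[str]],
    lethal_threshold: float,
    safe_threshold: float,
    max_order: int,
) -> dict[int, list[frozenset[str]]]:
    candidates = ground_truth_catalog(
        spec, lethal_threshold, max_order, inactive_genes=cancer_inactive
    )
    verdicts: dict[int, list[frozenset[str]]] = {k: [] for k in candidates}
    for order, sets in candidates.items():
        for genes in sets:
            safe = True
            for inactive in normal_inactive.values():
                wild_type = analytic_growth(spec, inactive)
                mutant = analytic_growth(spec, inactive | (genes - inactive))
                if not (1.0 - mutant / wild_type) < safe_threshold:
                    safe = False
                    break
            if safe:
                verdicts[order].append(genes)
    return verdicts


def make_paired_contexts(
    network_spec: ToyNetworkSpec,
    cancer_mask: Mapping[str, bool],
    normal_masks: Mapping[str, Mapping[str, bool]],
    *,
    n_background: int = 400,
    n_samples: int = 30,
    seed: int = 0,
    lethal_threshold: float = 0.5,
    safe_threshold: float = 0.1,
    max_order: int = 4,
    sim_defaults: ExpressionSimSpec | None = None,
) -> ContextBundle:
    """Emit expression matrices for one cancer and several non-tumor contexts.

    The masks say which network genes are transcriptionally active in each
    context; a shared pool of background genes (active with probability
    ``pi_expressed`` in every context) pads the matrices so per-sample
    density fitting behaves as it would on real data.  The designed
    strictly-selective targets implied by the masks are returned alongside.
    """
    network, catalog = make_toy_network(network_spec, lethal_threshold, max_order)
    gene_ids = network_spec.gene_ids
    for label, mask in [("cancer", cancer_mask), *normal_masks.items()]:
        unknown = set(mask) - set(gene_ids)
        if unknown:
            raise ConfigurationError(
                f"mask for context {label!r} references unknown genes {sorted(unknown)}"
            )
    seeds = np.random.SeedSequence(seed).generate_state(len(normal_masks) + 2)
    background_ids = tuple(f"bg{j + 1:04d}" for j in range(n_background))
    background_rng = np.random.default_rng(int(seeds[0]))
    pi = (sim_defaults.pi_expressed if sim_defaults else 0.6)
    background_mask = background_rng.random(n_background) < pi

    def context_matrix(mask: Mapping[str, bool], context_seed: int):
        full_ids = gene_ids + background_ids
        full_mask = tuple(bool(mask.get(g, True)) for g in gene_ids) + tuple(
            background_mask
        )
        base = sim_defaults or ExpressionSimSpec(gene_ids=full_ids)
        spec = replace(
            base,
            gene_ids=full_ids,
            active_mask=full_mask,
            n_samples=n_samples,
            seed=context_seed,
        )
        matrix, truth = simulate_expression(spec)
        return matrix, truth

    cancer_label = "cancer"
    masks: dict[str, pd.Series] = {}
    expression: dict[str, pd.DataFrame] = {}
    matrix, truth = context_matrix(cancer_mask, int(seeds[1]))
    expression[cancer_label] = matrix
    masks[cancer_label] = truth
    normal_labels = list(normal_masks)
    for i, label in enumerate(normal_labels):
        matrix, truth = context_matrix(normal_masks[label], int(seeds[2 + i]))
        expression[label] = matrix
        masks[label] = truth

    cancer_inactive = frozenset(g for g in gene_ids if not cancer_mask.get(g, True))
    normal_inactive = {
        label: frozenset(g for g in gene_ids if not normal_masks[label].get(g, True))
        for label in normal_labels
    }
    ssdts = _ssdt_ground_truth(
        network_spec,
        cancer_inactive,
        normal_inactive,
        lethal_threshold,
        safe_threshold,
        max_order,
    )
    return ContextBundle(
        spec=network_spec,
        network=network,
        catalog=catalog,
        cancer_label=cancer_label,
        normal_labels=normal_labels,
        masks=masks,
        expression=expression,
        ground_truth_ssdts=ssdts,
    )


def demo_study(seed: int = 0, n_samples: int = 30, n_background: int = 400) -> ContextBundle:
    """The bundled demonstration study: one cancer, three protected tissues.

    The network couples six biomass precursors with designed redundancy:

    * precursor A has two equal paths; the cancer silences one, so the gene
      gating the other (``gA1``) becomes a selective essential gene;
    * precursor B has two small paths plus a large rescue path silenced in
      the cancer, yielding the selective pair ``{gB1, gB2}``;
    * precursor C has three mid-size paths active everywhere — its lethal
      pairs are equally lethal in every tissue and are screened out at the
      first protected tissue;
    * precursor D has four small paths plus a rescue silenced only in the
      cancer: its four triples are selective;
    * precursor E has five paths sized so that a triple deletion lands
      exactly on a 50% reduction (non-lethal under the strict criterion)
      while quadruple deletions are lethal, plus a rescue silenced in the
      cancer: its five quadruples are selective;
    * precursor F mirrors B, but its rescue is silenced in the second
      protected tissue as well, so ``{gF1, gF2}`` survives one protection
      step and is then rejected — exercising the protection curve.
    """
    spec = ToyNetworkSpec(
        precursors=(
            PrecursorSpec(
                "A",
                (PathSpec(10.0, ("gA1",)), PathSpec(10.0, ("gA2",))),
            ),
            PrecursorSpec(
                "B",
                (
                    PathSpec(6.0, ("gB1",)),
                    PathSpec(6.0, ("gB2",)),
                    PathSpec(10.0, ("gB3",)),
                ),
            ),
            PrecursorSpec(
                "C",
                (
                    PathSpec(4.0, ("gC1",)),
                    PathSpec(4.0, ("gC2",)),
                    PathSpec(4.0, ("gC3",)),
                ),
            ),
            PrecursorSpec(
                "D",
                (
                    PathSpec(12.0, ("gD0",)),
                    PathSpec(3.0, ("gD1",)),
                    PathSpec(3.0, ("gD2",)),
                    PathSpec(3.0, ("gD3",)),
                    PathSpec(3.0, ("gD4",)),
                ),
            ),
            PrecursorSpec(
                "E",
                (
                    PathSpec(12.0, ("gE0",)),
                    PathSpec(2.5, ("gE1",)),
                    PathSpec(2.5, ("gE2",)),
                    PathSpec(2.5, ("gE3",)),
                    PathSpec(2.5, ("gE4",)),
                    PathSpec(2.5, ("gE5",)),
                ),
            ),
            PrecursorSpec(
                "F",
                (
                    PathSpec(6.0, ("gF1",)),
                    PathSpec(6.0, ("gF2",)),
                    PathSpec(10.0, ("gF0",)),
                ),
            ),
        ),
        biomass_cap=10.0,
        seed=seed,
    )
    off_in_cancer = {"gA2", "gB3", "gD0", "gE0", "gF0"}
    cancer_mask = {g: g not in off_in_cancer for g in spec.gene_ids}
    normal_masks = {
        "normal_matched": {g: True for g in spec.gene_ids},
        "normal_liver": {g: g != "gF0" for g in spec.gene_ids},
        "normal_kidney": {g: True for g in spec.gene_ids},
    }
    return make_paired_contexts(
        spec,
        cancer_mask,
        normal_masks,
        n_background=n_background,
        n_samples=n_samples,
        seed=seed,
    )
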