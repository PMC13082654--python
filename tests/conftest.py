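"""Shared fixtures: hand-designed toy networks and an independent LP oracle."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from slscreen.context_build import ContextModel, build_context
from slscreen.model_core import MetabolicNetwork
from slscreen.synth_data import (
    PathSpec,
    PrecursorSpec,
    ToyNetworkSpec,
    demo_study,
    make_toy_network,
)


def linprog_fba(network: MetabolicNetwork) -> float:
    """Independent FBA oracle: scipy HiGHS on the raw stoichiometric matrix.

    Builds max c·v s.t. S·v = 0, lb ≤ v ≤ ub directly, bypassing cobra's
    solver stack entirely.  Returns the biomass optimum (0 if infeasible
    only at the trivial level; raises if HiGHS reports infeasible).
    """
    from scipy.optimize import linprog

    model = network.cobra_model
    mets = {m.id: i for i, m in enumerate(model.metabolites)}
    rxns = list(model.reactions)
    S = np.zeros((len(mets), len(rxns)))
    bounds = []
    c = np.zeros(len(rxns))
    for j, rxn in enumerate(rxns):
        for met, coef in rxn.metabolites.items():
            S[mets[met.id], j] = coef
        bounds.append((rxn.lower_bound, rxn.upper_bound))
        if rxn.id == network.objective_reaction:
            c[j] = -1.0  # linprog minimizes
    result = linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
    if not result.success:
        raise RuntimeError(f"oracle LP failed: {result.message}")
    return -float(result.fun)


def as_context(network: MetabolicNetwork, label: str = "ctx", condition: str = "cancer") -> ContextModel:
    """Wrap an unrestricted network as a context model (no inactive reactions)."""
    return build_context(network, {}, label, condition)


@pytest.fixture()
def two_path_spec() -> ToyNetworkSpec:
    """One precursor fed by two 5-unit paths gated by g1 and g2.

    Wild-type growth 10; a single deletion leaves 5 (reduction exactly 0.5,
    non-lethal under the strict criterion); the pair is lethal.
    """
    return ToyNetworkSpec(
        precursors=(
            PrecursorSpec("A", (PathSpec(5.0, ("g1",)), PathSpec(5.0, ("g2",)))),
        )
    )


@pytest.fixture()
def two_path_network(two_path_spec) -> MetabolicNetwork:
    network, _ = make_toy_network(two_path_spec)
    return network


@pytest.fixture()
def two_path_context(two_path_network) -> ContextModel:
    return as_context(two_path_network)


@pytest.fixture(scope="session")
def demo_bundle():
    """The bundled differential-vulnerability study (seed 1), built once."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return demo_study(seed=1)
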