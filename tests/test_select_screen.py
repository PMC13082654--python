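"""select_screen: strict-selectivity verdicts, curves, summaries, reports."""

from __future__ import annotations

import itertools

import pytest

from slscreen.context_build import build_context
from slscreen.select_screen import (
    SelectivityRecord,
    cooccurrence_edges,
    gene_frequency,
    percentage_selective,
    protection_curve,
    screen,
)
from slscreen.sl_enum import SLSet, enumerate_sl, essential_genes
from slscreen.synth_data import (
    PathSpec,
    PrecursorSpec,
    ToyNetworkSpec,
    make_toy_network,
    random_toy_spec,
)

from conftest import as_context


def record(genes, selective=True, cancer="COAD", reduction=0.9):
    return SelectivityRecord(
        gene_set=SLSet(tuple(sorted(genes)), 0.0, reduction),
        target_cancer=cancer,
        cancer_reduction=reduction,
        safety={},
        strictly_selective=selective,
    )


class TestPercentageSelective:
    @pytest.mark.parametrize(
        "lethal,selective,expected",
        [(76, 12, 15.8), (145, 57, 39.3), (416, 135, 32.5), (64, 26, 40.6), (7, 7, 100.0)],
    )
    def test_rounding_half_away_from_zero(self, lethal, selective, expected):
        assert percentage_selective(lethal, selective) == expected

    def test_zero_lethal_is_not_applicable(self):
        assert percentage_selective(0, 0) is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            percentage_selective(3, 5)


@pytest.fixture()
def differential_pair_setup():
    """Pathway B rescue silenced in the cancer: {b1, b2} is lethal there but
    harmless in the non-tumor context where the rescue is active."""
    spec = ToyNetworkSpec(
        precursors=(
            PrecursorSpec(
                "B",
                (
                    PathSpec(6.0, ("b1",)),
                    PathSpec(6.0, ("b2",)),
                    PathSpec(10.0, ("rescue",)),
                ),
            ),
        ),
        biomass_cap=10.0,
    )
    network, _ = make_toy_network(spec)
    cancer = build_context(network, {"P_B_3": -1}, "cancer")
    normal = as_context(network, "normal", "non_tumor")
    return cancer, normal


class TestScreen:
    def test_clean_pass_is_selective(self, differential_pair_setup):
        cancer, normal = differential_pair_setup
        candidates = enumerate_sl(cancer, 2)
        assert {c.gene_set for c in candidates} == {frozenset({"b1", "b2"})}
        records = screen(candidates, cancer, [normal])
        assert records[0].strictly_selective
        assert records[0].safety["normal"] == pytest.approx(0.0, abs=1e-9)

    def test_harmful_in_protected_tissue_rejected(self, differential_pair_setup):
        cancer, _ = differential_pair_setup
        candidates = enumerate_sl(cancer, 2)
        # protect a copy of the cancer context itself: reduction 1.0 there
        records = screen(candidates, cancer, [cancer])
        assert not records[0].strictly_selective
        assert records[0].failed_tissue == "cancer"

    def test_reduction_point_twelve_rejected(self):
        """A 12% growth reduction in a protected tissue disqualifies."""
        spec = ToyNetworkSpec(
            precursors=(
                PrecursorSpec("A", (PathSpec(8.8, ("keep",)), PathSpec(1.2, ("hit",)))),
            ),
        )
        network, _ = make_toy_network(spec)
        protected = as_context(network, "prot", "non_tumor")
        lethal_spec = ToyNetworkSpec(
            precursors=(PrecursorSpec("A", (PathSpec(5.0, ("hit",)),)),)
        )
        cancer = as_context(make_toy_network(lethal_spec)[0], "cancer")
        candidate = SLSet(("hit",), 0.0, 1.0)
        records = screen([candidate], cancer, [protected])
        assert records[0].safety["prot"] == pytest.approx(0.12, abs=1e-6)
        assert not records[0].strictly_selective

    def test_exact_thresholds_are_strict(self, two_path_network):
        """Reduction exactly 0.5 in the cancer is not lethal; reduction
        exactly 0.1 in a protected tissue is not safe."""
        cancer = as_context(two_path_network, "cancer")
        half = SLSet(("g1",), 5.0, 0.5)  # deleting one of two 5-unit paths
        spec = ToyNetworkSpec(
            precursors=(
                PrecursorSpec("A", (PathSpec(9.0, ("keep",)), PathSpec(1.0, ("g1",)))),
            ),
        )
        tenth = as_context(make_toy_network(spec)[0], "prot", "non_tumor")
        records = screen([half], cancer, [tenth])
        assert records[0].cancer_reduction == pytest.approx(0.5, abs=1e-9)
        assert records[0].safety["prot"] == pytest.approx(0.1, abs=1e-9)
        assert not records[0].strictly_selective

    def test_gene_absent_from_protected_model_is_noop(self, differential_pair_setup):
        cancer, _ = differential_pair_setup
        other = ToyNetworkSpec(
            precursors=(PrecursorSpec("Z", (PathSpec(5.0, ("z1",)),)),)
        )
        foreign = as_context(make_toy_network(other)[0], "foreign", "non_tumor")
        records = screen(enumerate_sl(cancer, 2), cancer, [foreign])
        assert records[0].safety["foreign"] == 0.0
        assert records[0].strictly_selective

    def test_protected_order_invariance(self, demo_bundle):
        scores = {r: -1 for r in ("P_A_2", "P_B_3", "P_D_1", "P_E_1", "P_F_3")}
        cancer = build_context(demo_bundle.network, scores, "cancer")
        protected = [
            as_context(demo_bundle.network, f"n{i}", "non_tumor") for i in range(3)
        ]
        candidates = essential_genes(cancer) + enumerate_sl(cancer, 3)
        baseline = None
        for perm in itertools.permutations(protected):
            verdicts = {
                r.gene_set.gene_set: r.strictly_selective
                for r in screen(candidates, cancer, list(perm))
            }
            baseline = baseline or verdicts
            assert verdicts == baseline


class TestProtectionCurve:
    def test_no_attrition(self, differential_pair_setup):
        cancer, normal = differential_pair_setup
        candidates = enumerate_sl(cancer, 2)
        curve = protection_curve(candidates, cancer, [normal])
        assert curve.counts[2] == [1]

    def test_total_attrition_when_last_tissue_is_harmed(self, differential_pair_setup):
        cancer, normal = differential_pair_setup
        candidates = enumerate_sl(cancer, 2)
        curve = protection_curve(candidates, cancer, [normal, cancer])
        assert curve.counts[2] == [1, 0]

    def test_monotone_on_random_fixtures(self):
        """Counts never increase as more tissues are protected (5 seeds)."""
        import numpy as np

        checked = 0
        for seed in range(10):
            if checked >= 5:
                break
            spec = random_toy_spec(seed, max_precursors=2, max_paths=2)
            network, _ = make_toy_network(spec, max_order=2)
            rng = np.random.default_rng(seed)
            try:
                cancer = as_context(network, "cancer")
                protected = []
                for i in range(3):
                    scores = {
                        r: -1 if rng.random() < 0.3 else 0
                        for r in network.reaction_ids
                    }
                    protected.append(
                        build_context(network, scores, f"n{i}", "non_tumor")
                    )
            except Exception:
                continue
            candidates = essential_genes(cancer) + enumerate_sl(cancer, 2)
            if not candidates:
                continue
            curve = protection_curve(candidates, cancer, protected)
            for counts in curve.counts.values():
                assert all(a >= b for a, b in zip(counts, counts[1:]))
            checked += 1
        assert checked >= 3


class TestReports:
    def test_gene_frequency_counts_and_order(self):
        records = [
            record({"gA", "gB"}),
            record({"gA", "gC"}),
            record({"gB"}),
            record({"gZ"}, selective=False),
        ]
        freq = gene_frequency(records)
        assert freq.index.tolist() == ["gA", "gB", "gC"]
        assert freq.tolist() == [2, 2, 1]
        assert gene_frequency([]).empty

    def test_cooccurrence_edges(self):
        triple = record({"a", "b", "c"})
        assert len(cooccurrence_edges([triple])) == 3
        assert cooccurrence_edges([record({"solo"})]) == []
        quad = record({"a", "b", "c", "d"})
        assert len(cooccurrence_edges([quad, quad])) == 6  # dedup
        assert cooccurrence_edges([record({"x", "y"}, selective=False)]) == []


class TestPercentageProperties:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(
        lethal=st.integers(min_value=1, max_value=10_000),
        selective=st.integers(min_value=0, max_value=10_000),
    )
    @settings(derandomize=True, max_examples=200)
    def test_bounded_and_exact_at_edges(lethal, selective):
        from hypothesis import assume

        assume(selective <= lethal)
        value = percentage_selective(lethal, selective)
        assert 0.0 <= value <= 100.0
        if selective == lethal:
            assert value == 100.0
        if selective == 0:
            assert value == 0.0
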