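"""Unit and property tests for the prioritization funnel."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secrepair.funnel import (
    AnnotationBundle,
    DetectionTable,
    SecretomeFunnel,
    annotate_factors,
    consistent_proteins,
    expression_flags_from_matrix,
    marker_enrichment,
    receptor_filter,
    run_funnel,
    secretion_filter,
    venn_partition,
)
from secrepair.simulate import SecretomeFixtureConfig, generate_secretome_fixture

from conftest import make_detection_frame


class TestDetectionTable:
    def test_duplicate_key_rejected(self):
        rows = [("P1", "G1", "EV", 1, True), ("P1", "G1", "EV", 1, False)]
        with pytest.raises(ValueError, match="duplicate"):
            DetectionTable(make_detection_frame(rows))

    def test_unknown_fraction_rejected(self):
        rows = [("P1", "G1", "PLASMA", 1, True)]
        with pytest.raises(ValueError, match="fraction"):
            DetectionTable(make_detection_frame(rows))

    def test_intensity_binarization(self):
        df = pd.DataFrame(
            {
                "protein_id": ["P1", "P1"],
                "gene_symbol": ["G1", "G1"],
                "fraction": ["EV", "EV"],
                "replicate": [1, 2],
                "intensity": [0.0, 12.5],
            }
        )
        t = DetectionTable.from_dataframe(df)
        assert t.frame["detected"].tolist() == [False, True]

    def test_dialect_mapping(self):
        df = pd.DataFrame(
            {
                "acc": ["P1"],
                "symbol": ["g1 "],
                "frac": ["ev"],
                "rep": [1],
                "detected": [True],
            }
        )
        t = DetectionTable.from_dataframe(
            df,
            dialect={
                "protein_id": "acc",
                "gene_symbol": "symbol",
                "fraction": "frac",
                "replicate": "rep",
            },
        )
        assert t.frame.loc[0, "gene_symbol"] == "G1"
        assert t.frame.loc[0, "fraction"] == "EV"


class TestConsistency:
    def test_all_replicates_default(self, toy_table):
        assert consistent_proteins(toy_table, "EV") == {f"G{i}" for i in range(1, 7)}

    def test_min_one_is_identified_universe(self, toy_table):
        got = consistent_proteins(toy_table, "EV", min_replicates=1)
        # proteins 1-6 fully detected, 8-10 partially, 7 never in EV
        assert got == {f"G{i}" for i in range(1, 11)} - {"G7"}

    def test_absent_fraction_errors(self):
        t = DetectionTable(make_detection_frame([("P1", "G1", "EV", 1, True)]))
        with pytest.raises(ValueError, match="absent"):
            consistent_proteins(t, "SF")


class TestVenn:
    def test_example_partition(self):
        v = venn_partition({"A", "B", "C"}, {"B", "C", "D"})
        assert v.ev_only == {"A"} and v.both == {"B", "C"} and v.sf_only == {"D"}

    def test_disjoint_inputs(self):
        v = venn_partition({"A"}, {"B"})
        assert not v.both

    @given(
        ev=st.sets(st.sampled_from("ABCDEFGH"), max_size=8),
        sf=st.sets(st.sampled_from("ABCDEFGH"), max_size=8),
    )
    @settings(derandomize=True, max_examples=50)
    def test_partition_conserves_union(self, ev, sf):
        v = venn_partition(ev, sf)
        assert len(v.ev_only) + len(v.sf_only) + len(v.both) == len(ev | sf)
        assert len(v.ev_only) + len(v.both) == len(ev)
        assert v.ev_only.isdisjoint(v.sf_only)
        assert v.union == ev | sf


class TestAnnotationStages:
    def test_annotate_intersection(self, small_bundle):
        assert annotate_factors({"GF1", "X"}, small_bundle) == {"GF1"}

    def test_annotate_empty_intersection_is_not_error(self, small_bundle):
        assert annotate_factors({"X", "Y"}, small_bundle) == set()

    def test_empty_gene_set_errors(self, small_bundle):
        small_bundle.growth_factor_cytokine_set = set()
        with pytest.raises(ValueError, match="empty"):
            annotate_factors({"GF1"}, small_bundle)

    def test_secretion_any_vs_all(self, small_bundle):
        factors = {"GF1", "GF2", "GF3"}
        assert secretion_filter(factors, small_bundle, mode="any") == {"GF1", "GF3"}
        assert secretion_filter(factors, small_bundle, mode="all") == {"GF3"}

    def test_secretion_missing_call_dropped_by_default(self, small_bundle):
        assert secretion_filter({"UNKNOWN"}, small_bundle) == set()

    def test_secretion_requires_predictors(self):
        bundle = AnnotationBundle(
            growth_factor_cytokine_set={"GF1"},
            secretion_calls={},
            ligand_receptor_pairs=set(),
            receptor_expression={},
        )
        with pytest.raises(ValueError, match="predictor"):
            secretion_filter({"GF1"}, bundle)

    def test_receptor_filter_keeps_expressed(self, small_bundle):
        kept, dropped = receptor_filter({"GF1", "GF2", "GF3"}, small_bundle)
        assert [c.gene_symbol for c in kept] == ["GF1"]
        assert kept[0].receptors == ("R1",) and kept[0].cell_types == ("AT2",)
        assert dropped["GF2"] == "no known receptor"
        assert "not expressed" in dropped["GF3"]

    def test_expression_flags_from_matrix(self):
        expr = pd.DataFrame(
            {"AT1": [0.05, 0.5], "AT2": [0.11, 0.0]}, index=["R1", "R2"]
        )
        flags = expression_flags_from_matrix(expr, fraction_threshold=0.10)
        assert flags[("R1", "AT2")] and not flags[("R1", "AT1")]
        assert flags[("R2", "AT1")] and not flags[("R2", "AT2")]


class TestRunFunnel:
    def test_fixture_recovery(self):
        cfg = SecretomeFixtureConfig(seed=1, n_proteins=200, n_planted_candidates=5)
        table, bundle, truth = generate_secretome_fixture(cfg)
        res = run_funnel(table, bundle)
        assert res.candidate_set == truth.expected_candidate_set
        got = {s: per or n for s, n, per in res.stage_counts}
        exp = truth.expected_stage_counts
        assert got["identified"] == exp["identified"]
        assert got["consistent"] == exp["consistent"]
        assert got["venn"] == exp["venn"]
        for stage in ("growth_factor", "secreted", "receptor_matched"):
            total = dict(
                (s, n) for s, n, _ in res.stage_counts
            )[stage]
            assert total == exp[stage]

    def test_empty_table(self, small_bundle):
        t = DetectionTable(make_detection_frame([]))
        res = run_funnel(t, small_bundle)
        assert all(n == 0 for _, n, _ in res.stage_counts)
        assert res.candidates == []

    def test_stage_monotonicity_and_order_insensitivity(self):
        rng = np.random.default_rng(7)
        for seed in rng.integers(0, 2**31, size=5):
            cfg = SecretomeFixtureConfig(
                seed=int(seed), n_proteins=60, n_planted_candidates=3,
                detection_noise=0.05,
            )
            table, bundle, truth = generate_secretome_fixture(cfg)
            res = run_funnel(table, bundle)
            chain = ["consistent", "growth_factor", "secreted", "receptor_matched"]
            for a, b in zip(chain, chain[1:]):
                assert res.surviving_sets[b] <= res.surviving_sets[a]
            assert res.surviving_sets["consistent"] <= res.surviving_sets["identified"]
            # permuting input rows changes nothing
            shuffled = DetectionTable(
                table.frame.sample(frac=1, random_state=int(seed) % 1000)
            )
            res2 = run_funnel(shuffled, bundle)
            assert res2.candidate_set == res.candidate_set
            assert [n for _, n, _ in res2.stage_counts] == [
                n for _, n, _ in res.stage_counts
            ]

    def test_summary_mentions_candidates(self):
        cfg = SecretomeFixtureConfig(seed=3, n_proteins=80, n_planted_candidates=2)
        table, bundle, truth = generate_secretome_fixture(cfg)
        text = SecretomeFunnel(table, bundle).run().summary()
        for gene in truth.expected_candidate_set:
            assert gene in text


def hypergeom_two_sided_p(table):
    """Exact two-sided Fisher p by enumerating the hypergeometric support."""
    a, b = table[0]
    c, d = table[1]
    n1, n2, k = a + b, c + d, a + c

    def prob(x):
        return (
            math.comb(n1, x)
            * math.comb(n2, k - x)
            / math.comb(n1 + n2, k)
        )

    p_obs = prob(a)
    lo, hi = max(0, k - n2), min(k, n1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestMarkerEnrichment:
    def _table(self, records):
        return DetectionTable(make_detection_frame(records))

    def _full(self, gene, fraction, detected=True):
        return [(gene, gene, fraction, rep, detected) for rep in range(1, 5)]

    def test_identical_composition_gives_unit_odds(self):
        rows = []
        for g in ("M1", "M2", "N1", "N2"):
            rows += self._full(g, "EV") + self._full(g, "SF")
        odds, p, counts = marker_enrichment(self._table(rows), {"M1", "M2"})
        assert odds == pytest.approx(1.0)

    def test_markers_only_in_ev_gives_infinite_odds(self):
        rows = self._full("M1", "EV") + self._full("M1", "SF", False)
        rows += self._full("N1", "EV") + self._full("N1", "SF")
        rows += self._full("N2", "SF") + self._full("N2", "EV", False)
        odds, p, counts = marker_enrichment(self._table(rows), {"M1"})
        assert math.isinf(odds)

    def test_exact_p_matches_enumeration(self):
        # build consistent sets giving the 2x2 table (8,2;2,8)
        rows = []
        for i in range(8):
            rows += self._full(f"MEV{i}", "EV")
        for i in range(2):
            rows += self._full(f"MSF{i}", "SF")
        for i in range(2):
            rows += self._full(f"NEV{i}", "EV")
        for i in range(8):
            rows += self._full(f"NSF{i}", "SF")
        markers = {f"MEV{i}" for i in range(8)} | {f"MSF{i}" for i in range(2)}
        odds, p, counts = marker_enrichment(self._table(rows), markers)
        assert counts.tolist() == [[8, 2], [2, 8]]
        assert p == pytest.approx(hypergeom_two_sided_p(counts.tolist()), rel=1e-9)
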