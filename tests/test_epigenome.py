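"""Promoter signals, expression calls and epigenetic-deregulation calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbcompare import (
    ExpressionStudy,
    IntegrationConfig,
    OrthologPairSet,
    call_expression,
    classify_epigenetic,
    cross_species_overlap,
    mark_deltas,
    promoter_signal,
)
from rbcompare.epigenome import MARKS
from rbcompare.synthetic import SimConfig, gen_expression_pair, gen_promoter_marks


def _delta_frame(gene, k4, ac, k9, meth):
    rows = []
    for mark, tumor in zip(MARKS, (k4, ac, k9, meth)):
        rows.append((gene, mark, tumor, 0.0))
    return mark_deltas(pd.DataFrame(rows, columns=["gene", "mark", "tumor", "normal"]))


def _expr_calls(gene, call):
    return pd.DataFrame({"call": [call], "logfc": [0.0]}, index=[gene])


class TestPromoterSignal:
    def _tables(self):
        signals = pd.Series({"p1": 2.0, "p2": 4.0, "p3": 8.0})
        coords = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [900, 5000, 10_300],
                "end": [950, 5050, 10_350],
            },
            index=["p1", "p2", "p3"],
        )
        return signals, coords

    def test_single_probe_in_window(self):
        signals, coords = self._tables()
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [1000], "strand": ["+"]},
                           index=["gA"])
        out = promoter_signal(signals, coords, tss)
        assert out["gA"] == pytest.approx(2.0)

    def test_no_probe_gives_missing_not_zero(self):
        signals, coords = self._tables()
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [50_000], "strand": ["+"]},
                           index=["gB"])
        out = promoter_signal(signals, coords, tss)
        assert np.isnan(out["gB"])

    def test_minus_strand_window_extends_to_higher_coordinates(self):
        signals, coords = self._tables()
        # probe p3 sits ~1.3 kb *downstream in genome coordinates* of tss=9000;
        # only a minus-strand gene (upstream = higher coords) captures it
        tss_minus = pd.DataFrame({"chrom": ["chr1"], "tss": [9000], "strand": ["-"]},
                                 index=["gC"])
        tss_plus = tss_minus.assign(strand="+")
        assert promoter_signal(signals, coords, tss_minus)["gC"] == pytest.approx(8.0)
        assert np.isnan(promoter_signal(signals, coords, tss_plus)["gC"])

    def test_malformed_probe_coordinates_rejected(self):
        signals = pd.Series({"p1": 1.0})
        coords = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [100]},
                              index=["p1"])
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [100], "strand": ["+"]},
                           index=["g"])
        with pytest.raises(ValueError, match="start >= end"):
            promoter_signal(signals, coords, tss)


class TestCallExpression:
    def test_null_data_calibration(self):
        """~5% raw p <= 0.05 on null data; none survive FDR + logFC."""
        rng = np.random.default_rng(8)
        n = 5000
        mat = rng.normal(0, 1, (n, 12))
        study = ExpressionStudy(mat, [f"g{i}" for i in range(n)],
                                ["tumor"] * 6 + ["control"] * 6)
        out = call_expression(study)
        raw_rate = (out["pvalue"] <= 0.05).mean()
        assert abs(raw_rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n)
        assert (out["call"] != "none").sum() <= 2

    def test_planted_strong_gene_called_up(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(0, 0.2, (100, 10))
        mat[0, :5] += 3.0
        study = ExpressionStudy(mat, [f"g{i}" for i in range(100)],
                                ["tumor"] * 5 + ["control"] * 5)
        out = call_expression(study)
        assert out.loc["g0", "call"] == "up"

    def test_constant_gene_degenerate_none(self):
        mat = np.vstack([np.ones(8), np.random.default_rng(0).normal(0, 1, 8)])
        study = ExpressionStudy(mat, ["flat", "noisy"],
                                ["tumor"] * 4 + ["control"] * 4)
        out = call_expression(study)
        assert out.loc["flat", "call"] == "none"
        assert bool(out.loc["flat", "degenerate"])


class TestClassifyEpigenetic:
    def test_active_mark_gain_makes_epi_up(self):
        cfg = IntegrationConfig()
        deltas = _delta_frame("g", 3 * cfg.tau_active, 3 * cfg.tau_active, 0, 0)
        out = classify_epigenetic(_expr_calls("g", "up"), deltas, cfg)
        assert out.loc["g", "epi_call"] == "epi-up"

    def test_expression_gating_is_absolute(self):
        cfg = IntegrationConfig()
        deltas = _delta_frame("g", 10, 10, -10, -10)
        out = classify_epigenetic(_expr_calls("g", "none"), deltas, cfg)
        assert out.loc["g", "epi_call"] == "not-epi"

    def test_discordant_only_evidence_is_not_epi(self):
        cfg = IntegrationConfig()
        # expression up but marks move the repressed way
        deltas = _delta_frame("g", -10, -10, 10, 10)
        out = classify_epigenetic(_expr_calls("g", "up"), deltas, cfg)
        assert out.loc["g", "epi_call"] == "not-epi"

    def test_methylation_loss_alone_suffices(self):
        cfg = IntegrationConfig()
        deltas = _delta_frame("g", 0, 0, 0, -3 * cfg.tau_meth)
        out = classify_epigenetic(_expr_calls("g", "up"), deltas, cfg)
        assert out.loc["g", "epi_call"] == "epi-up"
        assert bool(out.loc["g", "meth_evidence"])

    def test_missing_marks_excluded_and_reported(self):
        cfg = IntegrationConfig()
        deltas = _delta_frame("g", 5, 5, 0, 0)
        calls = pd.DataFrame({"call": ["up", "up"]}, index=["g", "absent"])
        out = classify_epigenetic(calls, deltas, cfg)
        assert out.loc["absent", "status"] == "missing-marks"
        assert out.loc["g", "epi_call"] == "epi-up"

    @given(st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=40, derandomize=True)
    def test_monotone_in_thresholds(self, tau, bump):
        """Raising any tau never converts not-epi into epi."""
        deltas = _delta_frame("g", 2.5, 2.5, -1.0, -1.0)
        lo = IntegrationConfig(tau_active=tau, tau_repressive=tau, tau_meth=tau)
        hi = IntegrationConfig(tau_active=tau + bump, tau_repressive=tau + bump,
                               tau_meth=tau + bump)
        call_lo = classify_epigenetic(_expr_calls("g", "up"), deltas, lo).loc["g", "epi_call"]
        call_hi = classify_epigenetic(_expr_calls("g", "up"), deltas, hi).loc["g", "epi_call"]
        if call_lo == "not-epi":
            assert call_hi == "not-epi"

    def test_planted_epi_genes_recovered(self):
        """Precision and recall >= 0.9 at mark_shift = 3x noise_sd."""
        cfg = SimConfig(seed=21)
        study_m, _, _, truth = gen_expression_pair(cfg)
        marks = gen_promoter_marks(cfg, truth)
        calls = call_expression(study_m)
        deltas = mark_deltas(marks)
        epi = classify_epigenetic(calls.loc[truth.features["feature_m"]], deltas)
        called = set(epi.index[epi["epi_call"].isin(["epi-up", "epi-down"])])
        planted = set(truth.features.loc[truth.features["epi"], "feature_m"])
        tp = len(called & planted)
        assert tp / max(len(called), 1) >= 0.9
        assert tp / len(planted) >= 0.9


class TestCrossSpeciesOverlap:
    def _calls(self, mapping):
        return pd.DataFrame(
            {
                "expr_call": [v[0] for v in mapping.values()],
                "epi_call": [v[1] for v in mapping.values()],
            },
            index=list(mapping),
        )

    def test_disjoint_sets_no_overlap(self):
        c1 = self._calls({"A": ("up", "epi-up"), "B": ("none", "not-epi")})
        c2 = self._calls({"a": ("none", "not-epi"), "b": ("down", "epi-down")})
        pairs = OrthologPairSet([("A", "a"), ("B", "b")])
        out = cross_species_overlap(c1, c2, pairs)
        assert out.n_both == 0 and out.n_epi_both == 0

    def test_identical_calls_all_same_direction(self):
        c1 = self._calls({"A": ("up", "epi-up"), "B": ("down", "epi-down")})
        c2 = self._calls({"a": ("up", "epi-up"), "b": ("down", "epi-down")})
        pairs = OrthologPairSet([("A", "a"), ("B", "b")])
        out = cross_species_overlap(c1, c2, pairs)
        assert out.n_both == out.n_both_same_direction == 2
        assert out.n_epi_both == out.n_epi_both_same_direction == 2

    def test_toy_enumeration(self):
        """3 epi-up vs {up, down}: two joint epi pairs, one same-direction."""
        c1 = self._calls({g: ("up", "epi-up") for g in "ABC"})
        c2 = self._calls({"a": ("up", "epi-up"), "b": ("down", "epi-down"),
                          "c": ("none", "not-epi")})
        pairs = OrthologPairSet([("A", "a"), ("B", "b"), ("C", "c")])
        out = cross_species_overlap(c1, c2, pairs)
        assert out.n_epi_both == 2
        assert out.n_epi_both_same_direction == 1

    def test_unmapped_genes_counted(self):
        c1 = self._calls({"A": ("up", "epi-up")})
        c2 = self._calls({"a": ("up", "epi-up")})
        pairs = OrthologPairSet([("A", "a"), ("Z", "a")])
        out = cross_species_overlap(c1, c2, pairs)
        assert out.n_unmapped_pairs == 1

    def test_invariants_on_synthetic_run(self):
        cfg = SimConfig(seed=2, n_features_m=800, n_features_h=800)
        sm, sh, pairs, truth = gen_expression_pair(cfg)
        calls_m = call_expression(sm)
        calls_h = call_expression(sh)
        cm = pd.DataFrame({"expr_call": calls_m["call"], "epi_call": "not-epi"},
                          index=calls_m.index)
        ch = pd.DataFrame({"expr_call": calls_h["call"], "epi_call": "not-epi"},
                          index=calls_h.index)
        out = cross_species_overlap(cm, ch, pairs)
        assert out.n_epi_both <= min(out.n_epi_1, out.n_epi_2)
        assert out.n_both_same_direction <= out.n_both
        assert out.n_both <= min(out.n_dereg_species1, out.n_dereg_species2)
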