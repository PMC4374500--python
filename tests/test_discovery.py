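import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from modmark import (
    CASE,
    NORMAL,
    DiscoveryConfig,
    ExpressionMatrix,
    NormalFitPair,
    PhenotypeLabels,
    PPINetwork,
    activity_correlations,
    disa,
    discover_modules,
    fit_group_normals,
    grow_module,
    module_activity,
    overlap_area,
)
from modmark.discovery import ActivityVector
from .conftest import make_group_expr


def overlap_quadrature(mu1, s1, mu2, s2):
    """Independent oracle: adaptive integration of min(pdf1, pdf2), with the
    density crossings located by root bracketing."""
    lo = min(mu1 - 12 * s1, mu2 - 12 * s2)
    hi = max(mu1 + 12 * s1, mu2 + 12 * s2)
    f = lambda x: norm.pdf(x, mu1, s1) - norm.pdf(x, mu2, s2)
    xs = np.linspace(lo, hi, 4001)
    fx = f(xs)
    crossings = [
        brentq(f, xs[i], xs[i + 1])
        for i in range(len(xs) - 1)
        if fx[i] * fx[i + 1] < 0
    ]
    val, _ = quad(
        lambda x: min(norm.pdf(x, mu1, s1), norm.pdf(x, mu2, s2)),
        lo, hi, limit=500, points=crossings or None,
        epsabs=1e-13, epsrel=1e-12,
    )
    return val


class TestModuleActivity:
    def test_single_gene_is_its_row(self, tiny_expr):
        act = module_activity(tiny_expr, ["g1"])
        np.testing.assert_array_equal(act.values, tiny_expr.row("g1"))

    def test_all_ones_rows(self):
        genes = [f"g{i}" for i in range(4)]
        expr = ExpressionMatrix(genes, ["s1", "s2", "s3", "s4"],
                                np.ones((4, 4)))
        act = module_activity(expr, genes)
        np.testing.assert_allclose(act.values, 2.0)  # 4 / sqrt(4)

    def test_duplicate_row_scaling(self):
        v = np.array([1.0, -2.0, 3.0, 0.5])
        expr = ExpressionMatrix(["a", "b"], ["s1", "s2", "s3", "s4"],
                                np.vstack([v, v]))
        act = module_activity(expr, ["a", "b"])
        np.testing.assert_allclose(act.values, math.sqrt(2) * v, atol=1e-12)

    def test_unknown_member_is_error(self, tiny_expr):
        with pytest.raises(KeyError, match="gX"):
            module_activity(tiny_expr, ["g1", "gX"])


class TestGroupFits:
    def test_two_point_groups(self, tiny_labels):
        act = ActivityVector(["s1", "s2", "s3", "s4"],
                             np.array([0.0, 2.0, 10.0, 12.0]))
        fit = fit_group_normals(act, tiny_labels)
        assert fit.mu_N == pytest.approx(1.0)
        assert fit.sigma_N == pytest.approx(math.sqrt(2))
        assert fit.mu_C == pytest.approx(11.0)
        assert fit.sigma_C == pytest.approx(math.sqrt(2))

    def test_five_point_sd(self):
        labels = PhenotypeLabels(
            {f"s{i}": NORMAL for i in range(1, 6)}
            | {f"s{i}": CASE for i in range(6, 11)}
        )
        act = ActivityVector([f"s{i}" for i in range(1, 11)],
                             np.array([1, 2, 3, 4, 5, 0, 1, 0, 1, 0.5]))
        fit = fit_group_normals(act, labels)
        assert fit.mu_N == pytest.approx(3.0)
        assert fit.sigma_N == pytest.approx(math.sqrt(2.5))

    def test_constant_group_is_degenerate(self, tiny_labels):
        act = ActivityVector(["s1", "s2", "s3", "s4"],
                             np.array([1.0, 1.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="degenerate"):
            fit_group_normals(act, tiny_labels)


class TestOverlapArea:
    def test_identical_distributions(self):
        assert overlap_area(NormalFitPair(0.3, 1.2, 0.3, 1.2)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_equal_sigma_closed_form(self):
        # 2 * Phi(-|dmu| / 2 sigma)
        got = overlap_area(NormalFitPair(0.0, 1.0, 2.0, 1.0))
        assert got == pytest.approx(2 * norm.cdf(-1.0), abs=1e-12)
        assert got == pytest.approx(0.31731, abs=1e-5)

    def test_unequal_sigma_against_quadrature(self):
        got = overlap_area(NormalFitPair(0.0, 1.0, 0.0, 2.0))
        assert got == pytest.approx(overlap_quadrature(0, 1, 0, 2), abs=1e-10)
        assert got == pytest.approx(0.677325, abs=1e-6)

    def test_nonpositive_sigma_is_error(self):
        with pytest.raises(ValueError):
            NormalFitPair(0, 0.0, 1, 1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m1, m2 = rng.uniform(-10, 10, 2)
            s1, s2 = rng.uniform(0.1, 5, 2)
            a = overlap_area(NormalFitPair(m1, s1, m2, s2))
            b = overlap_area(NormalFitPair(m2, s2, m1, s1))
            assert b == pytest.approx(a, abs=1e-12)
            c = rng.uniform(-5, 5)
            shifted = overlap_area(NormalFitPair(m1 + c, s1, m2 + c, s2))
            assert shifted == pytest.approx(a, abs=1e-9)
            k = rng.uniform(0.2, 4)
            scaled = overlap_area(NormalFitPair(k * m1, k * s1, k * m2, k * s2))
            assert scaled == pytest.approx(a, abs=1e-9)

    def test_decreasing_in_mean_gap_at_equal_sigma(self):
        vals = [overlap_area(NormalFitPair(0, 1, d, 1))
                for d in np.linspace(0, 6, 13)]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestDisa:
    def test_planted_shift_gives_small_disa(self):
        # activity gap of ~6 pooled SDs -> overlap ~ 2 Phi(-3) ~ 0.0027
        rng = np.random.default_rng(0)
        expr, labels = make_group_expr(rng, 20, 100, shift_genes=["g1"],
                                       shift=6.0)
        val = disa(expr, labels, ["g1"])
        assert val < 0.01

    def test_pure_noise_disa_large(self):
        rng = np.random.default_rng(1)
        expr, labels = make_group_expr(rng, 5, 200)
        val = disa(expr, labels, ["g1", "g2", "g3"])
        assert val > 0.8

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        expr, labels = make_group_expr(rng, 6, 30, shift_genes=["g1"],
                                       shift=1.0)
        swapped = PhenotypeLabels(
            {s: (CASE if v == NORMAL else NORMAL)
             for s, v in labels.labels.items()}
        )
        assert disa(expr, swapped, ["g1", "g2"]) == pytest.approx(
            disa(expr, labels, ["g1", "g2"]), abs=1e-12
        )


def _toy_instance(seed_rng, n_genes=5, n_per_group=40):
    """Star network around g1 with exactly one signal-bearing neighbour."""
    rng = np.random.default_rng(seed_rng)
    expr, labels = make_group_expr(
        rng, n_genes, n_per_group, shift_genes=["g1", "g2"], shift=1.2
    )
    edges = [("g1", f"g{i}") for i in range(2, n_genes + 1)]
    return expr, labels, PPINetwork.from_edges(edges)


class TestGrowModule:
    def test_isolated_seed(self):
        rng = np.random.default_rng(0)
        expr, labels = make_group_expr(rng, 3, 10, shift_genes=["g1"], shift=2)
        net = PPINetwork.from_edges([("g2", "g3")], nodes=["g1"])
        m = grow_module("g1", net, expr, labels)
        assert m.members == ["g1"] and m.trace == []

    def test_signal_neighbour_added_first(self):
        expr, labels, net = _toy_instance(5)
        cfg = DiscoveryConfig()
        m = grow_module("g1", net, expr, labels, cfg)
        # exhaustive oracle over all single additions
        candidates = sorted(net.neighborhood(["g1"]))
        best = min(candidates, key=lambda g: disa(expr, labels, ["g1", g]))
        assert best == "g2"
        assert m.members[1] == best

    def test_trace_strictly_decreasing(self):
        expr, labels, net = _toy_instance(6)
        m = grow_module("g1", net, expr, labels)
        seq = [disa(expr, labels, ["g1"])] + [d for _, d in m.trace]
        assert all(b < a for a, b in zip(seq, seq[1:]))
        # the recorded disa equals the value recomputed from the members
        assert m.disa == pytest.approx(disa(expr, labels, m.members), abs=1e-12)

    def test_deterministic(self):
        expr, labels, net = _toy_instance(7)
        a = grow_module("g1", net, expr, labels)
        b = grow_module("g1", net, expr, labels)
        assert a == b

    def test_size_cap(self):
        expr, labels, net = _toy_instance(8)
        cfg = DiscoveryConfig(max_module_size=2, require_improvement=False)
        m = grow_module("g1", net, expr, labels, cfg)
        assert m.size <= 2

    def test_missing_seed_is_error(self):
        expr, labels, net = _toy_instance(9)
        with pytest.raises(KeyError):
            grow_module("gX", net, expr, labels)


class TestDiscoverModules:
    def test_filter_and_connectivity(self, default_instance):
        expr, labels, net, *_ , truth = default_instance
        from modmark.preprocess import restrict_to_common_genes, zscore_rows

        net, expr = restrict_to_common_genes(net, expr)
        expr = zscore_rows(expr)
        seeds = sorted(truth.planted_genes)[:5]
        cfg = DiscoveryConfig()
        mods = discover_modules(seeds, net, expr, labels, cfg)
        assert mods, "planted seeds should yield surviving modules"
        for m in mods:
            assert m.disa <= cfg.disa_filter
            assert net.is_connected_subset(m.members)
        disas = [m.disa for m in mods]
        assert disas == sorted(disas)

    def test_permissive_filter_keeps_all(self):
        expr, labels, net = _toy_instance(10)
        cfg = DiscoveryConfig(disa_filter=1.0)
        mods = discover_modules(["g1", "g3"], net, expr, labels, cfg)
        assert len(mods) == 2

    def test_duplicate_seeds_deduplicated(self):
        expr, labels, net = _toy_instance(11)
        cfg = DiscoveryConfig(disa_filter=1.0)
        mods = discover_modules(["g1", "g1", "g1"], net, expr, labels, cfg)
        assert len(mods) == 1


class TestActivityCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(4)
        n = 6
        genes = [f"g{i}" for i in range(1, n + 1)]
        vals = rng.standard_normal((n, 8))
        vals[1] = -vals[0]
        expr = ExpressionMatrix(genes, [f"s{i}" for i in range(8)], vals)
        from modmark import Module

        mods = [
            Module("g1", ["g1"], 0.1),
            Module("g2", ["g2"], 0.1),
        ]
        cc = activity_correlations(mods, expr)
        assert cc[0, 0] == pytest.approx(1.0)
        assert cc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_pearson(self):
        # v=(1,2,3,4), w=(1,2,3,100): cov sum 149, dev^2 sums 5 and 7205
        from modmark import Module

        expr = ExpressionMatrix(
            ["a", "b"], ["s1", "s2", "s3", "s4"],
            np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 100]]),
        )
        cc = activity_correlations(
            [Module("a", ["a"], 0.1), Module("b", ["b"], 0.1)], expr
        )
        assert cc[0, 1] == pytest.approx(149 / math.sqrt(5 * 7205), abs=1e-12)

    def test_zero_variance_flagged_not_fatal(self):
        from modmark import Module

        expr = ExpressionMatrix(
            ["a", "b"], ["s1", "s2", "s3", "s4"],
            np.array([[1.0, 2, 3, 4], [2.0, 2, 2, 2]]),
        )
        cc = activity_correlations(
            [Module("a", ["a"], 0.1), Module("b", ["b"], 0.1)], expr
        )
        assert np.isnan(cc[0, 1]) and np.isnan(cc[1, 1])
        assert cc[0, 0] == pytest.approx(1.0)
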