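"""MCMC kernel, operators and posterior summaries.

Operator correctness is established distributionally: with a flat
likelihood the chain must reproduce the prior, which is exactly how the
platform's own proposals are validated.
"""

import math

import numpy as np
import pytest
from scipy.stats import chisquare, expon, kstest, norm

from skytree.mcmc import (
    ExchangeOperator,
    GroupRateScaleOperator,
    McmcState,
    OperatorSchedule,
    RJSplitMergeOperator,
    SAToggleOperator,
    ScaleOperator,
    TipHeightOperator,
    TraceLog,
    TreeScaleOperator,
    UniformNodeHeightOperator,
    WilsonBaldingOperator,
    clade_supports,
    compute_ess,
    credible_model_set,
    hpd_interval,
    run_mcmc,
    site_model_log_prior,
    summarize_mcc,
)
from skytree.mcmc.rjsite import _merge_options, _split_options
from skytree.simulate import simulate_bd_tree, simulate_coalescent_tree
from skytree.substitution import (
    SiteModel,
    enumerate_model_set,
    merge_neighbors,
    split_neighbors,
)
from skytree.treeprior import (
    BDParams,
    CoalescentParams,
    bd_serial_log_density,
    coalescent_log_density,
)

from conftest import build_tree


class TestKernel:
    def test_scale_operator_samples_exponential_prior(self):
        state = McmcState(params={"x": 1.0})
        res = run_mcmc(
            state,
            lambda s: -s.params["x"] if s.params["x"] > 0 else -math.inf,
            OperatorSchedule([ScaleOperator("x")]),
            chain_length=250000,
            log_every=50,
            seed=3,
        )
        xs = res.trace.burned(0.15)["x"]
        assert kstest(xs, expon.cdf).pvalue > 0.01

    def test_same_seed_bit_identical(self, rng):
        tree = simulate_coalescent_tree(5, 1.0, rng)
        cp = CoalescentParams(1.0)
        def make():
            ops = [TreeScaleOperator(1.0), UniformNodeHeightOperator(2.0),
                   ExchangeOperator(1.0), WilsonBaldingOperator(1.0)]
            return run_mcmc(
                McmcState(tree=tree.copy()),
                lambda s: coalescent_log_density(s.tree, cp),
                OperatorSchedule(ops), chain_length=3000, log_every=10, seed=77,
            )
        a, b = make(), make()
        assert a.trace.table.equals(b.trace.table)

    def test_infinite_start_rejected_with_advice(self):
        state = McmcState(params={"x": -1.0})
        with pytest.raises(ValueError, match="starting"):
            run_mcmc(
                state,
                lambda s: -math.inf,
                OperatorSchedule([ScaleOperator("x")]),
                chain_length=10,
                seed=1,
            )

    def test_trace_first_column_is_sample(self):
        import pandas as pd

        with pytest.raises(ValueError, match="Sample"):
            TraceLog(pd.DataFrame({"posterior": [1.0]}))

    def test_trace_tsv_round_trip(self, tmp_path):
        state = McmcState(params={"x": 1.0})
        res = run_mcmc(
            state, lambda s: -s.params["x"],
            OperatorSchedule([ScaleOperator("x")]),
            chain_length=100, log_every=10, seed=5,
        )
        p = str(tmp_path / "trace.log")
        res.trace.write_tsv(p)
        back = TraceLog.read_tsv(p)
        assert back.table.columns[0] == "Sample"
        assert np.allclose(back["x"], res.trace["x"])


class TestTreeOperators:
    def test_uniform_height_respects_bounds(self, rng):
        tree = simulate_coalescent_tree(6, 1.0, rng)
        tree.origin_height = tree.root.height + 1.0
        op = UniformNodeHeightOperator()
        state = McmcState(tree=tree)
        for _ in range(200):
            prop = op.propose(state, rng)
            assert prop is not None
            prop[0].tree.validate()

    def test_wilson_balding_uniform_over_three_topologies(self):
        rng = np.random.default_rng(1)
        tree = simulate_coalescent_tree(3, 1.0, rng)
        cp = CoalescentParams(1.0)
        ops = [TreeScaleOperator(1.0), UniformNodeHeightOperator(1.0),
               WilsonBaldingOperator(3.0)]
        res = run_mcmc(
            McmcState(tree=tree),
            lambda s: coalescent_log_density(s.tree, cp),
            OperatorSchedule(ops), chain_length=60000, log_every=10, seed=13,
            loggers=[("cherry", lambda s: _cherry(s.tree))],
        )
        counts = res.trace.burned(0.1).table["cherry"].value_counts()
        assert set(counts.index) == {"t1t2", "t1t3", "t2t3"}
        assert chisquare(counts.to_numpy()).pvalue > 0.01

    def test_exchange_preserves_validity(self, rng):
        tree = simulate_coalescent_tree(8, 1.0, rng)
        op = ExchangeOperator()
        state = McmcState(tree=tree)
        n_ok = 0
        for _ in range(300):
            prop = op.propose(state, rng)
            if prop is not None:
                prop[0].tree.validate()
                n_ok += 1
        assert n_ok > 10


def _cherry(tree):
    labels = []
    for n in tree.preorder():
        if len(n.children) == 2 and all(c.is_leaf for c in n.children):
            labels = sorted(c.taxon.label for c in n.children)
    return "".join(labels)


class TestSampledAncestorToggle:
    @pytest.fixture
    def serial_state(self):
        rng = np.random.default_rng(7)
        b = BDParams(t0=3.0, lam=1.0, mu=0.3, psi=0.6, r=0.0, rho=0.0)
        tree = simulate_bd_tree(b, rng, conditioning="at_least_n_samples",
                                min_samples=4)
        return McmcState(tree=tree), b

    def test_double_toggle_returns_to_dimension_class(self, serial_state, rng):
        state, _ = serial_state
        op = SAToggleOperator()
        n0 = len(state.tree.sampled_ancestors)
        for _ in range(100):
            prop = op.propose(state, rng)
            if prop is None:
                continue
            mid, _ = prop
            n1 = len(mid.tree.sampled_ancestors)
            assert abs(n1 - n0) == 1
            # toggling the same sample back restores the class
            back = None
            for _ in range(200):
                cand = op.propose(mid, rng)
                if cand is not None and len(cand[0].tree.sampled_ancestors) == n0:
                    back = cand[0]
                    break
            assert back is not None
            back.tree.validate()
            break

    def test_full_removal_forbids_sampled_ancestors_in_chain(self):
        rng = np.random.default_rng(9)
        b1 = BDParams(t0=3.0, lam=1.0, mu=0.3, psi=0.6, r=1.0, rho=0.0)
        tree = simulate_bd_tree(b1, rng, conditioning="at_least_n_samples",
                                min_samples=4)
        state = McmcState(tree=tree)
        ops = [TreeScaleOperator(1.0), UniformNodeHeightOperator(2.0),
               TipHeightOperator(2.0), SAToggleOperator(2.0)]
        res = run_mcmc(
            state,
            lambda s: bd_serial_log_density(s.tree, b1, "none"),
            OperatorSchedule(ops), chain_length=20000, log_every=20, seed=3,
        )
        assert res.trace["n_sampled_ancestors"].max() == 0


class TestReversibleJump:
    def test_split_then_merge_reconstructs_rates(self):
        rng = np.random.default_rng(2)
        ms = enumerate_model_set("all_reversible")
        op = RJSplitMergeOperator(ms)
        state = McmcState(site=SiteModel(code="111111",
                                         group_rates=np.array([1.7])))
        split = None
        while split is None:
            cand = op._split(state, state.site, rng)
            split = cand
        mid = split[0]
        assert max(int(c) for c in mid.site.code) == 2
        merged = op._merge(mid, mid.site, rng)[0]
        assert merged.site.code == "111111"
        assert merged.site.group_rates[0] == pytest.approx(1.7, abs=1e-12)

    def test_proposal_support_matches_brute_force_neighbors(self):
        ms = enumerate_model_set("no_ti_tv_sharing")
        for code in ("121121", "111111", "121131"):
            from skytree.substitution import canonical_code

            split_support = {
                canonical_code(d) for _, _, d in _split_options(code, ms)
            }
            merge_support = {
                canonical_code(d) for _, _, d in _merge_options(code, ms)
            }
            assert split_support == set(split_neighbors(code, ms))
            assert merge_support == set(merge_neighbors(code, ms))

    def test_indicator_flips_sample_their_bernoulli_prior(self):
        from skytree.mcmc import (
            FrequencyFlipOperator,
            GammaFlipOperator,
            InvariantFlipOperator,
        )

        ms = enumerate_model_set("all_reversible")
        state = McmcState(site=SiteModel())
        ops = [FrequencyFlipOperator(1.0), GammaFlipOperator(1.0),
               InvariantFlipOperator(1.0)]
        res = run_mcmc(
            state, lambda s: site_model_log_prior(s.site, ms),
            OperatorSchedule(ops), chain_length=20000, log_every=10, seed=6,
            loggers=[
                ("freqs_equal", lambda s: int(s.site.freqs_equal)),
                ("use_gamma", lambda s: int(s.site.use_gamma)),
                ("use_inv", lambda s: int(s.site.use_inv)),
                ("gamma_shape", lambda s: s.site.gamma_shape
                 if s.site.use_gamma else np.nan),
            ],
        )
        tr = res.trace.burned(0.1)
        for col in ("freqs_equal", "use_gamma", "use_inv"):
            freq = tr[col].mean()
            assert 0.42 < freq < 0.58, (col, freq)
        # activated gamma shapes are fresh Exp(1) prior draws
        shapes = tr["gamma_shape"]
        shapes = shapes[~np.isnan(shapes)]
        assert len(shapes) > 100
        assert 0.7 < shapes.mean() < 1.3

    def test_uniform_visits_small_set(self):
        # restricted 31-code set mixes fast enough for a compact check;
        # the full 203-code uniformity lives in the acceptance suite
        ms = enumerate_model_set("no_ti_tv_sharing")
        state = McmcState(site=SiteModel())
        ops = [RJSplitMergeOperator(ms, weight=3.0), GroupRateScaleOperator(weight=1.0)]
        res = run_mcmc(
            state, lambda s: site_model_log_prior(s.site, ms),
            OperatorSchedule(ops), chain_length=120000, log_every=15, seed=4,
            loggers=[("code", lambda s: s.site.code)],
        )
        codes = res.trace.burned(0.05).table["code"]
        counts = codes.value_counts()
        assert set(counts.index) == set(ms)
        assert chisquare(counts.to_numpy()).pvalue > 0.01


class TestSummaries:
    def test_ess_iid_normals(self):
        x = np.random.default_rng(0).normal(size=10000)
        assert 8500 <= compute_ess(x) <= 11500

    def test_ess_constant_is_zero(self):
        assert compute_ess(np.ones(100)) == 0.0

    def test_ess_ar1_closed_form(self):
        rng = np.random.default_rng(8)
        phi, n = 0.5, 20000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        # ESS(AR1) = n (1-phi)/(1+phi) = n/3
        assert compute_ess(x) == pytest.approx(n / 3, rel=0.15)

    def test_credible_set_cumulative_rule(self):
        codes = ["A"] * 60 + ["B"] * 30 + ["C"] * 10
        got = credible_model_set(codes, level=0.95)
        assert [c for c, _ in got] == ["A", "B", "C"]
        got90 = credible_model_set(codes, level=0.90)
        assert [c for c, _ in got90] == ["A", "B"]

    def test_credible_set_singleton(self):
        got = credible_model_set(["111111"] * 10)
        assert got == [("111111", 1.0)]

    def test_credible_set_matches_brute_force(self, rng):
        freqs = {"a": 0.42, "b": 0.31, "c": 0.15, "d": 0.08, "e": 0.04}
        codes = [c for c, f in freqs.items() for _ in range(int(f * 1000))]
        got = [c for c, _ in credible_model_set(codes, 0.95)]
        import itertools

        best = None
        for k in range(1, 6):
            for sub in itertools.combinations(freqs, k):
                if sum(freqs[c] for c in sub) >= 0.95 - 1e-9:
                    if best is None or len(sub) < len(best):
                        best = sub
        assert len(got) == len(best)

    def test_hpd_matches_quantile_oracle(self):
        x = np.random.default_rng(3).normal(size=20000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.08)
        assert hi == pytest.approx(1.96, abs=0.08)

    def test_clade_supports_single_tree(self, three_taxon_tree):
        sup = clade_supports([three_taxon_tree] * 5)
        assert all(v == 1.0 for v in sup.values())
        assert frozenset({"A", "B"}) in sup

    def test_clade_supports_counts(self):
        t_ab = build_tree((2.0, (1.0, ("A", 0.0), ("B", 0.0)), ("C", 0.0)))
        t_ac = build_tree((2.0, (1.0, ("A", 0.0), ("C", 0.0)), ("B", 0.0)))
        sup = clade_supports([t_ab, t_ab, t_ac, t_ab])
        assert sup[frozenset({"A", "B"})] == pytest.approx(0.75)
        assert sup[frozenset({"A", "C"})] == pytest.approx(0.25)

    def test_mcc_single_tree_log(self, three_taxon_tree):
        mcc = summarize_mcc([three_taxon_tree] * 3)
        assert mcc.supports[frozenset({"A", "B"})] == 1.0
        assert mcc.tree.n_tips == 3

    def test_mcc_prefers_majority_topology(self):
        t_ab = build_tree((2.0, (1.0, ("A", 0.0), ("B", 0.0)), ("C", 0.0)))
        t_ac = build_tree((2.0, (1.0, ("A", 0.0), ("C", 0.0)), ("B", 0.0)))
        mcc = summarize_mcc([t_ab, t_ab, t_ac])
        cherries = {
            frozenset(c.taxon.label for c in n.children)
            for n in mcc.tree.preorder()
            if len(n.children) == 2 and all(c.is_leaf for c in n.children)
        }
        assert frozenset({"A", "B"}) in cherries
        clade = frozenset({"A", "B"})
        assert mcc.height_mean[clade] == pytest.approx(1.0)
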