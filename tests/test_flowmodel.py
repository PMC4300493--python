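"""Transforms, baseline estimator, subproblem closed form, full fits, flows."""

import itertools
import math

import numpy as np
import pytest
from scipy import optimize, stats

import riboflow as rf
from riboflow.flowmodel import (
    FitConfig, ModelFit, baseline_dwells, codon_rates, compute_flows,
    objective_value, restricted_positions, solve_codon_subproblem,
    transform_counts,
)


def make_profiles(genes, counts):
    return {
        g: rf.FootprintProfile(g, np.asarray(c), None, 1.0)
        for g, c in counts.items()
    }


class TestRestrictedPositions:
    @pytest.mark.parametrize(
        "L,expected",
        [
            (200, range(100, 200)),   # first 100 codons ignored
            (80, range(20, 80)),      # first 25% for genes under 100
            (100, range(100, 100)),   # exactly 100 -> empty, unusable
            (1, range(1, 1)),
            (101, range(100, 101)),
        ],
    )
    def test_branches(self, L, expected):
        assert restricted_positions(L) == expected

    def test_quarter_rounds_up(self):
        # 25% of 9 codons = 2.25 -> start at codon 3
        assert restricted_positions(9) == range(3, 9)


class TestTransformCounts:
    def test_single_gene_hand_pipeline(self):
        # raw [0, 2], D = 1 -> pseudo [1, 3] -> flow-norm [1, 3];
        # dataset minimum already 1 -> scale 1
        profs = make_profiles(None, {"g": [0, 2]})
        tc = transform_counts(profs)
        assert tc.global_scale == 1.0
        assert tc.dprime["g"].tolist() == [1.0, 3.0]
        assert tc.gene_mean["g"] == 1.0

    def test_global_scale_applies_to_all(self):
        # gA: D=2, pseudo [1,5]/2 = [0.5, 2.5] -> min 0.5 -> scale 2
        profs = make_profiles(None, {"gA": [0, 4], "gB": [1, 1]})
        tc = transform_counts(profs)
        assert tc.global_scale == 2.0
        assert tc.dprime["gA"].tolist() == [1.0, 5.0]
        assert tc.dprime["gB"].tolist() == [4.0, 4.0]

    def test_all_zero_counts_uniform(self):
        profs = {
            g: rf.FootprintProfile(g, np.zeros(4, dtype=int), None, 1.0)
            for g in ("a", "b")
        }
        tc = transform_counts(profs, J_fixed={"a": 1.0, "b": 1.0})
        for g in ("a", "b"):
            assert np.all(tc.dprime[g] == 1.0)

    def test_nonpositive_flow_rejected(self):
        profs = make_profiles(None, {"g": [0, 0]})
        with pytest.raises(ValueError, match="positive"):
            transform_counts(profs)  # D = 0


class TestBaselineDwells:
    def test_uniform_counts_uniform_dwells(self):
        genes = {"g": rf.GeneRecord("g", "ATG" + "AAACCC" * 3 + "TAA")}
        profs = make_profiles(genes, {"g": [4] * 7})  # 7 sense codons
        dwell, rate = baseline_dwells(profs, genes)
        vals = set(dwell.values())
        assert len(vals) == 1
        (v,) = vals
        assert v == pytest.approx(5 / 4)  # (d+1)/D with d=4, D=4
        assert all(rate[c] == pytest.approx(1 / dwell[c]) for c in dwell)

    def test_normalized_average(self):
        # one codon type with normalized pseudo counts {1, 2} -> dwell 1.5
        genes = {"g": rf.GeneRecord("g", "ATG" + "AAA" * 8 + "TAA")}
        counts = np.array([2, 2, 2, 2, 2, 2, 2, 2, 4])
        profs = make_profiles(genes, {"g": counts})
        dwell, _ = baseline_dwells(profs, genes)
        # restricted region of 9 codons starts at ceil(0.25*9)=3
        expected = np.mean((counts[3:] + 1) / counts.mean())
        assert dwell["AAA"] == pytest.approx(expected)

    def test_rate_is_reciprocal(self):
        genes = {"g": rf.GeneRecord("g", "ATG" + "AAA" * 8 + "TAA")}
        profs = make_profiles(genes, {"g": [3] * 9})
        dwell, rate = baseline_dwells(profs, genes)
        assert rate["AAA"] == pytest.approx(1 / dwell["AAA"])


def _tc_for(genes, counts):
    profs = make_profiles(genes, counts)
    return transform_counts(profs, genes=genes)


class TestObjectiveValue:
    def _fit(self, mu_gene, mu_global, weights, C, tc):
        return ModelFit(mu_gene=mu_gene, mu_global=mu_global, J={},
                        weights=weights, objective_trace=[],
                        config=FitConfig(C=C))

    def test_data_term_closed_form(self):
        # one gene, one codon type, d' = {e, e^3}, mu = e^2 -> (1-2)^2+(3-2)^2
        genes = {"g": rf.GeneRecord("g", "ATG" + "AAA" * 8 + "TAA")}
        tc = _tc_for(genes, {"g": [1] * 9})
        tc.restricted["g"] = range(7, 9)
        tc.dprime["g"] = np.array([1.0] * 7 + [math.e, math.e**3])
        fit = self._fit({("g", "AAA"): math.e**2}, {"AAA": math.e**2},
                        {("g", "AAA"): 1.0}, 0.0, tc)
        assert objective_value(fit, tc) == pytest.approx(2.0)

    def test_zero_penalty_when_equal(self):
        genes = {"g": rf.GeneRecord("g", "ATG" + "AAA" * 8 + "TAA")}
        tc = _tc_for(genes, {"g": [2] * 9})
        for C in (0.0, 100.0, 1e4):
            fit = self._fit({("g", "AAA"): 1.5}, {"AAA": 1.5},
                            {("g", "AAA"): 1.0}, C, tc)
            base = objective_value(fit, tc)
            assert base == pytest.approx(
                sum((np.log(tc.dprime["g"][k]) - np.log(1.5)) ** 2
                    for k in tc.restricted["g"])
            )

    def test_penalty_linear_in_C(self):
        genes = {"g": rf.GeneRecord("g", "ATG" + "AAA" * 8 + "TAA")}
        tc = _tc_for(genes, {"g": [2] * 9})
        args = ({("g", "AAA"): 2.0}, {"AAA": 1.0}, {("g", "AAA"): 1.0})
        f0 = objective_value(self._fit(*args, 0.0, tc), tc)
        f1 = objective_value(self._fit(*args, 100.0, tc), tc)
        f2 = objective_value(self._fit(*args, 200.0, tc), tc)
        assert f2 - f0 == pytest.approx(2 * (f1 - f0))


class TestCodonSubproblem:
    def test_single_gene_C0_geometric_mean(self):
        genes = {"g": rf.GeneRecord("g", "ATG" + "AAA" * 8 + "TAA")}
        tc = _tc_for(genes, {"g": [1, 2, 3, 4, 5, 6, 7, 8, 9]})
        mu_g, _mu = solve_codon_subproblem("AAA", tc, C=0.0)
        y = np.log(tc.dprime["g"][3:])
        assert mu_g["g"] == pytest.approx(float(np.exp(y.mean())))

    def test_large_C_weighted_geometric_mean(self):
        genes = {
            "a": rf.GeneRecord("a", "ATG" + "AAA" * 8 + "TAA"),
            "b": rf.GeneRecord("b", "ATG" + "AAA" * 8 + "TAA"),
        }
        tc = _tc_for(genes, {"a": [1] * 9, "b": [5] * 9})
        mu_g, mu = solve_codon_subproblem("AAA", tc, C=1e12)
        ya = np.log(tc.dprime["a"][3:]).sum()
        yb = np.log(tc.dprime["b"][3:]).sum()
        expected = float(np.exp((ya + yb) / 12))  # 6+6 positions, equal weights
        assert mu == pytest.approx(expected, rel=1e-6)
        assert mu_g["a"] == pytest.approx(expected, rel=1e-4)
        assert mu_g["b"] == pytest.approx(expected, rel=1e-4)

    def test_two_equal_genes_symmetry(self):
        genes = {
            "a": rf.GeneRecord("a", "ATG" + "AAA" * 8 + "TAA"),
            "b": rf.GeneRecord("b", "ATG" + "AAA" * 8 + "TAA"),
        }
        tc = _tc_for(genes, {"a": [3] * 9, "b": [3] * 9})
        mu_g, mu = solve_codon_subproblem("AAA", tc, C=100.0)
        assert mu_g["a"] == pytest.approx(mu_g["b"])
        assert mu_g["a"] == pytest.approx(mu)

    @pytest.mark.parametrize("C", [0.0, 1.0, 100.0])
    def test_agrees_with_numeric_minimizer(self, C):
        """Closed form vs direct numeric minimization of the objective on a
        3-gene instance (the independent oracle)."""
        rng = np.random.default_rng(42)
        genes = {
            g: rf.GeneRecord(g, "ATG" + "AAA" * 6 + "CCC" * 2 + "TAA")
            for g in ("a", "b", "c")
        }
        counts = {g: rng.integers(1, 30, size=9) for g in genes}
        tc = _tc_for(genes, counts)
        mu_g, mu = solve_codon_subproblem("AAA", tc, C=C)

        gids = sorted(genes)
        stats_y = {}
        for g in gids:
            r = tc.restricted[g]
            cods = tc.codons[g][r.start:r.stop]
            stats_y[g] = np.log(tc.dprime[g][r.start:r.stop][cods == "AAA"])
        n = np.array([len(stats_y[g]) for g in gids], dtype=float)
        w = n / n.sum()

        def obj(params):
            beta, bbar = params[:-1], params[-1]
            val = sum(
                float(((stats_y[g] - beta[i]) ** 2).sum())
                for i, g in enumerate(gids)
            )
            return val + C * float((w * (beta - bbar) ** 2).sum())

        x0 = np.zeros(len(gids) + 1)
        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 20000})
        for i, g in enumerate(gids):
            assert math.log(mu_g[g]) == pytest.approx(res.x[i], abs=1e-4)
        if C > 0:
            assert math.log(mu) == pytest.approx(res.x[-1], abs=1e-4)


class TestFitModel:
    def test_uniform_truth(self):
        """Uniform true dwells: fitted global dwells equal within 2% and
        flows proportional to mean counts."""
        rng = np.random.default_rng(5)
        genes = rf.synthdata.simulate_genome(100, mean_length=300, seed=5)
        profiles = {}
        for g, rec in genes.items():
            lam = 300.0 * (0.8 + 0.4 * rng.random())
            profiles[g] = rf.FootprintProfile(
                g, rng.poisson(lam, size=rec.n_codons), None, 1.0
            )
        fit = rf.fit_model(genes, profiles, FitConfig(seed=2))
        mus = np.array(list(fit.mu_global.values()))
        assert mus.max() / mus.min() < 1.02
        D = np.array([profiles[g].mean_count for g in fit.J])
        J = np.array([fit.J[g] for g in fit.J])
        r = stats.pearsonr(D, J).statistic
        assert r > 0.999

    def test_deterministic_reruns(self, small_world):
        genes, _truth, profiles = small_world
        f1 = rf.fit_model(genes, profiles, FitConfig(seed=7))
        f2 = rf.fit_model(genes, profiles, FitConfig(seed=7))
        assert f1.mu_global == f2.mu_global
        assert f1.mu_gene == f2.mu_gene
        assert f1.J == f2.J
        assert f1.objective_trace == f2.objective_trace

    def test_trace_non_increasing(self, small_fit):
        fit, _tc = small_fit
        tr = fit.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(tr, tr[1:]))

    def test_weights_sum_to_one(self, small_fit):
        fit, _tc = small_fit
        totals = {}
        for (_g, c), w in fit.weights.items():
            totals[c] = totals.get(c, 0.0) + w
        assert all(abs(t - 1.0) < 1e-9 for t in totals.values())

    def test_scale_equivariance_large_counts(self):
        """x5 raw counts: global dwells nearly invariant, flows ~x5."""
        genes = rf.synthdata.simulate_genome(30, mean_length=150, seed=9)
        truth = rf.synthdata.simulate_dwells(genes, seed=10)
        prof1 = rf.synthdata.simulate_footprints(truth, depth=150.0)
        prof5 = {
            g: rf.FootprintProfile(g, p.counts * 5, p.mrna_counts,
                                   p.mrna_abundance)
            for g, p in prof1.items()
        }
        f1 = rf.fit_model(genes, prof1, FitConfig(seed=3))
        f5 = rf.fit_model(genes, prof5, FitConfig(seed=3))
        logs = [math.log(f5.mu_global[c] / f1.mu_global[c]) for c in f1.mu_global]
        assert np.std(logs) < 0.02
        ratios = [f5.J[g] / f1.J[g] for g in f1.J]
        assert np.allclose(ratios, 5.0, rtol=0.05)

    def test_global_only_matches_infinite_C(self, small_world):
        genes, _truth, profiles = small_world
        fg = rf.fit_model(genes, profiles, FitConfig(mode="global_only", seed=1))
        finf = rf.fit_model(genes, profiles, FitConfig(C=1e12, seed=1))
        for c in fg.mu_global:
            assert math.log(fg.mu_global[c]) == pytest.approx(
                math.log(finf.mu_global[c]), abs=1e-5
            )

    def test_per_position_variant_consistent(self, small_world):
        genes, _truth, profiles = small_world
        fpp = rf.fit_model(genes, profiles, FitConfig(mode="per_position", seed=1))
        fref = rf.fit_model(genes, profiles, FitConfig(seed=1))
        cods = sorted(fref.mu_global)
        rho = stats.spearmanr([fpp.mu_global[c] for c in cods],
                              [fref.mu_global[c] for c in cods]).statistic
        assert rho > 0.95
        tr = fpp.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(tr, tr[1:]))

    def test_poisson_loss_variant(self, small_world):
        genes, _truth, profiles = small_world
        fp = rf.fit_model(genes, profiles, FitConfig(loss="poisson", seed=1))
        fref = rf.fit_model(genes, profiles, FitConfig(seed=1))
        cods = sorted(fref.mu_global)
        rho = stats.spearmanr([fp.mu_global[c] for c in cods],
                              [fref.mu_global[c] for c in cods]).statistic
        assert rho > 0.95


class TestFlows:
    def test_identity_dwells(self, toy_genes):
        tc = _tc_for(toy_genes, {g: [2] * 8 for g in toy_genes})
        mu_global = {c: 1.0 for c in ("AAA", "CCC", "GGG", "ATG")}
        fit = ModelFit({}, mu_global, {}, {}, [], FitConfig())
        J = compute_flows(tc, fit)
        for g in toy_genes:
            expected = tc.gene_mean[g] * float(np.mean(tc.dprime[g]))
            assert J[g] == pytest.approx(expected)

    def test_homogeneity_in_dwells(self, toy_genes):
        tc = _tc_for(toy_genes, {g: [1, 2, 3, 4, 5, 6, 7, 8] for g in toy_genes})
        mus = {c: 2.0 for c in ("AAA", "CCC", "GGG", "ATG")}
        half = {c: 1.0 for c in mus}
        J2 = compute_flows(tc, ModelFit({}, mus, {}, {}, [], FitConfig()))
        J1 = compute_flows(tc, ModelFit({}, half, {}, {}, [], FitConfig()))
        for g in toy_genes:
            assert J1[g] == pytest.approx(2 * J2[g])

    def test_toy_arithmetic(self):
        # counts on the flow axis [2, 6], dwells [1, 3] -> J = (2/1 + 6/3)/2
        genes = {"g": rf.GeneRecord("g", "ATGAAACCCTAA")}
        prof = {"g": rf.FootprintProfile("g", np.array([0, 1, 5]), None, 1.0)}
        tc = transform_counts(prof, genes=genes)
        # d' = (d+1)/D = [0.5, 1, 3] * scale 2 = [1, 2, 6]; D = 2
        fit = ModelFit({}, {"ATG": 1.0, "AAA": 1.0, "CCC": 3.0}, {}, {}, [],
                       FitConfig())
        J = compute_flows(tc, fit)
        assert J["g"] == pytest.approx(2.0 * (1 / 1 + 2 / 1 + 6 / 3) / 3)

    def test_flow_conservation_by_construction(self, small_fit):
        fit, tc = small_fit
        for g in itertools.islice(fit.J, 5):
            cods = tc.codons[g]
            mu = np.array([
                fit.mu_gene.get((g, c), fit.mu_global[c]) for c in cods
            ])
            recomputed = tc.gene_mean[g] * float(np.mean(tc.dprime[g] / mu))
            assert recomputed == pytest.approx(fit.J[g], rel=1e-12)


class TestCodonRates:
    def test_normalization(self):
        fit = ModelFit({}, {"AAA": 2.0, "CCC": 4.0}, {}, {}, [], FitConfig())
        rates = codon_rates(fit)
        assert rates == {"AAA": 2.0, "CCC": 1.0}

    def test_all_equal(self):
        fit = ModelFit({}, {c: 3.0 for c in ("AAA", "CCC", "GGG")}, {}, {}, [],
                       FitConfig())
        assert set(codon_rates(fit).values()) == {1.0}

    def test_cardinality(self, small_fit):
        fit, _tc = small_fit
        assert len(codon_rates(fit)) == len(fit.mu_global)
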