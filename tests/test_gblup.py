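"""GBLUP fitting, cross-validation, bias, and the paired encoding test."""
import numpy as np
import pandas as pd
import pytest

import tetradose as td
from conftest import make_genotypes
from tetradose.gblup import CVResult


def _random_grm(n, seed=0, n_markers=200):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, n_markers)) / np.sqrt(n_markers)
    return td.GRM(sample_ids=[f"S{i}" for i in range(n)], values=Z @ Z.T)


def _quick_sim(h2, seed, n=250, m=800, n_qtl=0):
    """Small panel with noiseless (true allele fraction) genotypes."""
    cfg = td.SimConfig(n_parents=8, n_offspring=n - 8, n_loci=m,
                       n_chromosomes=3, duplicate_fraction=0.0, seed=seed,
                       traits=(td.TraitSpec("t", h2=h2, n_qtl=n_qtl,
                                            polygenic_share=1.0 if n_qtl == 0 else 0.5),))
    truth = td.simulate_population(cfg)
    ph = td.simulate_phenotypes(truth, cfg)
    geno = td.GenotypeMatrix(truth.sample_ids, truth.locus_map,
                             truth.true_af, "continuous")
    return geno, ph.values["t"]


class TestFitGblup:
    def test_fixed_ratio_matches_closed_form(self):
        """With a supplied variance ratio the GEBVs equal the direct
        linear-algebra solution g = sg2*G V^-1 (y - mu)."""
        n = 40
        G = _random_grm(n, seed=1)
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(size=n), index=G.sample_ids)
        lam = 1.7
        fit = td.fit_gblup(y, G, fixed_ratio=lam)
        V = fit.sigma2_g * G.values + fit.sigma2_e * np.eye(n)
        Vinv = np.linalg.inv(V)
        ones = np.ones(n)
        mu = (ones @ Vinv @ y.values) / (ones @ Vinv @ ones)
        g = fit.sigma2_g * G.values @ Vinv @ (y.values - mu)
        assert fit.sigma2_e / fit.sigma2_g == pytest.approx(lam)
        assert fit.mu == pytest.approx(mu)
        assert np.allclose(fit.gebv.to_numpy(), g, atol=1e-8)

    def test_null_trait_recovers_low_h2(self):
        geno, y = _quick_sim(h2=0.0, seed=3, n=500)
        G = td.build_grm(geno)
        fit = td.fit_gblup(y, G)
        assert fit.h2 < 0.1

    def test_unphenotyped_samples_receive_gebvs(self):
        geno, y = _quick_sim(h2=0.7, seed=4)
        G = td.build_grm(geno)
        y2 = y.copy()
        y2.iloc[:30] = np.nan
        fit = td.fit_gblup(y2, G)
        assert np.isfinite(fit.gebv.iloc[:30]).all()
        # relatives' information makes the predictions informative
        r = np.corrcoef(fit.gebv.iloc[:30], y.iloc[:30])[0, 1]
        assert r > 0.2

    def test_requires_ten_phenotypes(self):
        G = _random_grm(20)
        y = pd.Series(np.nan, index=G.sample_ids)
        y.iloc[:5] = 1.0
        with pytest.raises(ValueError, match="10 non-missing"):
            td.fit_gblup(y, G)

    def test_non_psd_rejected(self):
        n = 10
        vals = -np.eye(n)
        G = td.GRM(sample_ids=[f"S{i}" for i in range(n)], values=vals)
        y = pd.Series(np.random.default_rng(0).normal(size=n), index=G.sample_ids)
        with pytest.raises(ValueError, match="positive semidefinite"):
            td.fit_gblup(y, G)

    def test_gibbs_agrees_with_reml(self):
        geno, y = _quick_sim(h2=0.5, seed=5, n=300, m=600)
        G = td.build_grm(geno)
        reml = td.fit_gblup(y, G, method="reml")
        gibbs = td.fit_gblup(y, G, method="gibbs", seed=8)
        r = np.corrcoef(reml.gebv, gibbs.gebv)[0, 1]
        assert r > 0.99

    def test_gibbs_deterministic_given_seed(self):
        geno, y = _quick_sim(h2=0.5, seed=6, n=120, m=300)
        G = td.build_grm(geno)
        a = td.fit_gblup(y, G, method="gibbs", n_iter=500, burn_in=100, seed=3)
        b = td.fit_gblup(y, G, method="gibbs", n_iter=500, burn_in=100, seed=3)
        assert np.array_equal(a.gebv.to_numpy(), b.gebv.to_numpy())


class TestPredictionBias:
    def test_identity_and_scaling(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=50)
        assert td.prediction_bias(g, g) == pytest.approx(1.0)
        assert td.prediction_bias(2 * g, g) == pytest.approx(2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            td.prediction_bias(np.arange(5.0), np.ones(5))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 paired"):
            td.prediction_bias(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestCrossValidate:
    def test_deterministic_given_seed(self):
        geno, y = _quick_sim(h2=0.5, seed=7, n=150, m=300)
        G = td.build_grm(geno)
        a = td.cross_validate(y, G, n_folds=4, n_repeats=2, seed=9)
        b = td.cross_validate(y, G, n_folds=4, n_repeats=2, seed=9)
        assert np.array_equal(a.correlations, b.correlations)
        assert np.array_equal(a.bias, b.bias)
        assert all(np.array_equal(x, z) for x, z in
                   zip(a.fold_assignments, b.fold_assignments))

    def test_too_few_phenotyped_rejected(self):
        G = _random_grm(20)
        y = pd.Series(np.nan, index=G.sample_ids)
        y.iloc[:5] = [1, 2, 3, 4, 5]
        with pytest.raises(ValueError, match="folds"):
            td.cross_validate(y, G, n_folds=8)

    def test_null_trait_correlation_near_zero(self):
        geno, y = _quick_sim(h2=0.0, seed=8, n=300, m=400)
        G = td.build_grm(geno)
        cv = td.cross_validate(y, G, n_folds=5, n_repeats=3, seed=1)
        assert abs(cv.mean_correlation) < 0.1

    def test_accuracy_increases_with_heritability(self):
        means = []
        for h2 in (0.1, 0.4, 0.7):
            rs = []
            for seed in (0, 1, 2):
                geno, y = _quick_sim(h2=h2, seed=20 + seed, n=250, m=600)
                G = td.build_grm(geno)
                cv = td.cross_validate(y, G, n_folds=5, n_repeats=2, seed=seed)
                rs.append(cv.mean_correlation)
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]

    def test_out_of_fold_phenotypes_are_masked(self, monkeypatch):
        """Audit: every refit receives NaN at exactly the held-out fold plus
        originally-missing entries."""
        geno, y = _quick_sim(h2=0.5, seed=9, n=120, m=200)
        y = y.copy()
        y.iloc[:10] = np.nan
        G = td.build_grm(geno)
        seen = []
        import tetradose.gblup as gblup_mod
        real_fit = gblup_mod.fit_gblup

        def spy(y_arg, *args, **kw):
            seen.append(np.flatnonzero(~np.isfinite(y_arg.to_numpy())))
            return real_fit(y_arg, *args, **kw)

        monkeypatch.setattr(gblup_mod, "fit_gblup", spy)
        cv = td.cross_validate(y, G, n_folds=4, n_repeats=1, seed=2)
        phen = np.flatnonzero(np.isfinite(y.to_numpy()))
        fold_of = cv.fold_assignments[0]
        assert len(seen) == 4
        for f, masked in enumerate(seen):
            expected = np.union1d(np.arange(10), phen[fold_of == f])
            assert np.array_equal(masked, expected)


class TestCompareCorrelations:
    def _cv(self, rs):
        rs = np.asarray(rs, dtype=float)
        return CVResult(correlations=rs, bias=np.ones_like(rs),
                        n_folds=8, n_repeats=len(rs), seed=0)

    def test_identical_results_give_p_one(self):
        cv = self._cv([0.3, 0.4, 0.5])
        res = td.compare_correlations(cv, cv)
        assert res.mean_difference == 0.0
        assert res.p == 1.0

    def test_constant_shift_reports_vanishing_p(self):
        # a constant z-shift leaves (near-)zero variance of differences;
        # the reported p collapses far below any usable threshold
        a = self._cv(np.linspace(0.2, 0.4, 10))
        b = self._cv(np.tanh(np.arctanh(a.correlations) + 0.01))
        res = td.compare_correlations(a, b)
        assert res.mean_difference == pytest.approx(0.01, abs=1e-10)
        assert res.t > 1e6 or np.isinf(res.t)
        assert res.p < 1e-100

    def test_exact_constant_shift_hits_guard(self):
        a = self._cv([0.3] * 10)
        b = self._cv([0.31] * 10)
        res = td.compare_correlations(a, b)
        assert np.isinf(res.t) and res.t > 0
        assert res.p == 0.0

    def test_unequal_repeats_rejected(self):
        with pytest.raises(ValueError, match="equal repeat"):
            td.compare_correlations(self._cv([0.1, 0.2]), self._cv([0.1]))

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            td.compare_correlations(self._cv([1.0, 0.5]), self._cv([0.4, 0.5]))

    def test_type_one_error_calibration(self):
        """Paired CVs from one generating process reject at ~alpha."""
        rng = np.random.default_rng(12)
        n_rep, alpha = 200, 0.05
        rejections = 0
        for _ in range(n_rep):
            base = rng.normal(0.5, 0.05, size=10)
            ra = np.tanh(np.arctanh(base) + rng.normal(0, 0.03, size=10))
            rb = np.tanh(np.arctanh(base) + rng.normal(0, 0.03, size=10))
            res = td.compare_correlations(self._cv(ra), self._cv(rb))
            rejections += res.p < alpha
        rate = rejections / n_rep
        ci = 1.96 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= ci + 0.01
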