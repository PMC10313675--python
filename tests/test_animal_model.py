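"""REML, Gibbs sampling, LRT, chain diagnostics and the bivariate model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

import gallop as g
from gallop.animal_model import _pcramer, lag1_autocorr, restricted_loglik
from gallop.simulate import simulate_correlated_bvs


# ---------------------------------------------------------------------------
# restricted likelihood: identity and optimum
# ---------------------------------------------------------------------------


def _tiny_dataset(seed=11):
    cfg = g.GeneratorConfig(
        n_founders=25, n_years=6, offspring_per_year=15, races_per_year=4,
        mean_records_per_horse=3.0, true_genetic_trend=0.0, seed=seed,
    )
    ped, bv, rec = g.simulate_dataset(cfg)
    A = g.relationship_matrix(ped)
    des = g.build_design(g.prepare_records(rec), g.ModelSpec.model_a(), ped)
    return ped, A, des


def _direct_loglik(des, A, sig, sig_e):
    """Dense-V restricted log-likelihood, built independently of the MME."""
    y, X = des.y, des.X
    V = sig_e * np.eye(len(y))
    Ad = A.toarray()
    ai = des.term_index["animal"]
    V += sig[0] * Ad[np.ix_(ai, ai)]
    pi = des.term_index["pe"]
    V += sig[1] * (pi[:, None] == pi[None, :])
    ti = des.term_index["trainer"]
    V += sig[2] * (ti[:, None] == ti[None, :])
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (ld_v + ld_x + y @ P @ y)


class TestRemlLikelihood:
    def test_mme_identity_matches_dense_V_formula(self):
        ped, A, des = _tiny_dataset()
        sig = np.array([0.03, 0.08, 0.02])
        ll = restricted_loglik(
            des, A, dict(V_A=sig[0], V_PE=sig[1], V_T=sig[2], V_R=0.18)
        )
        assert ll == pytest.approx(_direct_loglik(des, A, sig, 0.18), abs=1e-8)

    def test_em_fixed_point_is_the_likelihood_maximum(self):
        ped, A, des = _tiny_dataset()
        fit = g.fit_reml(des, A, opts=g.RemlOptions(compute_se=False))
        res = scipy.optimize.minimize(
            lambda th: -_direct_loglik(des, A, np.exp(th[:3]), np.exp(th[3])),
            np.log([0.05, 0.05, 0.05, 0.15]), method="Nelder-Mead",
            options=dict(maxiter=1200, xatol=1e-7, fatol=1e-9),
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-3)
        assert fit.loglik >= -res.fun - 1e-6   # EM at least as good as NM
        opt = np.exp(res.x)
        got = [fit.vc.V_A, fit.vc.V_PE, fit.vc.V_T, fit.vc.V_R]
        np.testing.assert_allclose(got, opt, rtol=2e-2, atol=1e-4)

    def test_gradient_vanishes_at_optimum(self):
        ped, A, des = _tiny_dataset(seed=17)
        fit = g.fit_reml(des, A, opts=g.RemlOptions(compute_se=False))
        theta = dict(V_A=fit.vc.V_A, V_PE=fit.vc.V_PE, V_T=fit.vc.V_T,
                     V_R=fit.vc.V_R)
        ll0 = restricted_loglik(des, A, theta)
        for name, val in theta.items():
            h = 1e-5 * max(val, 1e-4)
            up = dict(theta, **{name: val + h})
            dn = dict(theta, **{name: max(val - h, 1e-12)})
            grad = (restricted_loglik(des, A, up) - restricted_loglik(des, A, dn)) / (2 * h)
            assert abs(grad * val / (abs(ll0) + 1)) < 1e-3, name

    def test_scale_and_location_invariance(self):
        """h2 is invariant under y -> c*y + d; components scale by c^2."""
        ped, A, des = _tiny_dataset(seed=23)
        fit = g.fit_reml(des, A, opts=g.RemlOptions(compute_se=False))
        c, d = 3.0, -40.0
        des2 = dataclasses.replace(des, y=c * des.y + d)
        fit2 = g.fit_reml(des2, A, opts=g.RemlOptions(compute_se=False))
        # the transformed fit re-converges from scratch, so agreement is at
        # the optimiser's parameter accuracy, not machine precision
        assert fit2.vc.h2 == pytest.approx(fit.vc.h2, rel=1e-2, abs=1e-3)
        assert fit2.vc.V_A == pytest.approx(c**2 * fit.vc.V_A, rel=1e-2, abs=1e-4)
        assert fit2.vc.V_R == pytest.approx(c**2 * fit.vc.V_R, rel=1e-2)


class TestRemlNull:
    def test_zero_additive_variance_recovered(self):
        """With V_A = 0 in the generator (its share moved to the permanent
        environment), fitted h2 is consistent with zero in >= 95% of
        replicates: below 0.02, or within two of its own standard errors
        when the desk-scale sampling error exceeds that bound."""
        hits = 0
        n_rep = 20
        for i in range(n_rep):
            cfg = g.GeneratorConfig(
                n_founders=50, n_years=10, offspring_per_year=45,
                races_per_year=10, mean_records_per_horse=4.0,
                V_A=0.0, V_PE=0.112, true_genetic_trend=0.0, seed=4000 + 7 * i,
            )
            ped, bv, rec = g.simulate_dataset(cfg)
            A = g.relationship_matrix(ped)
            des = g.build_design(g.prepare_records(rec), g.ModelSpec.model_a(), ped)
            fit = g.fit_reml(des, A)
            bound = max(0.02, 2 * fit.vc.se.get("h2", 0.0))
            hits += fit.vc.h2 <= bound
        assert hits >= 0.95 * n_rep


# ---------------------------------------------------------------------------
# variance-component invariants on a real fit
# ---------------------------------------------------------------------------


class TestVarianceComponents:
    def test_partition_and_ordering(self, small_reml):
        vc = small_reml.vc
        assert vc.V_A >= 0 and vc.V_PE >= 0 and vc.V_T >= 0 and vc.V_R > 0
        assert vc.V_P == pytest.approx(vc.V_A + vc.V_PE + vc.V_T + vc.V_R,
                                       abs=1e-10)
        assert 0 <= vc.h2 <= vc.repeatability <= 1

    def test_pbv_covers_every_pedigree_individual(self, small_sim, small_reml):
        assert set(small_reml.pbv.index) == set(small_sim["ped"].ids)
        assert np.isfinite(small_reml.loglik) and small_reml.converged


# ---------------------------------------------------------------------------
# likelihood-ratio test (boundary mixture)
# ---------------------------------------------------------------------------


class TestLrt:
    def test_mixture_reference_values(self, small_reml, small_reml_reduced):
        stat, p = g.lrt_va(small_reml, small_reml_reduced)
        assert stat >= 0
        # the 50:50 chi2(0)/chi2(1) mixture critical values
        assert 0.5 * scipy.stats.chi2.sf(2.706, 1) == pytest.approx(0.05, abs=1e-3)

    def test_boundary_and_tail(self, small_reml, small_reml_reduced):
        fake_full = dataclasses.replace(small_reml, loglik=small_reml_reduced.loglik)
        stat, p = g.lrt_va(fake_full, small_reml_reduced)
        assert stat == 0.0 and p == 1.0
        big = dataclasses.replace(
            small_reml, loglik=small_reml_reduced.loglik + 1990.8 / 2
        )
        stat, p = g.lrt_va(big, small_reml_reduced)
        assert stat == pytest.approx(1990.8) and p < 0.001

    def test_mismatched_designs_rejected(self, small_reml):
        other = dataclasses.replace(small_reml, n_records=small_reml.n_records + 1)
        with pytest.raises(g.ModelError):
            g.lrt_va(small_reml, other)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


class TestGibbs:
    def test_chain_bookkeeping(self):
        assert g.ChainSpec(2_000_000, 800_000, 1200).n_retained == 1000
        assert g.ChainSpec(11, 1, 3).n_retained == 3
        with pytest.raises(g.ModelError):
            g.ChainSpec(100, 100, 1)

    def test_retained_draw_count_and_positivity(self, small_gibbs):
        assert small_gibbs.n_retained == (6000 - 1000) // 5
        assert (small_gibbs.vc_draws > 0).all().all()

    def test_reproducible_given_seed(self, small_sim):
        kw = dict(chain=g.ChainSpec(300, 100, 2), seed=7)
        s1 = g.fit_gibbs(small_sim["design"], small_sim["A"], **kw)
        s2 = g.fit_gibbs(small_sim["design"], small_sim["A"], **kw)
        pd.testing.assert_frame_equal(s1.vc_draws, s2.vc_draws)
        np.testing.assert_array_equal(s1.bv_draws, s2.bv_draws)

    def test_posterior_agrees_with_reml(self, small_reml, small_gibbs):
        post = small_gibbs.vc_draws.mean()
        sd = small_gibbs.vc_draws.std()
        for name in ("V_A", "V_PE", "V_T", "V_R"):
            reml_val = getattr(small_reml.vc, name)
            assert abs(post[name] - reml_val) < 2 * sd[name], name

    def test_blup_correlates_with_posterior_mean_bv(self, small_sim, small_reml,
                                                    small_gibbs):
        post_bv = pd.Series(small_gibbs.bv_draws.mean(axis=0),
                            index=small_gibbs.ids)
        pheno = sorted(small_sim["phenotyped"])
        r = np.corrcoef(small_reml.pbv[pheno], post_bv[pheno])[0, 1]
        assert r > 0.98


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


class TestDiagnostics:
    def test_pcramer_matches_reference_cdf(self):
        # reference values from an established implementation of the
        # asymptotic Cramer-von Mises CDF
        for q, ref in [
            (0.05, 0.1237190690), (0.1, 0.4151265616), (0.2, 0.7325295695),
            (0.3, 0.8648287312), (0.4614, 0.9500114624), (0.7435, 0.9900022577),
            (1.1679, 0.9990002224), (2.0, 0.9999872178),
        ]:
            assert _pcramer(q) == pytest.approx(ref, abs=2e-6)

    def test_iid_chain_calibration(self):
        """i.i.d. Gaussian pseudo-chains: stationarity passes and lag-1
        autocorrelation is below 0.1 in >= 90% of 50 replicates."""
        rng = np.random.default_rng(0)
        ok = 0
        for _ in range(50):
            x = rng.standard_normal(600)
            _, _, passed = g.heidelberger_welch(x)
            ok += passed and abs(lag1_autocorr(x)) < 0.1
        assert ok >= 45

    def test_linear_trend_fails_stationarity(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(800)
        x = x + np.linspace(0, 3 * x.std(), len(x))
        _, _, passed = g.heidelberger_welch(x)
        assert not passed

    def test_constant_chain_degenerate(self):
        p, frac, passed = g.heidelberger_welch(np.full(200, 2.5))
        assert passed and p == 1.0
        assert np.isnan(lag1_autocorr(np.full(200, 2.5)))

    def test_report_on_real_chain(self, small_gibbs):
        rep = g.diagnostics(small_gibbs)
        assert set(rep) == {"V_A", "V_PE", "V_T", "V_R"}
        for comp in rep.values():
            assert 0 <= comp.stationarity_p <= 1

    def test_too_few_draws_rejected(self, small_gibbs):
        short = dataclasses.replace(
            small_gibbs, vc_draws=small_gibbs.vc_draws.iloc[:10],
            bv_draws=small_gibbs.bv_draws[:10],
        )
        with pytest.raises(g.ModelError, match="50"):
            g.diagnostics(short)


# ---------------------------------------------------------------------------
# bivariate genetic correlation
# ---------------------------------------------------------------------------


def _bivariate_fit(rg, seed, chain=(6000, 1500, 2)):
    """Correlated-trait data without PE/trainer variance; the fit matches
    (additive + residual only), keeping the slow-mixing r_G chain cheap
    enough for a 20-replicate coverage experiment.  A founder-rich pedigree
    pins the realised genetic correlation near the generating parameter."""
    cfg = g.GeneratorConfig(
        n_founders=150, n_years=6, offspring_per_year=35, races_per_year=8,
        true_genetic_trend=0.0, mean_records_per_horse=6.0,
        V_PE=0.0, V_T=0.0, seed=seed,
    )
    ped, _ = g.simulate_pedigree(cfg)
    bv1, bv2 = simulate_correlated_bvs(ped, cfg.V_A, cfg.V_A, rg, seed=seed + 1)
    cfg2 = dataclasses.replace(cfg, category="middle")
    rec1 = g.simulate_records(ped, bv1, cfg, seed=seed + 2)
    rec2 = g.simulate_records(ped, bv2, cfg2, seed=seed + 3)
    A = g.relationship_matrix(ped)
    d1 = g.build_design(g.prepare_records(rec1), g.ModelSpec.model_a(), ped)
    d2 = g.build_design(g.prepare_records(rec2), g.ModelSpec.model_a(), ped)
    return g.fit_bivariate_gibbs((d1, d2), A, chain=g.ChainSpec(*chain),
                                 seed=seed + 4, random_terms=())


class TestBivariate:
    def test_self_correlation_identified_as_one(self, small_sim):
        """Both traits given identical copies of the same records: the
        genetic-correlation interval must contain 1 and exclude 0."""
        des = small_sim["design"]
        res = g.fit_bivariate_gibbs(
            (des, des), small_sim["A"], chain=g.ChainSpec(3000, 1000, 2), seed=2,
        )
        lo, hi = res.interval
        # the posterior concentrates just inside the r_G = 1 boundary (each
        # trait keeps its own residual/PE draws), so "contains 1" holds to
        # the width of that concentration
        assert hi > 0.99 and res.r_G > 0.99
        assert lo > 0.0
        assert -1 <= res.r_G <= 1

    def test_unlinked_traits_unidentifiable(self):
        ped = g.Pedigree.from_records(
            ["A", "B"], [None, None], [None, None], [2000, 2000], ["M", "M"]
        )
        rec = pd.DataFrame([
            dict(horse="A", race_id="R1", finish_time=80.0, distance=1320.0,
                 speed=16.5, going=5.0, n_runners=5, timing="automatic",
                 racecourse="RC0", year=2003, age=3, sex="M", trainer="T0"),
            dict(horse="A", race_id="R2", finish_time=81.0, distance=1320.0,
                 speed=16.3, going=5.0, n_runners=5, timing="automatic",
                 racecourse="RC0", year=2003, age=3, sex="M", trainer="T0"),
        ])
        rec2 = rec.copy()
        rec2["horse"] = "B"
        d1 = g.build_design(g.prepare_records(rec), g.ModelSpec(name="0", factors=()), ped)
        d2 = g.build_design(g.prepare_records(rec2), g.ModelSpec(name="0", factors=()), ped)
        with pytest.raises(g.ModelError, match="unidentifiable"):
            g.fit_bivariate_gibbs((d1, d2), chain=g.ChainSpec(200, 100, 1), seed=0)

    @pytest.mark.parametrize("rg", [0.8, 0.0])
    def test_credible_interval_coverage(self, rg):
        """95% credible intervals cover the generating genetic correlation
        in at least 18 of 20 replicates."""
        covered = 0
        for i in range(20):
            res = _bivariate_fit(rg, 2000 + 17 * i)
            lo, hi = res.interval
            covered += lo <= rg <= hi
        assert covered >= 18
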