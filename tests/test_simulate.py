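"""The synthetic-data generator: determinism, structure and ground truth."""

import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest

import gallop as g
from gallop.drift import drift_slopes
from gallop.simulate import SimulationError


class TestConfig:
    def test_derived_ratios_match_study_conditions(self):
        cfg = g.GeneratorConfig()
        assert cfg.h2 == pytest.approx(0.124, abs=1e-3)
        assert cfg.repeatability == pytest.approx(0.35, abs=1e-3)
        assert cfg.V_P == pytest.approx(0.32, abs=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(SimulationError):
            g.GeneratorConfig(V_A=-0.1)
        with pytest.raises(SimulationError):
            g.GeneratorConfig(sire_pool_fraction=0.0)
        with pytest.raises(SimulationError):
            g.GeneratorConfig(mean_records_per_horse=0.5)

    def test_round_trips_through_dict(self):
        cfg = g.GeneratorConfig(n_founders=33, seed=5)
        again = g.GeneratorConfig.from_dict(cfg.to_dict())
        assert again == cfg


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = g.GeneratorConfig(n_founders=40, n_years=6, offspring_per_year=25,
                                races_per_year=6, seed=77)
        p1, b1, r1 = g.simulate_dataset(cfg)
        p2, b2, r2 = g.simulate_dataset(cfg)
        np.testing.assert_array_equal(p1.ids, p2.ids)
        np.testing.assert_array_equal(p1.sire, p2.sire)
        pd.testing.assert_series_equal(b1, b2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_different_seed_differs(self):
        cfg = g.GeneratorConfig(n_founders=40, n_years=6, offspring_per_year=25,
                                races_per_year=6, seed=77)
        _, b1, _ = g.simulate_dataset(cfg)
        _, b2, _ = g.simulate_dataset(cfg, seed=78)
        assert not np.allclose(b1, b2)


class TestStructure:
    def test_output_passes_readers_without_warnings(self, tmp_path, caplog):
        cfg = g.GeneratorConfig(n_founders=40, n_years=8, offspring_per_year=30,
                                races_per_year=8, seed=13)
        ped, bv, rec = g.simulate_dataset(cfg)
        g.write_pedigree(ped, tmp_path / "ped.csv")
        rec.to_csv(tmp_path / "rec.csv", index=False)
        with caplog.at_level(logging.WARNING):
            ped2 = g.read_pedigree(tmp_path / "ped.csv")
            rec2 = g.read_records(tmp_path / "rec.csv")
            g.prepare_records(rec2, category=cfg.category)
        assert not caplog.records
        assert ped2.n == ped.n and len(rec2) == len(rec)

    def test_small_sire_pool_creates_large_paternal_halfsibships(self):
        cfg = g.GeneratorConfig(n_founders=60, n_years=8, offspring_per_year=60,
                                sire_pool_fraction=0.05, seed=21)
        ped, _ = g.simulate_pedigree(cfg)
        s = g.summarize_pedigree(ped)
        assert s.max_paternal_halfsib > 3 * s.max_maternal_halfsib

    def test_records_carry_all_model_covariates(self, small_sim):
        rec = small_sim["records"]
        from gallop.records import REQUIRED_COLUMNS

        assert set(REQUIRED_COLUMNS + ["speed", "finish_time"]) <= set(rec.columns)
        assert (rec["n_runners"] >= 1).all()
        # finishing time is consistent with speed and distance
        np.testing.assert_allclose(rec["speed"] * rec["finish_time"],
                                   rec["distance"], rtol=1e-9)


class TestGroundTruth:
    def test_noiseless_records_reproduce_breeding_values(self):
        cfg = g.GeneratorConfig(
            n_founders=30, n_years=6, offspring_per_year=20, races_per_year=5,
            V_PE=0.0, V_T=0.0, V_R=0.0, race_effect_sd=0.0,
            going_coef=0.0, distance_coef=0.0, sex_effect=0.0,
            age_effects={a: 0.0 for a in range(2, 13)},
            true_genetic_trend=0.0, seed=3,
        )
        ped, bv, rec = g.simulate_dataset(cfg)
        expected = cfg.mean_speed + bv[rec["horse"]].to_numpy()
        np.testing.assert_allclose(rec["speed"], expected, atol=1e-12)

    def test_variance_decomposition_moments(self):
        """Method-of-moments on known groupings at large n: residual,
        horse-level and total variance within 5% of the configuration."""
        cfg = g.GeneratorConfig(
            n_founders=400, n_years=4, offspring_per_year=900,
            races_per_year=120, mean_records_per_horse=6.0,
            true_genetic_trend=0.0, race_effect_sd=0.0, going_coef=0.0,
            distance_coef=0.0, sex_effect=0.0,
            age_effects={a: 0.0 for a in range(2, 13)},
            sire_pool_fraction=1.0, n_trainers=60, seed=123,
        )
        ped, bv, rec = g.simulate_dataset(cfg)
        gb = rec.groupby("horse")["speed"]
        wv = gb.apply(lambda x: x.var(ddof=1) if len(x) > 1 else np.nan).dropna()
        vr_hat = wv.mean()
        assert vr_hat == pytest.approx(cfg.V_R, rel=0.05)
        hm, n_i = gb.mean(), gb.count()
        vh_hat = hm.var(ddof=1) - vr_hat * np.mean(1.0 / n_i)
        assert vh_hat == pytest.approx(cfg.V_A + cfg.V_PE + cfg.V_T, rel=0.05)
        assert rec["speed"].var(ddof=1) == pytest.approx(cfg.V_P, rel=0.05)
        # paternal half-sib resemblance identifies V_A/4 (wide band: the
        # family-level moment is far noisier than the record-level ones)
        pos = ped.positions(hm.index)
        d2 = pd.DataFrame({"hm": hm.to_numpy(), "sire": ped.sire[pos]})
        d2 = d2[d2["sire"] >= 0]
        grp = d2.groupby("sire")["hm"]
        big = grp.count()[grp.count() >= 10].index
        sub = d2[d2["sire"].isin(big)]
        gm = sub.groupby("sire")["hm"]
        nbar = gm.count().mean()
        msb = (gm.count() * (gm.mean() - sub["hm"].mean()) ** 2).sum() / (len(big) - 1)
        msw = gm.apply(lambda x: ((x - x.mean()) ** 2).sum()).sum() / (len(sub) - len(big))
        va4 = (msb - msw) / nbar
        assert va4 == pytest.approx(cfg.V_A / 4, rel=0.5)

    def test_selection_direction(self):
        """Truncation selection of sires produces a positive realised trend
        in true breeding values in >= 18 of 20 replicates."""
        hits = 0
        for i in range(20):
            cfg = g.GeneratorConfig(
                n_founders=50, n_years=10, offspring_per_year=40,
                sire_pool_fraction=0.08, seed=7000 + 3 * i,
            )
            ped, bv = g.simulate_pedigree(cfg)
            slope = g.true_trend(ped, bv, cfg.first_year,
                                 cfg.first_year + cfg.n_years - 1)
            hits += slope > 0
        assert hits >= 18

    def test_phenotypic_truncation_mode(self):
        """Selecting sires on a noisy phenotype proxy still yields a
        positive — but weaker — realised genetic trend."""
        slopes = {}
        for crit in ("breeding_value", "phenotype"):
            vals = []
            for i in range(10):
                cfg = g.GeneratorConfig(
                    n_founders=50, n_years=10, offspring_per_year=40,
                    sire_pool_fraction=0.08, selection_criterion=crit,
                    seed=7100 + 3 * i,
                )
                ped, bv = g.simulate_pedigree(cfg)
                vals.append(g.true_trend(ped, bv, cfg.first_year,
                                         cfg.first_year + cfg.n_years - 1))
            slopes[crit] = np.mean(vals)
        assert slopes["phenotype"] > 0
        assert slopes["phenotype"] < slopes["breeding_value"]
        with pytest.raises(SimulationError):
            g.GeneratorConfig(selection_criterion="horoscope")

    def test_no_selection_trend_within_drift_bounds(self):
        """Without selection the realised true-BV trend is a drift draw:
        it must sit inside the generator's own gene-drop null distribution."""
        cfg = g.GeneratorConfig(n_founders=60, n_years=12, offspring_per_year=50,
                                true_genetic_trend=0.0, seed=321)
        ped, bv = g.simulate_pedigree(cfg)
        y2 = cfg.first_year + cfg.n_years - 1
        slope = g.true_trend(ped, bv, cfg.first_year, y2)
        null = drift_slopes(ped, np.full(2000, cfg.V_A), cfg.first_year, y2,
                            seed=322)
        lo, hi = np.quantile(null, [0.0005, 0.9995])
        assert lo < slope < hi

    def test_correlated_traits_preserve_rg(self):
        from gallop.simulate import simulate_correlated_bvs

        cfg = g.GeneratorConfig(n_founders=300, n_years=6, offspring_per_year=250,
                                true_genetic_trend=0.0, seed=31)
        ped, _ = g.simulate_pedigree(cfg)
        for rg in (0.8, 0.0, -0.5):
            b1, b2 = simulate_correlated_bvs(ped, 1.0, 1.0, rg, seed=32)
            assert np.corrcoef(b1, b2)[0, 1] == pytest.approx(rg, abs=0.08)

    def test_infeasible_config_errors(self):
        cfg = g.GeneratorConfig(n_founders=2, n_years=5, offspring_per_year=5,
                                seed=1)
        with pytest.raises(SimulationError):
            g.simulate_pedigree(cfg)
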