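"""Shared fixtures: small simulated datasets and fitted models.

Expensive fits are session-scoped so several tests can interrogate the same
converged model; every fixture is fully seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import gallop as g


def make_random_pedigree(seed: int, n: int, p_unknown: float = 0.25):
    """Structurally random valid pedigree (independent of the package's
    generator): parents drawn from strictly earlier individuals."""
    rng = np.random.default_rng(seed)
    ids = [f"I{k:04d}" for k in range(n)]
    sires, dams, years, sexes = [], [], [], []
    sex = rng.random(n) < 0.5
    for k in range(n):
        sexes.append("M" if sex[k] else "F")
        years.append(1980 + k // max(1, n // 30))
        males = [j for j in range(k) if sex[j]]
        females = [j for j in range(k) if not sex[j]]
        s = d = None
        if males and rng.random() > p_unknown:
            s = ids[int(rng.choice(males))]
        if females and rng.random() > p_unknown:
            d = ids[int(rng.choice(females))]
        sires.append(s)
        dams.append(d)
    return g.Pedigree.from_records(ids, sires, dams, years, sexes)


def kinship_oracle(ped: g.Pedigree):
    """Brute-force recursive coefficient of kinship, written independently
    of the package's tabular relationship-matrix code."""
    from functools import lru_cache

    sire, dam = ped.sire, ped.dam

    @lru_cache(maxsize=None)
    def f(a, b):
        if a < 0 or b < 0:
            return 0.0
        if a > b:
            a, b = b, a
        if a == b:
            return 0.5 * (1.0 + f(sire[a], dam[a]))
        return 0.5 * (f(a, sire[b]) + f(a, dam[b]))

    n = ped.n
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            K[i, j] = K[j, i] = f(j, i)
    return K


@pytest.fixture(scope="session")
def small_sim():
    """A compact dataset under the default (sprint-like) study conditions."""
    cfg = g.GeneratorConfig(
        n_founders=60, n_years=10, offspring_per_year=40, races_per_year=12,
        seed=3,
    )
    ped, true_bv, rec = g.simulate_dataset(cfg)
    A = g.relationship_matrix(ped)
    design = g.build_design(g.prepare_records(rec), g.ModelSpec.model_a(), ped)
    return dict(cfg=cfg, ped=ped, true_bv=true_bv, records=rec, A=A,
                design=design, phenotyped=set(rec["horse"].unique()))


@pytest.fixture(scope="session")
def small_reml(small_sim):
    return g.fit_reml(small_sim["design"], small_sim["A"])


@pytest.fixture(scope="session")
def small_reml_reduced(small_sim):
    """Same data and fixed effects, additive genetic term omitted."""
    return g.fit_reml(
        small_sim["design"], small_sim["A"], random_terms=("pe", "trainer"),
        opts=g.RemlOptions(compute_se=False),
    )


@pytest.fixture(scope="session")
def small_gibbs(small_sim):
    return g.fit_gibbs(
        small_sim["design"], small_sim["A"],
        chain=g.ChainSpec(6000, 1000, 5), seed=11,
    )


@pytest.fixture(scope="session")
def recovery():
    """Sprint-like parameter-recovery experiment (h2 = 0.124 truth):
    ~770 phenotyped horses with ~5.7 records each, REML and Gibbs fits."""
    cfg = g.GeneratorConfig(
        n_founders=100, n_years=14, offspring_per_year=55, races_per_year=25,
        seed=42,
    )
    ped, true_bv, rec = g.simulate_dataset(cfg)
    A = g.relationship_matrix(ped)
    design = g.build_design(g.prepare_records(rec), g.ModelSpec.model_a(), ped)
    fit = g.fit_reml(design, A)
    samples = g.fit_gibbs(design, A, chain=g.ChainSpec(8000, 2000, 6), seed=1)
    return dict(cfg=cfg, ped=ped, true_bv=true_bv, records=rec, A=A,
                design=design, fit=fit, samples=samples,
                phenotyped=set(rec["horse"].unique()))


@pytest.fixture(scope="session")
def halfsib():
    """Balanced paternal half-sib design: 100 sires x 20 offspring, one
    record each, no permanent-environment or trainer variance."""
    rng = np.random.default_rng(77)
    h2, vp = 0.25, 1.0
    va = h2 * vp
    ns, no = 100, 20
    ids = [f"S{s}" for s in range(ns)]
    sires: list = [None] * ns
    for s in range(ns):
        for o in range(no):
            ids.append(f"O{s}_{o}")
            sires.append(f"S{s}")
    ped = g.Pedigree.from_records(
        ids, sires, [None] * len(ids),
        [1990] * ns + [2000] * (ns * no), ["M"] * ns + ["F"] * (ns * no),
    )
    sire_bv = rng.normal(0, np.sqrt(va), ns)
    rows = []
    for s in range(ns):
        for o in range(no):
            bv = 0.5 * sire_bv[s] + rng.normal(0, np.sqrt(0.75 * va))
            sp = 18.0 + bv + rng.normal(0, np.sqrt(vp - va))
            rows.append(dict(
                horse=f"O{s}_{o}", race_id=f"R{s}_{o}", finish_time=1320 / sp,
                distance=1320.0, speed=sp, going=5.0, n_runners=10,
                timing="automatic", racecourse="RC0", year=2003, age=3,
                sex="F", trainer="T0",
            ))
    rec = pd.DataFrame(rows)
    return dict(ped=ped, records=rec, n_sires=ns, n_off=no, h2=h2)
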