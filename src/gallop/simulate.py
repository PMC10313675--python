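"""Synthetic racehorse pedigrees and race records with known ground truth.

The generator emulates the statistical structure the animal model assumes:
a multi-generation overlapping pedigree in which a small pool of heavily
used sires creates large paternal half-sibships, repeated records per horse
across races and ages, race-level covariates (distance, going, field size,
racecourse, timing method) and a variance structure of additive genetic,
permanent environment, trainer and residual components.  True breeding
values follow the same Mendelian-sampling transmission rule as the
gene-dropping module, so every downstream stage can be checked against
known truth.

Default variances give the sprint-race study conditions: V_P = 0.32 with
h^2 = 0.124, repeatability 0.35 and a trainer share of 10%, around a mean
speed of 18 yards/s.  Selection, when active, is truncation on true
breeding value of the sire pool, which links the realised trend directly to
the selection-intensity arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .records import DEFAULT_CATEGORIES, DistanceCategory

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


#: probability of racing at each age 2, 3, ..., 12 (tail exercises "11+")
AGE_AT_RACE_PROBS = {
    2: 0.28, 3: 0.26, 4: 0.18, 5: 0.10, 6: 0.06, 7: 0.04,
    8: 0.03, 9: 0.02, 10: 0.01, 11: 0.01, 12: 0.01,
}


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of the synthetic population."""

    # pedigree structure
    n_founders: int = 120
    n_years: int = 18
    offspring_per_year: int = 60
    sire_pool_fraction: float = 0.10
    parental_age_mean: float = 9.5
    parental_age_sd: float = 3.5
    first_year: int = 1995

    # variance structure (yards^2 s^-2): V_P = 0.32, h2 = 0.124, R = 0.35
    V_A: float = 0.03968
    V_PE: float = 0.07232
    V_T: float = 0.032
    V_R: float = 0.176

    # selection: truncation of the sire pool when > 0, on true breeding
    # value ("breeding_value") or on a one-record phenotype proxy
    # ("phenotype": BV plus environmental noise of variance V_P - V_A)
    true_genetic_trend: float = 0.009
    selection_criterion: str = "breeding_value"

    # race structure
    mean_speed: float = 18.0
    races_per_year: int = 30
    mean_records_per_horse: float = 5.96
    category: str = "sprint"
    going_range: tuple = (2.0, 10.0)
    n_racecourses: int = 8
    timing_auto_prob: float = 0.9
    n_trainers: int = 25
    trainer_bv_confounding: float = 0.0
    race_effect_sd: float = 0.10

    # fixed-effect coefficients
    age_effects: dict = field(default_factory=lambda: {
        2: -0.30, 3: 0.00, 4: 0.05, 5: 0.05, 6: 0.00, 7: -0.05,
        8: -0.10, 9: -0.15, 10: -0.20, 11: -0.25, 12: -0.30,
    })
    sex_effect: float = 0.05           # males relative to females
    going_coef: float = -0.08          # per going unit from mid-range
    distance_coef: float = -0.0008     # per yard from window midpoint

    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("V_A", "V_PE", "V_T", "V_R"):
            if getattr(self, nm) < 0:
                raise SimulationError(f"{nm} must be non-negative")
        if not (0 < self.sire_pool_fraction <= 1):
            raise SimulationError("sire_pool_fraction must lie in (0, 1]")
        for nm in ("n_founders", "n_years", "offspring_per_year",
                   "races_per_year", "n_racecourses", "n_trainers"):
            if getattr(self, nm) < 1:
                raise SimulationError(f"{nm} must be >= 1")
        if self.mean_records_per_horse < 1:
            raise SimulationError("mean_records_per_horse must be >= 1")
        if self.selection_criterion not in ("breeding_value", "phenotype"):
            raise SimulationError(
                "selection_criterion must be 'breeding_value' or 'phenotype'"
            )

    @property
    def V_P(self) -> float:
        return self.V_A + self.V_PE + self.V_T + self.V_R

    @property
    def h2(self) -> float:
        return self.V_A / self.V_P

    @property
    def repeatability(self) -> float:
        return (self.V_A + self.V_PE) / self.V_P

    def distance_window(self) -> DistanceCategory:
        for c in DEFAULT_CATEGORIES:
            if c.name == self.category:
                return c
        raise SimulationError(f"unknown distance category {self.category!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "age_effects" in d:
            d["age_effects"] = {int(k): float(v) for k, v in d["age_effects"].items()}
        if "going_range" in d:
            d["going_range"] = tuple(d["going_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------


def _kinship_arrays(sire, dam, memo, i, j) -> float:
    """Recursive kinship on raw parent-index arrays (parents precede children)."""
    if i < 0 or j < 0:
        return 0.0
    if i > j:
        i, j = j, i
    key = (i, j)
    if key in memo:
        return memo[key]
    if i == j:
        val = 0.5 * (1.0 + _kinship_arrays(sire, dam, memo, sire[i], dam[i]))
    else:
        val = 0.5 * (
            _kinship_arrays(sire, dam, memo, i, sire[j])
            + _kinship_arrays(sire, dam, memo, i, dam[j])
        )
    memo[key] = val
    return val


def simulate_pedigree(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[Pedigree, pd.Series]:
    """Overlapping-generation pedigree with true breeding values.

    Each year's offspring draw sires from the population of eligible males —
    restricted to the top ``sire_pool_fraction`` by true breeding value when
    selection is active (``true_genetic_trend > 0``), uniformly weighted by
    a parental-age kernel otherwise — and dams from eligible females (one
    foal per dam per year).  True breeding values follow the gene-drop rule:
    founders ~ N(0, V_A), offspring = parental mean + Mendelian deviation
    with variance 0.5 * V_A * (1 - mean parental inbreeding).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_total = cfg.n_founders + cfg.n_years * cfg.offspring_per_year

    ids: list[str] = []
    sire = np.full(n_total, -1, dtype=np.int64)
    dam = np.full(n_total, -1, dtype=np.int64)
    birth = np.zeros(n_total)
    sex = np.empty(n_total, dtype=object)
    bv = np.zeros(n_total)
    memo: dict = {}

    y0 = cfg.first_year
    for k in range(cfg.n_founders):
        ids.append(f"F{k:05d}")
        birth[k] = y0 - rng.integers(3, 21)      # founders born 3-20 yrs before
        sex[k] = "M" if rng.random() < 0.5 else "F"
        bv[k] = rng.normal(0.0, np.sqrt(cfg.V_A))

    select = cfg.true_genetic_trend > 0
    nxt = cfg.n_founders
    for year in range(y0, y0 + cfg.n_years):
        ages = year - birth[:nxt]
        males = np.flatnonzero((sex[:nxt] == "M") & (ages >= 3) & (ages <= 18))
        females = np.flatnonzero((sex[:nxt] == "F") & (ages >= 3) & (ages <= 16))
        if len(males) == 0 or len(females) == 0:
            raise SimulationError(f"no eligible parents in year {year}")

        if select:
            n_pool = max(1, int(np.ceil(cfg.sire_pool_fraction * len(males))))
            crit = bv[males]
            if cfg.selection_criterion == "phenotype":
                env_var = max(cfg.V_P - cfg.V_A, 0.0)
                crit = crit + rng.normal(0.0, np.sqrt(env_var), len(males))
            pool = males[np.argsort(crit)[::-1][:n_pool]]
        else:
            pool = males

        def age_weights(cand):
            w = np.exp(
                -0.5 * ((year - birth[cand] - cfg.parental_age_mean)
                        / cfg.parental_age_sd) ** 2
            )
            s = w.sum()
            return w / s if s > 0 else np.full(len(cand), 1.0 / len(cand))

        sires_year = rng.choice(pool, size=cfg.offspring_per_year,
                                p=age_weights(pool))
        n_dams = min(cfg.offspring_per_year, len(females))
        dams_pick = rng.choice(females, size=n_dams, replace=False,
                               p=age_weights(females))
        dams_year = dams_pick[
            rng.integers(0, n_dams, size=cfg.offspring_per_year)
        ] if n_dams < cfg.offspring_per_year else dams_pick

        for j in range(cfg.offspring_per_year):
            s, d = int(sires_year[j]), int(dams_year[j])
            Fs = 2.0 * _kinship_arrays(sire, dam, memo, s, s) - 1.0
            Fd = 2.0 * _kinship_arrays(sire, dam, memo, d, d) - 1.0
            mend_var = 0.5 * cfg.V_A * (1.0 - 0.5 * (Fs + Fd))
            ids.append(f"H{nxt:05d}")
            sire[nxt], dam[nxt] = s, d
            birth[nxt] = year
            sex[nxt] = "M" if rng.random() < 0.5 else "F"
            bv[nxt] = 0.5 * (bv[s] + bv[d]) + rng.normal(0.0, np.sqrt(mend_var))
            nxt += 1

    ped = Pedigree.from_records(
        ids,
        [ids[s] if s >= 0 else None for s in sire],
        [ids[d] if d >= 0 else None for d in dam],
        birth.astype(int).tolist(),
        sex.tolist(),
    )
    true_bv = pd.Series(bv, index=np.array(ids, dtype=object), name="true_bv")
    return ped, true_bv.reindex(ped.ids)


# ---------------------------------------------------------------------------
# record simulation
# ---------------------------------------------------------------------------


def simulate_records(
    ped: Pedigree,
    true_bv: pd.Series,
    cfg: GeneratorConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Race records: speed = mu + fixed effects + BV + PE + trainer + residual.

    Horses born during the simulated years race at ages 2-12 (mirroring the
    collapsed 11+ factor); every record carries the full covariate set of
    both model structures, and finishing time is back-computed from speed
    and distance.
    """
    rng = np.random.default_rng((cfg.seed + 1) if seed is None else seed)
    bv = true_bv.reindex(ped.ids).to_numpy()
    if np.isnan(bv).any():
        raise SimulationError("true breeding values do not cover the pedigree")

    y0 = cfg.first_year
    racing = np.flatnonzero(ped.birth_year >= y0)      # founders are links only
    if len(racing) == 0:
        raise SimulationError("no horses born during the simulated years")

    window = cfg.distance_window()
    ages = np.array(sorted(AGE_AT_RACE_PROBS))
    age_p = np.array([AGE_AT_RACE_PROBS[a] for a in ages])
    age_p = age_p / age_p.sum()
    last_year = int(np.nanmax(ped.birth_year)) + 4

    pe = rng.normal(0.0, np.sqrt(cfg.V_PE), size=ped.n)
    trainer_eff = rng.normal(0.0, np.sqrt(cfg.V_T), size=cfg.n_trainers)

    # trainer assignment, optionally confounded with sire breeding value
    sire_bv = np.where(ped.sire >= 0, bv[np.maximum(ped.sire, 0)], bv)
    trainer_of = rng.integers(0, cfg.n_trainers, size=ped.n)
    if cfg.trainer_bv_confounding > 0:
        rank = np.argsort(np.argsort(sire_bv[racing]))
        sorted_trainers = np.argsort(trainer_eff)      # better trainers last
        chunk = (rank * cfg.n_trainers) // len(racing)
        confound = rng.random(len(racing)) < cfg.trainer_bv_confounding
        trainer_of[racing[confound]] = sorted_trainers[chunk[confound]]

    rows_horse, rows_age, rows_year = [], [], []
    for k in racing:
        n_rec = 1 + rng.poisson(max(0.0, cfg.mean_records_per_horse - 1.0))
        rec_ages = rng.choice(ages, size=n_rec, p=age_p)
        for a in rec_ages:
            yr = int(ped.birth_year[k] + a)
            if yr <= last_year:
                rows_horse.append(k)
                rows_age.append(int(a))
                rows_year.append(yr)
    horse = np.array(rows_horse)
    age = np.array(rows_age)
    year = np.array(rows_year)
    n_rec = len(horse)

    # races per calendar year; each record joins one race of its year
    years_used = np.unique(year)
    race_ids = np.empty(n_rec, dtype=object)
    race_of = np.empty(n_rec, dtype=np.int64)
    race_attrs = {}
    rid = 0
    for yv in years_used:
        sel = np.flatnonzero(year == yv)
        n_races = cfg.races_per_year
        assign = rng.integers(0, n_races, size=len(sel))
        for r in range(n_races):
            members = sel[assign == r]
            if len(members) == 0:
                continue
            dist = rng.uniform(window.min_yards, window.max_yards)
            race_attrs[rid] = dict(
                distance=float(np.round(dist)),
                going=float(rng.uniform(*cfg.going_range)),
                racecourse=f"RC{rng.integers(0, cfg.n_racecourses):02d}",
                timing="automatic" if rng.random() < cfg.timing_auto_prob
                else "hand",
                effect=rng.normal(0.0, cfg.race_effect_sd),
                n_runners=len(members),
            )
            race_ids[members] = f"R{rid:06d}"
            race_of[members] = rid
            rid += 1

    dist = np.array([race_attrs[r]["distance"] for r in race_of])
    going = np.array([race_attrs[r]["going"] for r in race_of])
    race_eff = np.array([race_attrs[r]["effect"] for r in race_of])
    n_runners = np.array([race_attrs[r]["n_runners"] for r in race_of])
    course = np.array([race_attrs[r]["racecourse"] for r in race_of], dtype=object)
    timing = np.array([race_attrs[r]["timing"] for r in race_of], dtype=object)

    going_mid = 0.5 * (cfg.going_range[0] + cfg.going_range[1])
    dist_mid = 0.5 * (window.min_yards + window.max_yards)
    age_eff = np.array([cfg.age_effects.get(int(a), min(cfg.age_effects.values()))
                        for a in age])
    sex_eff = np.where(ped.sex[horse] == "M", cfg.sex_effect, 0.0)

    speed = (
        cfg.mean_speed
        + age_eff
        + sex_eff
        + cfg.going_coef * (going - going_mid)
        + cfg.distance_coef * (dist - dist_mid)
        + race_eff
        + bv[horse]
        + pe[horse]
        + trainer_eff[trainer_of[horse]]
        + rng.normal(0.0, np.sqrt(cfg.V_R), size=n_rec)
    )
    if np.any(speed <= 0):
        raise SimulationError("simulated speeds must be positive; check config")

    return pd.DataFrame(
        {
            "horse": ped.ids[horse],
            "race_id": race_ids,
            "finish_time": dist / speed,
            "distance": dist,
            "speed": speed,
            "going": going,
            "n_runners": n_runners,
            "timing": timing,
            "racecourse": course,
            "year": year,
            "age": age,
            "sex": np.where(ped.sex[horse] == "M", "M", "F"),
            "trainer": np.array(
                [f"T{t:03d}" for t in trainer_of[horse]], dtype=object
            ),
        }
    )


def simulate_dataset(cfg: GeneratorConfig, seed: int | None = None):
    """Pedigree, true breeding values and records in one call."""
    base = cfg.seed if seed is None else seed
    ped, true_bv = simulate_pedigree(cfg, seed=base)
    records = simulate_records(ped, true_bv, cfg, seed=base + 1)
    return ped, true_bv, records


def simulate_correlated_bvs(
    ped: Pedigree,
    V_A1: float,
    V_A2: float,
    r_G: float,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Gene-drop two genetically correlated traits down one pedigree.

    Founders draw bivariate-normal breeding values with additive covariance
    ``r_G * sqrt(V_A1 * V_A2)``; Mendelian deviations carry the same
    correlation with variance halved (and reduced by parental inbreeding),
    so the correlation structure is preserved across generations.
    """
    if not (-1.0 <= r_G <= 1.0):
        raise SimulationError("r_G must lie in [-1, 1]")
    from .drift import _generation_strata, _mendelian_sd2
    from .pedigree import inbreeding

    rng = np.random.default_rng(seed)
    G = np.array([
        [V_A1, r_G * np.sqrt(V_A1 * V_A2)],
        [r_G * np.sqrt(V_A1 * V_A2), V_A2],
    ])
    # matrix square root (PSD-safe for |r_G| = 1)
    w, V = np.linalg.eigh(G)
    Ghalf = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T

    F = inbreeding(ped).to_numpy()
    mend = _mendelian_sd2(ped, F)                   # per-individual multiplier
    z = rng.standard_normal((ped.n, 2))
    bv = np.sqrt(mend)[:, None] * (z @ Ghalf.T)
    for stratum in _generation_strata(ped)[1:]:
        s, d = ped.sire[stratum], ped.dam[stratum]
        pm = np.zeros((len(stratum), 2))
        pm[s >= 0] += 0.5 * bv[s[s >= 0]]
        pm[d >= 0] += 0.5 * bv[d[d >= 0]]
        bv[stratum] += pm
    return (
        pd.Series(bv[:, 0], index=ped.ids, name="true_bv_1"),
        pd.Series(bv[:, 1], index=ped.ids, name="true_bv_2"),
    )


def true_trend(ped: Pedigree, true_bv: pd.Series, first: int, last: int,
               restrict_to=None) -> float:
    """Realised OLS slope of cohort-mean true breeding value on birth year."""
    from .trend import cohort_means, estimate_beta_g

    tab = cohort_means(true_bv, ped, first, last, restrict_to=restrict_to)
    slope, _ = estimate_beta_g(tab)
    return slope


def write_truth(path, cfg: GeneratorConfig, ped: Pedigree,
                true_bv: pd.Series) -> None:
    """Ground-truth sidecar: true BVs plus the generating components."""
    df = true_bv.rename("true_bv").rename_axis("id").reset_index()
    df["birth_year"] = ped.birth_year[ped.positions(df["id"])].astype(int)
    with open(path, "w") as fh:
        fh.write(f"# V_A={cfg.V_A} V_PE={cfg.V_PE} V_T={cfg.V_T} V_R={cfg.V_R}\n")
        fh.write(f"# h2={cfg.h2:.6f} repeatability={cfg.repeatability:.6f}\n")
        df.to_csv(fh, index=False)
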