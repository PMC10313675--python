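"""Gene dropping and the drift null for the genetic trend.

Cohort-mean breeding values change over time even without selection, because
drift down a finite pedigree is not zero on average in any one realisation.
Gene dropping simulates neutral breeding values down the *observed* pedigree
(founders drawn from N(0, V_A), offspring from the parental mean plus a
Mendelian-sampling deviation) and regresses the simulated cohort means on
birth year, giving a null distribution of trend slopes against which the
estimated beta_G posterior is compared.  Selection is declared when the
probability that beta_G exceeds the drift slope is above 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .animal_model import PosteriorSamples
from .pedigree import Pedigree, inbreeding
from .trend import TrendResult


class DriftError(ValueError):
    pass


@dataclass
class DriftResult:
    """Null drift slopes and the exceedance probability of beta_G."""

    drift_slopes: np.ndarray
    p_exceeds_drift: float
    n_sim: int
    seed: int
    pairing: str = "resample"


def _mendelian_sd2(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Per-individual Mendelian-sampling variance multiplier (times V_A).

    Both parents known: 0.5 * (1 - (F_s + F_d)/2); one known parent: 3/4
    (the unknown parent's founder draw folded into the deviation); founders
    draw their whole breeding value, multiplier 1.
    """
    out = np.ones(ped.n)
    both = (ped.sire >= 0) & (ped.dam >= 0)
    one = (ped.sire >= 0) ^ (ped.dam >= 0)
    Fs = np.where(ped.sire >= 0, F[np.maximum(ped.sire, 0)], 0.0)
    Fd = np.where(ped.dam >= 0, F[np.maximum(ped.dam, 0)], 0.0)
    out[both] = 0.5 * (1.0 - 0.5 * (Fs[both] + Fd[both]))
    out[one] = 0.75
    return out


def _generation_strata(ped: Pedigree) -> list[np.ndarray]:
    """Index groups such that every parent lies in an earlier group."""
    level = np.zeros(ped.n, dtype=np.int64)
    for k in range(ped.n):
        lv = 0
        if ped.sire[k] >= 0:
            lv = level[ped.sire[k]] + 1
        if ped.dam[k] >= 0:
            lv = max(lv, level[ped.dam[k]] + 1)
        level[k] = lv
    return [np.flatnonzero(level == g) for g in range(level.max() + 1)]


def gene_drop(
    ped: Pedigree,
    V_A: float | np.ndarray,
    F: np.ndarray | pd.Series | None = None,
    seed: int | np.random.Generator = 0,
    n_sim: int = 1,
) -> np.ndarray:
    """Simulate neutral breeding values down the pedigree.

    ``V_A`` may be a scalar or one value per simulation.  Returns an array
    of shape ``(n_individuals, n_sim)`` (squeezed to 1-D when ``n_sim`` is 1
    and V_A is scalar), in pedigree order.
    """
    va = np.atleast_1d(np.asarray(V_A, dtype=float))
    if np.any(va < 0):
        raise DriftError("V_A must be non-negative")
    scalar_out = va.size == 1 and n_sim == 1
    if va.size == 1:
        va = np.full(n_sim, va[0])
    elif va.size != n_sim:
        raise DriftError("V_A must be scalar or of length n_sim")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if F is None:
        F = inbreeding(ped).to_numpy()
    else:
        F = np.asarray(F, dtype=float)

    mend = _mendelian_sd2(ped, F)                    # variance multipliers
    sd = np.sqrt(mend[:, None] * va[None, :])        # n_ind x n_sim
    bv = rng.standard_normal((ped.n, va.size)) * sd
    for stratum in _generation_strata(ped)[1:]:
        s, d = ped.sire[stratum], ped.dam[stratum]
        parent_mean = np.zeros((len(stratum), va.size))
        has_s, has_d = s >= 0, d >= 0
        parent_mean[has_s] += 0.5 * bv[s[has_s]]
        parent_mean[has_d] += 0.5 * bv[d[has_d]]
        bv[stratum] += parent_mean
    if scalar_out:
        return bv[:, 0]
    return bv


def drift_slopes(
    ped: Pedigree,
    V_A: np.ndarray,
    first: int,
    last: int,
    cohort_ids: set | None = None,
    seed: int | np.random.Generator = 0,
    F: np.ndarray | None = None,
) -> np.ndarray:
    """Regression slope of simulated cohort-mean BV on birth year, per sim."""
    bv = gene_drop(ped, V_A, F=F, seed=seed, n_sim=len(np.atleast_1d(V_A)))
    years = ped.birth_year
    mask = ~np.isnan(years) & (years >= first) & (years <= last)
    if cohort_ids is not None:
        cohort_ids = set(map(str, cohort_ids))
        mask &= np.array([str(i) in cohort_ids for i in ped.ids])
    if not mask.any():
        raise DriftError("no individuals born inside the cohort window")
    yrs = years[mask].astype(int)
    uniq = np.unique(yrs)
    if len(uniq) < 3:
        raise DriftError("need at least 3 cohorts for a drift slope")
    P = np.zeros((len(uniq), int(mask.sum())))
    for r, yv in enumerate(uniq):
        sel = yrs == yv
        P[r, sel] = 1.0 / sel.sum()
    means = P @ bv[mask]                             # years x n_sim
    xc = uniq - uniq.mean()
    return (xc @ (means - means.mean(axis=0))) / float(xc @ xc)


def run_drift_test(
    samples: PosteriorSamples,
    trend: TrendResult,
    ped: Pedigree,
    first: int,
    last: int,
    n_sim: int = 1000,
    seed: int = 0,
    cohort_ids: set | None = None,
    pairing: str = "resample",
) -> DriftResult:
    """Test whether the estimated genetic trend exceeds drift.

    For each replicate one V_A value is drawn (with replacement) from the
    posterior, breeding values are gene-dropped down the pedigree and the
    cohort regression slope recomputed over the same window and cohort
    definition as the observed trend.  With the default ``pairing
    ("resample")`` each drift slope is compared against an independent
    with-replacement draw from the beta_G posterior; ``pairing="full"``
    compares every posterior draw against every drift slope.
    """
    if trend.posterior is None:
        raise DriftError("trend result carries no beta_G posterior")
    if not np.array_equal(samples.ids, ped.ids):
        raise DriftError("posterior samples and pedigree do not match")
    if n_sim < 100:
        raise DriftError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    va_draws = samples.vc_draws["V_A"].to_numpy()
    va = rng.choice(va_draws, size=n_sim, replace=True)
    F = inbreeding(ped).to_numpy()
    slopes = drift_slopes(
        ped, va, first, last, cohort_ids=cohort_ids, seed=rng, F=F
    )
    if pairing == "resample":
        beta = rng.choice(trend.posterior, size=n_sim, replace=True)
        p = float(np.mean(beta > slopes))
    elif pairing == "full":
        p = float(np.mean(trend.posterior[:, None] > slopes[None, :]))
    else:
        raise DriftError(f"unknown pairing rule {pairing!r}")
    return DriftResult(
        drift_slopes=slopes, p_exceeds_drift=p, n_sim=n_sim, seed=seed,
        pairing=pairing,
    )
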