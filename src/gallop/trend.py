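"""Cohort breeding-value trends: the rate of genetic change beta_G.

The genetic trend is the ordinary least-squares slope of cohort-mean
predicted breeding value on year of birth (yards s^-1 year^-1), computed
over phenotyped horses born inside a cohort window (1995-2012 in the
source data).  With MCMC breeding-value draws the whole regression is
repeated per retained draw, giving a posterior for beta_G whose mode (via a
Gaussian-kernel density, Silverman bandwidth), 95% highest-density interval
and exceedance probability P(beta_G > 0) are reported; a genetic trend is
declared significant when that probability exceeds 0.95.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .animal_model import PosteriorSamples, posterior_mode
from .pedigree import Pedigree

logger = logging.getLogger(__name__)


class TrendError(ValueError):
    pass


@dataclass
class TrendResult:
    """Estimated rate of genetic change and, optionally, its posterior."""

    beta_G: float
    source: str                       # "REML" or "MCMC"
    cohort_range: tuple
    posterior: np.ndarray | None = None
    interval: tuple | None = None     # 95% highest-density interval
    p_positive: float | None = None
    beta_P: float | None = None
    ratio: float | None = None
    se: float | None = None
    cohort_table: pd.DataFrame | None = field(default=None, repr=False)

    def with_beta_p(self, beta_P: float) -> "TrendResult":
        self.beta_P = float(beta_P)
        self.ratio = self.beta_G / self.beta_P
        return self


def cohort_means(
    pbv: pd.Series,
    ped: Pedigree,
    first: int,
    last: int,
    restrict_to: set | None = None,
) -> pd.DataFrame:
    """Arithmetic mean predicted breeding value by year of birth.

    ``restrict_to`` (typically the phenotyped horses) limits the cohorts;
    cohorts with no individuals are omitted and logged.
    """
    if first > last:
        raise TrendError("cohort window must satisfy first <= last")
    ids = pbv.index.to_numpy()
    pos = ped.positions(ids)
    years = ped.birth_year[pos]
    if np.isnan(years).any():
        bad = ids[np.isnan(years)]
        raise TrendError(f"birth year missing for {len(bad)} individuals with PBVs")
    mask = (years >= first) & (years <= last)
    if restrict_to is not None:
        restrict_to = set(map(str, restrict_to))
        mask &= np.array([str(i) in restrict_to for i in ids])
    if not mask.any():
        raise TrendError("no individuals born inside the cohort window")
    df = pd.DataFrame({"year": years[mask].astype(int), "pbv": pbv.to_numpy()[mask]})
    tab = df.groupby("year")["pbv"].agg(["mean", "count"]).reset_index()
    tab.columns = ["year", "mean", "n"]
    missing = set(range(first, last + 1)) - set(tab["year"])
    if missing:
        logger.info("cohorts with no individuals omitted: %s", sorted(missing))
    return tab


def estimate_beta_g(
    cohort_table: pd.DataFrame, weight_by_size: bool = False
) -> tuple[float, float]:
    """OLS slope of cohort mean on year; returns (slope, se).

    Unweighted by default; ``weight_by_size`` weights each cohort by its
    number of individuals instead.
    """
    if len(cohort_table) < 3:
        raise TrendError("need at least 3 cohorts to estimate a trend")
    import statsmodels.api as sm

    X = sm.add_constant(cohort_table["year"].to_numpy(dtype=float))
    y = cohort_table["mean"].to_numpy(dtype=float)
    if weight_by_size:
        fit = sm.WLS(y, X, weights=cohort_table["n"].to_numpy(dtype=float)).fit()
    else:
        fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1])


def trend_from_fit(
    fit_pbv: pd.Series,
    ped: Pedigree,
    first: int,
    last: int,
    phenotyped: set | None = None,
    beta_P: float | None = None,
) -> TrendResult:
    """REML-style point estimate of beta_G from BLUP breeding values."""
    tab = cohort_means(fit_pbv, ped, first, last, restrict_to=phenotyped)
    slope, se = estimate_beta_g(tab)
    res = TrendResult(
        beta_G=slope, source="REML", cohort_range=(first, last),
        se=se, cohort_table=tab,
    )
    if beta_P is not None:
        res.with_beta_p(beta_P)
    return res


def beta_g_posterior(
    samples: PosteriorSamples,
    ped: Pedigree,
    first: int,
    last: int,
    phenotyped: set | None = None,
    beta_P: float | None = None,
) -> TrendResult:
    """Posterior of beta_G: one cohort regression per retained draw.

    Point estimate is the kernel-density posterior mode; the interval is the
    95% highest-density interval; ``p_positive`` is the fraction of draws
    with a positive slope.
    """
    pos = ped.positions(samples.ids)
    years = ped.birth_year[pos]
    mask = ~np.isnan(years)
    mask &= (years >= first) & (years <= last)
    if phenotyped is not None:
        phenotyped = set(map(str, phenotyped))
        mask &= np.array([str(i) in phenotyped for i in samples.ids])
    if not mask.any():
        raise TrendError("no individuals born inside the cohort window")

    yrs = years[mask].astype(int)
    uniq = np.unique(yrs)
    if len(uniq) < 3:
        raise TrendError("need at least 3 cohorts to estimate a trend")
    # cohort-mean operator: (n_years x n_individuals), rows sum to 1
    P = np.zeros((len(uniq), int(mask.sum())))
    for r, yv in enumerate(uniq):
        sel = yrs == yv
        P[r, sel] = 1.0 / sel.sum()
    means = samples.bv_draws[:, mask] @ P.T          # draws x years
    xc = uniq - uniq.mean()
    slopes = (means - means.mean(axis=1, keepdims=True)) @ xc / float(xc @ xc)

    mode = posterior_mode(slopes)
    if np.ptp(slopes) < 1e-14:
        lo = hi = float(slopes[0])
    else:
        import arviz

        lo, hi = arviz.hdi(np.asarray(slopes), hdi_prob=0.95)
    res = TrendResult(
        beta_G=float(mode),
        source="MCMC",
        cohort_range=(first, last),
        posterior=np.asarray(slopes),
        interval=(float(lo), float(hi)),
        p_positive=float(np.mean(slopes > 0)),
    )
    if beta_P is not None:
        res.with_beta_p(beta_P)
    return res


def plot_trend(
    samples: PosteriorSamples,
    ped: Pedigree,
    first: int,
    last: int,
    phenotyped: set | None = None,
    path=None,
):
    """Cohort posterior modes with 95% intervals and per-draw spaghetti."""
    import matplotlib

    matplotlib.use("Agg")
    import arviz
    import matplotlib.pyplot as plt

    pos = ped.positions(samples.ids)
    years = ped.birth_year[pos]
    mask = ~np.isnan(years) & (years >= first) & (years <= last)
    if phenotyped is not None:
        phenotyped = set(map(str, phenotyped))
        mask &= np.array([str(i) in phenotyped for i in samples.ids])
    yrs = years[mask].astype(int)
    uniq = np.unique(yrs)
    P = np.zeros((len(uniq), int(mask.sum())))
    for r, yv in enumerate(uniq):
        sel = yrs == yv
        P[r, sel] = 1.0 / sel.sum()
    means = samples.bv_draws[:, mask] @ P.T

    fig, ax = plt.subplots(figsize=(7, 4.5))
    step = max(1, len(means) // 200)
    ax.plot(uniq, means[::step].T, color="0.8", lw=0.4, zorder=1)
    modes = [posterior_mode(means[:, c]) for c in range(len(uniq))]
    his = np.array([arviz.hdi(means[:, c], hdi_prob=0.95) for c in range(len(uniq))])
    ax.errorbar(
        uniq, modes,
        yerr=[np.array(modes) - his[:, 0], his[:, 1] - np.array(modes)],
        fmt="o", color="k", capsize=2, zorder=2,
    )
    ax.set_xlabel("year of birth")
    ax.set_ylabel("mean PBV for speed (yards/s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
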