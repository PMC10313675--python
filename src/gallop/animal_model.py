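"""Univariate and bivariate animal models: REML, Gibbs sampling, diagnostics.

The animal model treats each horse's additive genetic merit (breeding value)
as a random effect whose covariance is ``V_A * A``, with **A** the pedigree
numerator relationship matrix.  Alongside it the model carries permanent
environment (horse identity) and trainer random effects, so phenotypic
variance conditional on fixed effects partitions as

    V_P = V_A + V_PE + V_T + V_R,

with heritability ``h2 = V_A / V_P`` and repeatability
``R = (V_A + V_PE) / V_P``.

REML fitting uses EM steps (with Aitken acceleration) on the mixed-model
equations built with the full relationship matrix; the Gibbs sampler updates
whole effect vectors from their multivariate-normal full conditionals and
draws each variance from its scaled inverse-chi-square full conditional
under a weak inverse-Wishart prior (nu = 0.002, V = 1, the MCMCglmm
parameterisation).  Breeding values are whitened through an eigendecomposition
of ``L' D L`` (L the Cholesky factor of A, D the record counts) so each
sweep costs a handful of matrix-vector products.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.special
import scipy.stats
from scipy.linalg import lapack

from .design import DesignMatrices
from .pedigree import RelationshipMatrix, relationship_matrix

logger = logging.getLogger(__name__)

VC_NAMES = ("V_A", "V_PE", "V_T", "V_R")
_TERM_TO_VC = {"animal": "V_A", "pe": "V_PE", "trainer": "V_T"}


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Variance partition conditional on fixed effects (yards^2 s^-2)."""

    V_A: float
    V_PE: float
    V_T: float
    V_R: float
    se: dict = field(default_factory=dict)

    @property
    def V_P(self) -> float:
        return self.V_A + self.V_PE + self.V_T + self.V_R

    @property
    def h2(self) -> float:
        return self.V_A / self.V_P

    @property
    def repeatability(self) -> float:
        return (self.V_A + self.V_PE) / self.V_P

    @property
    def sigma_A(self) -> float:
        return math.sqrt(self.V_A)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                **{k: getattr(self, k) for k in VC_NAMES},
                "V_P": self.V_P,
                "h2": self.h2,
                "repeatability": self.repeatability,
            }
        )


@dataclass
class ModelFit:
    """A converged (or best-effort) REML fit."""

    vc: VarianceComponents
    fixed_effects: pd.Series
    pbv: pd.Series               # BLUP breeding value for every pedigree individual
    loglik: float                # restricted log-likelihood (additive const dropped)
    converged: bool
    n_iter: int
    boundary: list = field(default_factory=list)
    spec_name: str = ""
    random_terms: tuple = ()
    n_records: int = 0
    n_fixed: int = 0


@dataclass
class ChainSpec:
    """MCMC bookkeeping: total iterations, burn-in, thinning interval."""

    n_iter: int
    burn_in: int
    thin: int = 1

    def __post_init__(self) -> None:
        if not (self.n_iter > self.burn_in >= 0 and self.thin >= 1):
            raise ModelError("chain spec requires n_iter > burn_in >= 0, thin >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PriorSpec:
    """Univariate inverse-Wishart prior, MCMCglmm parameterisation.

    Each variance has prior scaled-inverse-chi-square with ``nu`` degrees of
    belief and scale ``V``; nu = 0.002 is the conventional near-flat choice.
    """

    nu: float = 0.002
    V: float = 1.0


@dataclass
class PosteriorSamples:
    """Thinned Gibbs draws of the variance components and breeding values."""

    vc_draws: pd.DataFrame       # columns V_A, V_PE, V_T, V_R
    bv_draws: np.ndarray         # n_retained x n_pedigree
    ids: np.ndarray              # pedigree ids (columns of bv_draws)
    chain_meta: dict

    @property
    def n_retained(self) -> int:
        return len(self.vc_draws)

    def posterior_vc(self) -> VarianceComponents:
        m = self.vc_draws.mean()
        return VarianceComponents(
            m["V_A"], m["V_PE"], m["V_T"], m["V_R"],
            se={k: float(self.vc_draws[k].std()) for k in VC_NAMES},
        )


@dataclass
class GeneticCorrelationResult:
    """Posterior of the genetic correlation between two speed traits."""

    r_G: float                   # posterior mode
    interval: tuple              # 95% highest-density interval
    V_A: tuple                   # posterior-mean additive variance per trait
    rg_draws: np.ndarray
    chain_meta: dict


# ---------------------------------------------------------------------------
# shared precomputation
# ---------------------------------------------------------------------------


def _chol_psd(Adense: np.ndarray) -> np.ndarray:
    try:
        return scipy.linalg.cholesky(Adense, lower=True)
    except scipy.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(Adense) / len(Adense)
        logger.warning("relationship matrix not PD; adding jitter %g", jitter)
        return scipy.linalg.cholesky(
            Adense + jitter * np.eye(len(Adense)), lower=True
        )


def _resolve_A(design: DesignMatrices, A: RelationshipMatrix | None):
    if A is None:
        A = relationship_matrix(design.ped)
    if len(A.ids) != len(design.term_levels["animal"]) or not np.array_equal(
        A.ids, design.term_levels["animal"]
    ):
        raise ModelError("relationship matrix order does not match the design")
    return A


class _MME:
    """Mixed-model equations with full A, shared by REML iterations."""

    def __init__(self, design: DesignMatrices, A: RelationshipMatrix | None,
                 random_terms: Sequence[str]):
        A = _resolve_A(design, A)
        self.design = design
        self.terms = list(random_terms)
        y, X = design.y, design.X
        self.N, self.p = X.shape
        self.yty = float(y @ y)

        Zs = []
        self.q = []
        self.Ginv = []
        self.logdetG = []
        for t in self.terms:
            idx = design.term_index[t]
            qk = len(design.term_levels[t])
            Z = sp.csr_matrix(
                (np.ones(len(idx)), (np.arange(len(idx)), idx)),
                shape=(len(idx), qk),
            )
            Zs.append(Z)
            self.q.append(qk)
            if t == "animal":
                Ad = A.toarray()
                L = _chol_psd(Ad)
                self.logdetG.append(2.0 * float(np.sum(np.log(np.diag(L)))))
                ident = np.eye(len(Ad))
                Ainv = scipy.linalg.cho_solve((L, True), ident)
                self.Ginv.append(0.5 * (Ainv + Ainv.T))
            else:
                self.Ginv.append(None)
                self.logdetG.append(0.0)

        m = self.p + sum(self.q)
        self.m = m
        M0 = np.zeros((m, m))
        rhs0 = np.zeros(m)
        M0[: self.p, : self.p] = X.T @ X
        rhs0[: self.p] = X.T @ y
        off = [self.p]
        for Z in Zs:
            off.append(off[-1] + Z.shape[1])
        self.offsets = off
        for a, Za in enumerate(Zs):
            ia, ja = off[a], off[a + 1]
            M0[ia:ja, : self.p] = (Za.T @ X)
            M0[: self.p, ia:ja] = M0[ia:ja, : self.p].T
            rhs0[ia:ja] = Za.T @ y
            for b in range(a, len(Zs)):
                ib, jb = off[b], off[b + 1]
                blk = (Zs[a].T @ Zs[b]).toarray()
                M0[ia:ja, ib:jb] = blk
                M0[ib:jb, ia:ja] = blk.T
        self.M0 = M0
        self.rhs0 = rhs0

    def _assemble(self, sig: np.ndarray, sig_e: float) -> np.ndarray:
        C = self.M0 / sig_e
        for k, t in enumerate(self.terms):
            i, j = self.offsets[k], self.offsets[k + 1]
            if self.Ginv[k] is None:
                C[i:j, i:j] += np.eye(self.q[k]) / sig[k]
            else:
                C[i:j, i:j] += self.Ginv[k] / sig[k]
        return C

    def loglik(self, sig: np.ndarray, sig_e: float) -> float:
        """Restricted log-likelihood (constants independent of parameters dropped)."""
        C = self._assemble(sig, sig_e)
        cfac, info = lapack.dpotrf(C, lower=1)
        if info != 0:
            return -np.inf
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cfac))))
        s, _ = lapack.dpotrs(cfac, self.rhs0 / sig_e, lower=1)
        ypy = (self.yty - float(s @ self.rhs0)) / sig_e
        quad = (
            self.N * math.log(sig_e)
            + sum(
                self.q[k] * math.log(sig[k]) + self.logdetG[k]
                for k in range(len(self.terms))
            )
            + logdetC
            + ypy
        )
        return -0.5 * quad

    def solve_full(self, sig: np.ndarray, sig_e: float):
        """Solution vector, loglik and full inverse of the MME matrix."""
        C = self._assemble(sig, sig_e)
        cfac, info = lapack.dpotrf(C, lower=1)
        if info != 0:
            raise ModelError("mixed-model equations not positive definite")
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cfac))))
        s, _ = lapack.dpotrs(cfac, self.rhs0 / sig_e, lower=1)
        Cinv, info = lapack.dpotri(cfac, lower=1)
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        ypy = (self.yty - float(s @ self.rhs0)) / sig_e
        ll = -0.5 * (
            self.N * math.log(sig_e)
            + sum(
                self.q[k] * math.log(sig[k]) + self.logdetG[k]
                for k in range(len(self.terms))
            )
            + logdetC
            + ypy
        )
        return s, ll, Cinv


def restricted_loglik(
    design: DesignMatrices,
    A: RelationshipMatrix | None,
    sigmas: dict,
    random_terms: Sequence[str] = ("animal", "pe", "trainer"),
) -> float:
    """Restricted log-likelihood at the given variance components.

    ``sigmas`` maps ``V_A``/``V_PE``/``V_T`` (per fitted term) and ``V_R``.
    """
    mme = _MME(design, A, random_terms)
    sig = np.array([sigmas[_TERM_TO_VC[t]] for t in random_terms])
    return mme.loglik(sig, sigmas["V_R"])


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


@dataclass
class RemlOptions:
    max_iter: int = 800
    tol: float = 1e-8            # relative log-likelihood change
    accelerate: bool = True
    accel_every: int = 4
    bound_frac: float = 1e-10    # lower bound on a component, as fraction of V_P
    compute_se: bool = True


def fit_reml(
    design: DesignMatrices,
    A: RelationshipMatrix | None = None,
    random_terms: Sequence[str] = ("animal", "pe", "trainer"),
    opts: RemlOptions | None = None,
) -> ModelFit:
    """EM-REML fit of the animal model (with Aitken acceleration).

    Returns BLUP breeding values for every pedigree individual at the
    converged components, the restricted log-likelihood, and delta-method
    standard errors from the observed information matrix.
    """
    opts = opts or RemlOptions()
    mme = _MME(design, A, random_terms)
    nt = len(mme.terms)
    vy = float(np.var(design.y))
    sig = np.full(nt, vy / (nt + 1))
    sig_e = vy / (nt + 1)

    ll_prev = -np.inf
    history: list[np.ndarray] = []
    boundary: set[str] = set()
    converged = False
    s = None
    ll = -np.inf
    it = 0
    for it in range(1, opts.max_iter + 1):
        s, ll, Cinv = mme.solve_full(sig, sig_e)

        # EM updates
        new_sig = np.empty_like(sig)
        for k, t in enumerate(mme.terms):
            i, j = mme.offsets[k], mme.offsets[k + 1]
            u = s[i:j]
            blk = Cinv[i:j, i:j]
            if mme.Ginv[k] is None:
                num = float(u @ u) + float(np.trace(blk))
            else:
                num = float(u @ (mme.Ginv[k] @ u)) + float(
                    np.sum(mme.Ginv[k] * blk)
                )
            new_sig[k] = num / mme.q[k]
        new_sig_e = (mme.yty - float(s @ mme.rhs0)) / (mme.N - mme.p)

        vp = float(new_sig.sum() + new_sig_e)
        bound = opts.bound_frac * vp
        for k, t in enumerate(mme.terms):
            if new_sig[k] < bound:
                new_sig[k] = bound
                boundary.add(_TERM_TO_VC[t])
                logger.info("component %s pinned at lower bound", _TERM_TO_VC[t])
        sig, sig_e = new_sig, max(new_sig_e, bound)

        # Aitken acceleration on log-variances
        history.append(np.log(np.concatenate([sig, [sig_e]])))
        if (
            opts.accelerate
            and len(history) >= 3
            and it % opts.accel_every == 0
        ):
            t2, t1, t0 = history[-1], history[-2], history[-3]
            d1, d0 = t2 - t1, t1 - t0
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(np.abs(d0) > 1e-14, d1 / d0, 0.0)
            # slow ridges (confounded components) have rates near 1; the
            # log-likelihood guard below makes large extrapolations safe
            ok = (r > 0) & (r < 0.9999)
            if ok.any():
                theta = t2 + np.where(ok, d1 * r / (1 - r), 0.0)
                cand = np.exp(theta)
                ll_cand = mme.loglik(cand[:-1], cand[-1])
                if ll_cand > ll:
                    sig, sig_e = cand[:-1], cand[-1]
                    history.append(np.log(cand))

        param_stable = len(history) >= 2 and np.max(
            np.abs(history[-1] - history[-2])
        ) < 1e-7
        if np.isfinite(ll) and (
            abs(ll - ll_prev) < opts.tol * (1.0 + abs(ll)) or param_stable
        ):
            converged = True
            break
        ll_prev = ll

    if not converged:
        logger.warning("REML did not converge in %d iterations", opts.max_iter)

    s, ll, _ = mme.solve_full(sig, sig_e)

    comp = {"V_A": 0.0, "V_PE": 0.0, "V_T": 0.0}
    for k, t in enumerate(mme.terms):
        comp[_TERM_TO_VC[t]] = float(sig[k])
    vc = VarianceComponents(comp["V_A"], comp["V_PE"], comp["V_T"], float(sig_e))
    if opts.compute_se:
        vc.se = _reml_se(mme, sig, sig_e, boundary)

    fixed = pd.Series(s[: mme.p], index=design.x_labels, name="estimate")
    if "animal" in mme.terms:
        k = mme.terms.index("animal")
        i, j = mme.offsets[k], mme.offsets[k + 1]
        pbv = pd.Series(s[i:j], index=design.ped.ids, name="pbv")
    else:
        pbv = pd.Series(np.zeros(design.ped.n), index=design.ped.ids, name="pbv")

    return ModelFit(
        vc=vc,
        fixed_effects=fixed,
        pbv=pbv,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        boundary=sorted(boundary),
        spec_name=design.spec_name,
        random_terms=tuple(mme.terms),
        n_records=mme.N,
        n_fixed=mme.p,
    )


def _reml_se(mme: _MME, sig: np.ndarray, sig_e: float, boundary: set) -> dict:
    """Delta-method SEs from a finite-difference observed information matrix."""
    theta = np.concatenate([sig, [sig_e]])
    names = [_TERM_TO_VC[t] for t in mme.terms] + ["V_R"]
    # components at (or effectively at) the zero boundary have no two-sided
    # curvature; exclude them like explicitly pinned ones
    near_zero = {names[k] for k in range(len(names))
                 if theta[k] < 1e-6 * theta.sum()}
    boundary = set(boundary) | near_zero
    free = [k for k, nm in enumerate(names) if nm not in boundary]
    if not free:
        return {}

    def f(th):
        return mme.loglik(th[:-1], th[-1])

    h = 1e-4 * (theta + 1e-3 * theta.sum())
    nf = len(free)
    H = np.zeros((nf, nf))
    f0 = f(theta)
    for a_, ka in enumerate(free):
        ta = theta.copy()
        ta[ka] += h[ka]
        tb = theta.copy()
        tb[ka] -= h[ka]
        H[a_, a_] = (f(ta) - 2 * f0 + f(tb)) / h[ka] ** 2
        for b_, kb in enumerate(free[a_ + 1:], start=a_ + 1):
            tpp = theta.copy(); tpp[ka] += h[ka]; tpp[kb] += h[kb]
            tpm = theta.copy(); tpm[ka] += h[ka]; tpm[kb] -= h[kb]
            tmp = theta.copy(); tmp[ka] -= h[ka]; tmp[kb] += h[kb]
            tmm = theta.copy(); tmm[ka] -= h[ka]; tmm[kb] -= h[kb]
            H[a_, b_] = H[b_, a_] = (
                f(tpp) - f(tpm) - f(tmp) + f(tmm)
            ) / (4 * h[ka] * h[kb])
    if not np.all(np.isfinite(H)):
        logger.warning("non-finite curvature at the optimum; SEs unavailable")
        return {}
    try:
        cov = scipy.linalg.inv(-H)
    except scipy.linalg.LinAlgError:
        return {}
    if np.any(np.diag(cov) < 0):
        logger.warning("observed information not PD; SEs unavailable")
        return {}

    se = {names[k]: float(np.sqrt(cov[a_, a_])) for a_, k in enumerate(free)}

    # delta method for ratios: h2 = V_A / V_P and R = (V_A + V_PE) / V_P
    full_names = [names[k] for k in free]
    th = {names[k]: theta[k] for k in range(len(names))}
    vp = sum(th.values())

    def ratio_se(num_names):
        num = sum(th[nm] for nm in num_names)
        grad = np.array([
            ((1.0 if nm in num_names else 0.0) * vp - num) / vp**2
            for nm in full_names
        ])
        return float(np.sqrt(grad @ cov @ grad))

    if "V_A" in full_names:
        se["h2"] = ratio_se(["V_A"])
        se["repeatability"] = ratio_se(
            [nm for nm in ("V_A", "V_PE") if nm in full_names]
        )
    return se


# ---------------------------------------------------------------------------
# likelihood-ratio test for V_A
# ---------------------------------------------------------------------------


def lrt_va(full: ModelFit, reduced: ModelFit) -> tuple[float, float]:
    """LRT of the additive genetic variance against a boundary null.

    Twice the log-likelihood difference is referred to a 50:50 mixture of
    chi-square(0) and chi-square(1), the distribution for a single variance
    tested on the boundary of its parameter space.
    """
    if full.n_records != reduced.n_records or full.n_fixed != reduced.n_fixed:
        raise ModelError("full and reduced fits use different data or fixed effects")
    if set(reduced.random_terms) != set(full.random_terms) - {"animal"}:
        raise ModelError("reduced model must omit exactly the additive term")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if stat == 0.0 else 0.5 * float(scipy.stats.chi2.sf(stat, df=1))
    return stat, p


# ---------------------------------------------------------------------------
# Gibbs sampler (univariate)
# ---------------------------------------------------------------------------


def _draw_invgamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    """scale / Gamma(shape): the scaled inverse-chi-square full conditional."""
    return scale / rng.gamma(shape)


class _AnimalWhitener:
    """Rotation making the breeding-value full conditional diagonal.

    With ``A = L L'`` and ``M = L' D L = U diag(lam) U'`` (D the per-individual
    record counts), the rotated effect ``v = U' L^{-1} a`` has prior
    ``N(0, V_A I)`` and diagonal likelihood precision ``lam / V_R``.
    """

    def __init__(self, Adense: np.ndarray, counts: np.ndarray):
        self.L = _chol_psd(Adense)
        M = self.L.T @ (counts[:, None] * self.L)
        lam, U = scipy.linalg.eigh(M)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        B = self.L @ U               # a = B v
        # single precision halves the memory traffic of the two matvecs per
        # sweep; the induced error is far below the Monte-Carlo noise
        dtype = np.float32 if len(B) > 1000 else np.float64
        self.B = B.astype(dtype)
        self.Bt = np.ascontiguousarray(B.T).astype(dtype)

    def sample(self, rng, h, sig_a, sig_e, prior_mean_w=None, prior_var=None):
        """Draw v given aggregated residuals h = Z' r; returns (v, a)."""
        pv = sig_a if prior_var is None else prior_var
        prec = self.lam / sig_e + 1.0 / pv
        mean = (self.Bt @ h.astype(self.Bt.dtype)).astype(np.float64) / sig_e
        if prior_mean_w is not None:
            mean = mean + (self.U.T @ prior_mean_w) / pv
        mean = mean / prec
        v = mean + rng.standard_normal(len(mean)) / np.sqrt(prec)
        return v, (self.B @ v.astype(self.B.dtype)).astype(np.float64)


def fit_gibbs(
    design: DesignMatrices,
    A: RelationshipMatrix | None = None,
    chain: ChainSpec = ChainSpec(11000, 1000, 10),
    prior: PriorSpec | None = None,
    seed: int = 0,
    random_terms: Sequence[str] = ("animal", "pe", "trainer"),
) -> PosteriorSamples:
    """Block Gibbs sampler for the univariate animal model.

    Fully reproducible given ``seed``; retains
    ``(n_iter - burn_in) // thin`` draws of the variance components and of
    the breeding values of every pedigree individual.
    """
    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)
    A = _resolve_A(design, A)
    y, X = design.y, design.X
    N, p = X.shape
    terms = list(random_terms)

    XtX_cho = scipy.linalg.cho_factor(X.T @ X, lower=True)
    L_x = scipy.linalg.cholesky(X.T @ X, lower=True)
    # factor-heavy designs are mostly zeros: sparse products cut the sweep cost
    if np.count_nonzero(X) < 0.25 * X.size:
        Xop = sp.csr_matrix(X)
        XopT = sp.csr_matrix(X.T)
    else:
        Xop, XopT = X, X.T

    n_ped = design.ped.n
    ai = design.term_index["animal"]
    counts_a = np.bincount(ai, minlength=n_ped).astype(float)
    wh = _AnimalWhitener(A.toarray(), counts_a) if "animal" in terms else None

    blocks = {}
    for t in terms:
        if t == "animal":
            continue
        idx = design.term_index[t]
        q = len(design.term_levels[t])
        blocks[t] = (idx, np.bincount(idx, minlength=q).astype(float), q)

    # state
    vy = float(np.var(y))
    sig = {t: vy / (len(terms) + 1) for t in terms}
    sig_e = vy / (len(terms) + 1)
    beta = np.zeros(p)
    a = np.zeros(n_ped)
    v = np.zeros(n_ped)
    u = {t: np.zeros(blocks[t][2]) for t in blocks}

    n_ret = chain.n_retained
    vc_out = np.zeros((n_ret, 4))
    bv_out = np.zeros((n_ret, n_ped))
    kept = 0

    def rec_contrib():
        out = np.zeros(N)
        if wh is not None:
            out += a[ai]
        for t, (idx, _, _) in blocks.items():
            out += u[t][idx]
        return out

    for sweep in range(chain.n_iter):
        # fixed effects
        r = y - rec_contrib()
        mu = scipy.linalg.cho_solve(XtX_cho, XopT @ r)
        z = rng.standard_normal(p)
        beta = mu + math.sqrt(sig_e) * scipy.linalg.solve_triangular(
            L_x.T, z, lower=False
        )
        xb = Xop @ beta

        # breeding values
        if wh is not None:
            r = y - xb
            for t, (idx, _, _) in blocks.items():
                r -= u[t][idx]
            h = np.bincount(ai, weights=r, minlength=n_ped)
            v, a = wh.sample(rng, h, sig["animal"], sig_e)

        # diagonal random effects (permanent environment, trainer)
        for t, (idx, cnt, q) in blocks.items():
            r = y - xb
            if wh is not None:
                r -= a[ai]
            for t2, (idx2, _, _) in blocks.items():
                if t2 != t:
                    r -= u[t2][idx2]
            ssum = np.bincount(idx, weights=r, minlength=q)
            prec = cnt / sig_e + 1.0 / sig[t]
            mean = (ssum / sig_e) / prec
            u[t] = mean + rng.standard_normal(q) / np.sqrt(prec)

        # variances
        if wh is not None:
            S = float(v @ v)
            sig["animal"] = _draw_invgamma(
                rng, (prior.nu + n_ped) / 2.0, (prior.nu * prior.V + S) / 2.0
            )
        for t, (_, _, q) in blocks.items():
            S = float(u[t] @ u[t])
            sig[t] = _draw_invgamma(
                rng, (prior.nu + q) / 2.0, (prior.nu * prior.V + S) / 2.0
            )
        e = y - xb - rec_contrib()
        sig_e = _draw_invgamma(
            rng, (prior.nu + N) / 2.0, (prior.nu * prior.V + float(e @ e)) / 2.0
        )
        if not (np.isfinite(sig_e) and all(np.isfinite(s) for s in sig.values())):
            raise ModelError(
                f"divergent chain at sweep {sweep}: non-finite variance draw"
            )

        if sweep >= chain.burn_in and (sweep - chain.burn_in) % chain.thin == 0:
            if kept < n_ret:
                vc_out[kept] = [
                    sig.get("animal", 0.0),
                    sig.get("pe", 0.0),
                    sig.get("trainer", 0.0),
                    sig_e,
                ]
                bv_out[kept] = a
                kept += 1

    vc_df = pd.DataFrame(vc_out[:kept], columns=list(VC_NAMES))
    return PosteriorSamples(
        vc_draws=vc_df,
        bv_draws=bv_out[:kept],
        ids=design.ped.ids.copy(),
        chain_meta={
            "n_iter": chain.n_iter,
            "burn_in": chain.burn_in,
            "thin": chain.thin,
            "seed": seed,
            "prior_nu": prior.nu,
            "prior_V": prior.V,
        },
    )


# ---------------------------------------------------------------------------
# Gibbs sampler (bivariate genetic correlation)
# ---------------------------------------------------------------------------


def fit_bivariate_gibbs(
    designs: tuple[DesignMatrices, DesignMatrices],
    A: RelationshipMatrix | None = None,
    chain: ChainSpec = ChainSpec(6000, 1000, 5),
    seed: int = 0,
    nu_g: float = 0.004,
    random_terms: Sequence[str] = ("pe", "trainer"),
) -> GeneticCorrelationResult:
    """Two-trait animal model with a full 2x2 additive covariance matrix.

    Permanent-environment and trainer effects are kept diagonal across
    traits (races are distinct events, so residual covariance between the
    traits is fixed at zero).  The genetic covariance matrix receives an
    inverse-Wishart full conditional with weak prior (nu = 0.004, scale I).
    Requires either cross-classified individuals or pedigree links between
    the two record sets, otherwise r_G is unidentifiable.
    """
    d1, d2 = designs
    if d1.ped is not d2.ped and not np.array_equal(d1.ped.ids, d2.ped.ids):
        raise ModelError("the two designs must share one pedigree")
    ped = d1.ped
    A = _resolve_A(d1, A)
    Adense = A.toarray()
    n_ped = ped.n

    set1 = np.unique(d1.term_index["animal"])
    set2 = np.unique(d2.term_index["animal"])
    shared = np.intersect1d(set1, set2)
    if len(shared) == 0 and not np.any(Adense[np.ix_(set1, set2)] != 0):
        raise ModelError(
            "no cross-classified individuals and no genetic links between "
            "trait record sets: genetic correlation is unidentifiable"
        )

    rng = np.random.default_rng(seed)
    prior = PriorSpec()
    L = _chol_psd(Adense)
    Linv_solve = lambda x: scipy.linalg.solve_triangular(L, x, lower=True)

    traits = []
    for d in (d1, d2):
        y, X = d.y, d.X
        ai = d.term_index["animal"]
        counts = np.bincount(ai, minlength=n_ped).astype(float)
        M = L.T @ (counts[:, None] * L)
        lam, U = scipy.linalg.eigh(M)
        blocks = {}
        for t in random_terms:
            idx = d.term_index[t]
            q = len(d.term_levels[t])
            blocks[t] = (idx, np.bincount(idx, minlength=q).astype(float), q)
        traits.append(
            dict(
                y=y, X=X, N=len(y), p=X.shape[1], ai=ai,
                XtX_cho=scipy.linalg.cho_factor(X.T @ X, lower=True),
                L_x=scipy.linalg.cholesky(X.T @ X, lower=True),
                lam=np.clip(lam, 0, None), U=U, B=L @ U,
                blocks=blocks,
                beta=np.zeros(X.shape[1]),
                a=np.zeros(n_ped), w=np.zeros(n_ped),
                u={t: np.zeros(blocks[t][2]) for t in blocks},
                sig={t: float(np.var(y)) / 4 for t in ("pe", "trainer")},
                sig_e=float(np.var(y)) / 4,
            )
        )

    G = np.eye(2) * float(np.var(d1.y)) / 4

    n_ret = chain.n_retained
    rg_draws = np.zeros(n_ret)
    va_draws = np.zeros((n_ret, 2))
    kept = 0

    for sweep in range(chain.n_iter):
        for j, tr in enumerate(traits):
            other = traits[1 - j]
            y, X, ai = tr["y"], tr["X"], tr["ai"]

            contrib = tr["a"][ai]
            for t, (idx, _, _) in tr["blocks"].items():
                contrib = contrib + tr["u"][t][idx]

            # fixed effects
            r = y - contrib
            mu = scipy.linalg.cho_solve(tr["XtX_cho"], X.T @ r)
            z = rng.standard_normal(tr["p"])
            tr["beta"] = mu + math.sqrt(tr["sig_e"]) * scipy.linalg.solve_triangular(
                tr["L_x"].T, z, lower=False
            )
            xb = X @ tr["beta"]

            # breeding values: conditional prior w_j | w_other
            gjj, goo = G[j, j], G[1 - j, 1 - j]
            gjo = G[j, 1 - j]
            g_cond = gjj - gjo**2 / goo
            prior_mean_w = (gjo / goo) * other["w"]
            r = y - xb
            for t, (idx, _, _) in tr["blocks"].items():
                r -= tr["u"][t][idx]
            h = np.bincount(ai, weights=r, minlength=n_ped)
            prec = tr["lam"] / tr["sig_e"] + 1.0 / g_cond
            mean = (tr["B"].T @ h) / tr["sig_e"] + (tr["U"].T @ prior_mean_w) / g_cond
            mean = mean / prec
            v = mean + rng.standard_normal(n_ped) / np.sqrt(prec)
            tr["w"] = tr["U"] @ v
            tr["a"] = L @ tr["w"]

            # diagonal random terms and residual
            for t, (idx, cnt, q) in tr["blocks"].items():
                r = y - xb - tr["a"][ai]
                for t2, (idx2, _, _) in tr["blocks"].items():
                    if t2 != t:
                        r -= tr["u"][t2][idx2]
                ssum = np.bincount(idx, weights=r, minlength=q)
                prec_u = cnt / tr["sig_e"] + 1.0 / tr["sig"][t]
                mean_u = (ssum / tr["sig_e"]) / prec_u
                tr["u"][t] = mean_u + rng.standard_normal(q) / np.sqrt(prec_u)
                S = float(tr["u"][t] @ tr["u"][t])
                tr["sig"][t] = _draw_invgamma(
                    rng, (prior.nu + q) / 2.0, (prior.nu * prior.V + S) / 2.0
                )
            e = y - xb - tr["a"][ai]
            for t, (idx, _, _) in tr["blocks"].items():
                e -= tr["u"][t][idx]
            tr["sig_e"] = _draw_invgamma(
                rng, (prior.nu + tr["N"]) / 2.0,
                (prior.nu * prior.V + float(e @ e)) / 2.0,
            )

        # genetic covariance matrix
        W = np.column_stack([traits[0]["w"], traits[1]["w"]])
        S = W.T @ W
        G = scipy.stats.invwishart.rvs(
            df=nu_g + n_ped, scale=nu_g * np.eye(2) + S, random_state=rng
        )
        if not np.all(np.isfinite(G)):
            raise ModelError(f"divergent chain at sweep {sweep}")

        if sweep >= chain.burn_in and (sweep - chain.burn_in) % chain.thin == 0:
            if kept < n_ret:
                rg_draws[kept] = G[0, 1] / math.sqrt(G[0, 0] * G[1, 1])
                va_draws[kept] = [G[0, 0], G[1, 1]]
                kept += 1

    rg = rg_draws[:kept]
    mode = posterior_mode(rg)
    # equal-tailed quantile interval: more stable than an empirical HDI at
    # the effective sample sizes of this slow-mixing chain
    lo, hi = np.quantile(rg, [0.025, 0.975])
    return GeneticCorrelationResult(
        r_G=float(mode),
        interval=(float(lo), float(hi)),
        V_A=(float(va_draws[:kept, 0].mean()), float(va_draws[:kept, 1].mean())),
        rg_draws=rg,
        chain_meta={
            "n_iter": chain.n_iter, "burn_in": chain.burn_in,
            "thin": chain.thin, "seed": seed, "nu_g": nu_g,
        },
    )


def posterior_mode(draws: np.ndarray) -> float:
    """Kernel-density posterior mode (Gaussian kernel, Silverman bandwidth)."""
    draws = np.asarray(draws, dtype=float)
    if np.ptp(draws) < 1e-14:
        return float(draws[0])
    kde = scipy.stats.gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


# ---------------------------------------------------------------------------
# chain diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ComponentDiagnostics:
    stationarity_p: float
    discard_frac: float
    stationary: bool
    autocorr_lag1: float        # nan when undefined (constant chain)

    @property
    def autocorr_ok(self) -> bool:
        return bool(np.isnan(self.autocorr_lag1) or abs(self.autocorr_lag1) < 0.1)


def _pcramer(q: float) -> float:
    """Asymptotic CDF of the Cramer-von Mises statistic (Bessel-K series)."""
    if q <= 0:
        return 0.0
    total = 0.0
    for k in range(4):
        z = (4 * k + 1) ** 2 / (16.0 * q)
        term = (
            scipy.special.gamma(k + 0.5)
            * math.sqrt(4 * k + 1)
            / scipy.special.gamma(k + 1.0)
            * math.exp(-z)
            * scipy.special.kv(0.25, z)
        )
        total += term
    return min(1.0, total / (math.pi ** 1.5 * math.sqrt(q)))


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit."""
    from statsmodels.regression.linear_model import yule_walker

    n = len(x)
    v = float(np.var(x, ddof=1))
    if v <= 0:
        return 0.0
    best = (n * math.log(v), 0, v, None)
    max_order = min(20, n // 10)
    for p in range(1, max_order + 1):
        try:
            rho, sigma = yule_walker(x, order=p, method="mle")
        except Exception:
            continue
        s2 = float(sigma) ** 2
        if s2 <= 0:
            continue
        aic = n * math.log(s2) + 2 * p
        if aic < best[0]:
            best = (aic, p, s2, rho)
    _, p, s2, rho = best
    if p == 0:
        return v
    return s2 / (1.0 - float(np.sum(rho))) ** 2


def heidelberger_welch(x: np.ndarray, alpha: float = 0.05):
    """Stationarity test on cumulative means, discarding up to half the chain.

    The Cramer-von Mises statistic is computed on the Brownian-bridge of the
    chain (normalised by the spectral density at zero, estimated from the
    second half); the initial 10%, 20%, ... 50% are discarded in turn until
    the remainder passes at level ``alpha``.
    Returns ``(p_value, discard_fraction, passed)``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if np.ptp(x) < 1e-14:
        return 1.0, 0.0, True          # constant chain: trivially stationary
    s0 = _spectrum0_ar(x[n // 2:])
    if s0 <= 0:
        s0 = float(np.var(x, ddof=1))
    pval, frac = 0.0, 0.0
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        y = x[int(frac * n):]
        m = len(y)
        b = np.cumsum(y) - y.mean() * np.arange(1, m + 1)
        stat = float(np.sum(b * b) / (m * m * s0))
        pval = 1.0 - _pcramer(stat)
        if pval > alpha:
            return pval, frac, True
    return pval, frac, False


def lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    v = np.var(x)
    if v < 1e-28:
        return float("nan")
    x = x - x.mean()
    return float(np.sum(x[:-1] * x[1:]) / (len(x) * v))


def diagnostics(samples: PosteriorSamples, alpha: float = 0.05) -> dict:
    """Heidelberger-Welch stationarity and lag-1 autocorrelation per component.

    Requires at least 50 retained draws.  A component passes when the
    stationarity p-value exceeds ``alpha`` and the absolute lag-1
    autocorrelation of the retained draws is below 0.1.
    """
    if samples.n_retained < 50:
        raise ModelError("diagnostics require at least 50 retained draws")
    report = {}
    for col in samples.vc_draws.columns:
        x = samples.vc_draws[col].to_numpy()
        if np.ptp(x) < 1e-14 and col in ("V_PE", "V_T") and np.allclose(x, 0):
            continue                   # term not in the model
        p, frac, ok = heidelberger_welch(x, alpha=alpha)
        report[col] = ComponentDiagnostics(
            stationarity_p=float(p),
            discard_frac=float(frac),
            stationary=bool(ok),
            autocorr_lag1=lag1_autocorr(x),
        )
    return report
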