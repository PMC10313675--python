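"""Realised selection intensity and its truncation-selection interpretation.

Under the breeder's equation with repeated records per individual, the
selection intensity implied by an observed rate of genetic improvement is

    i = beta_G * L / (h * sigma_A * sqrt(n / (1 + (n - 1) * R)))

where beta_G is the per-annum genetic trend, L the generation interval in
years, h the square root of the heritability, sigma_A the additive genetic
standard deviation, n the mean number of records per individual and R the
repeatability.  For truncation selection on a normally distributed trait,
an intensity i corresponds to selecting the top fraction p of the
population with i = phi(z)/p, z = Phi^-1(1 - p); inverting that relation
turns a realised intensity into an implied selected proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .pedigree import Pedigree


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SelectionInputs:
    """Ingredients of the realised-intensity formula (speed in yards/s)."""

    beta_G: float          # yards s^-1 year^-1
    L: float               # generation interval, years
    h: float               # sqrt(heritability)
    sigma_A: float         # additive genetic SD, yards/s
    n: float               # mean records per individual
    R: float               # repeatability

    def __post_init__(self) -> None:
        if not (self.L > 0):
            raise SelectionError("generation interval L must be positive")
        if not (0 <= self.h <= 1):
            raise SelectionError("h must lie in [0, 1]")
        if self.sigma_A < 0:
            raise SelectionError("sigma_A must be non-negative")
        if self.n < 1:
            raise SelectionError("mean records per individual must be >= 1")
        if not (0 <= self.R <= 1):
            raise SelectionError("repeatability must lie in [0, 1]")
        if self.h**2 > self.R + 1e-12:
            raise SelectionError("h^2 cannot exceed the repeatability")


@dataclass(frozen=True)
class SelectionResult:
    i: float               # realised selection intensity, SD units
    p_selected: float      # implied proportion selected under truncation


def generation_interval(ped: Pedigree, subset=None) -> float:
    """Mean parental age at offspring birth, over sire and dam pairs jointly.

    ``subset`` restricts the offspring considered (e.g., one distance
    category's horses); pairs with a missing birth year on either side are
    skipped.
    """
    if subset is not None:
        subset = set(map(str, subset))
        offspring = [k for k in range(ped.n) if str(ped.ids[k]) in subset]
    else:
        offspring = range(ped.n)
    ages = []
    for k in offspring:
        if np.isnan(ped.birth_year[k]):
            continue
        for p in (ped.sire[k], ped.dam[k]):
            if p >= 0 and not np.isnan(ped.birth_year[p]):
                ages.append(ped.birth_year[k] - ped.birth_year[p])
    if not ages:
        raise SelectionError("no parent-offspring pairs with known birth years")
    return float(np.mean(ages))


def realised_intensity(inp: SelectionInputs) -> float:
    """i = beta_G * L / (h * sigma_A * sqrt(n / (1 + (n-1) * R)))."""
    denom = inp.h * inp.sigma_A
    if denom <= 0:
        raise SelectionError("h * sigma_A must be positive")
    acc = np.sqrt(inp.n / (1.0 + (inp.n - 1.0) * inp.R))
    return inp.beta_G * inp.L / (denom * acc)


_P_LO, _P_HI = 1e-8, 1.0 - 1e-8


def proportion_to_intensity(p: float) -> float:
    """Truncation-selection intensity i = phi(Phi^-1(1-p)) / p."""
    if not (0 < p < 1):
        raise SelectionError("selected proportion must lie in (0, 1)")
    z = norm.ppf(1.0 - p)
    return float(norm.pdf(z) / p)


def intensity_to_proportion(i: float) -> float:
    """Selected proportion implied by intensity i (bracketed root-finding).

    Solves ``i = phi(Phi^-1(1-p)) / p`` for p on (1e-8, 1-1e-8) to 1e-10.
    """
    if i <= 0:
        raise SelectionError("selection intensity must be positive")
    i_max = proportion_to_intensity(_P_LO)
    i_min = proportion_to_intensity(_P_HI)
    if i >= i_max or i <= i_min:
        raise SelectionError(
            f"intensity {i} outside the attainable range ({i_min:.3g}, {i_max:.3g})"
        )
    return float(brentq(
        lambda p: proportion_to_intensity(p) - i, _P_LO, _P_HI, xtol=1e-10
    ))


def realised_selection(inp: SelectionInputs) -> SelectionResult:
    """Intensity plus its implied truncation-selection proportion."""
    i = realised_intensity(inp)
    p = intensity_to_proportion(i) if i > 0 else 1.0
    return SelectionResult(i=i, p_selected=p)
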