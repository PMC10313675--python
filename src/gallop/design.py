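"""Fixed- and random-effect design construction for the two model structures.

Model A conditions on race identity directly (raceID + age + sex as fixed
factors); Model B replaces the raceID factor with race-level covariates
(year, timing method and racecourse factors; quadratics in distance, field
size and going; distance x year, distance x going, distance x field-size and
distance^2 x year interactions) so that Bayesian fitting stays tractable.
Both share the random structure: additive genetic merit (pedigree), permanent
environment (horse identity) and trainer identity.

Factors use reference-level coding (alphabetically first level dropped);
continuous covariates are centred and scaled to unit variance before
polynomials and interactions are formed, and the centring constants are kept
with the column labels so effects can be mapped back to the raw scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

RANDOM_TERMS = ("animal", "pe", "trainer")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Named fixed-effect structure; the random terms are shared."""

    name: str
    factors: tuple[str, ...]
    covariate_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = RANDOM_TERMS

    @classmethod
    def model_a(cls) -> "ModelSpec":
        return cls(name="A", factors=("race_id", "age_class", "sex"))

    @classmethod
    def model_b(cls) -> "ModelSpec":
        return cls(
            name="B",
            factors=("year", "timing", "racecourse", "age_class", "sex"),
            covariate_terms=(
                "distance", "distance^2",
                "n_runners", "n_runners^2",
                "going", "going^2",
                "distance:year_c", "distance:going", "distance:n_runners",
                "distance^2:year_c",
            ),
        )

    @classmethod
    def by_name(cls, name: str) -> "ModelSpec":
        name = name.upper()
        if name == "A":
            return cls.model_a()
        if name == "B":
            return cls.model_b()
        raise DesignError(f"unknown model spec {name!r}")


@dataclass
class DesignMatrices:
    """Response, fixed design and record->level maps for the random terms."""

    y: np.ndarray                       # speed, yards/s
    X: np.ndarray                       # dense fixed design, full column rank
    x_labels: list[str]
    term_index: dict[str, np.ndarray]   # random term -> record-level index
    term_levels: dict[str, np.ndarray]  # random term -> level identifiers
    ped: Pedigree
    transforms: dict[str, tuple[float, float]] = field(default_factory=dict)
    spec_name: str = ""

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


def _factor_columns(values: pd.Series, name: str):
    """Reference-coded dummies; alphabetically first level is the reference."""
    levels = sorted(map(str, pd.unique(values.astype(str))))
    if len(levels) < 2:
        return None, levels
    codes = pd.Categorical(values.astype(str), categories=levels).codes
    cols = np.zeros((len(values), len(levels) - 1))
    for j in range(1, len(levels)):
        cols[codes == j, j - 1] = 1.0
    labels = [f"{name}[{lev}]" for lev in levels[1:]]
    return (cols, labels), levels


def build_design(
    records: pd.DataFrame, spec: ModelSpec, ped: Pedigree
) -> DesignMatrices:
    """Assemble y, X and the random-effect index maps for one model.

    Degenerate factors (a single level) are dropped with a warning; columns
    made collinear by the data are removed by pivoted QR, also logged.
    """
    records = records.reset_index(drop=True)
    if "age_class" not in records.columns:
        from .records import collapse_age

        records = records.assign(age_class=collapse_age(records["age"].to_numpy()))
    missing = [h for h in records["horse"].unique() if str(h) not in ped]
    if missing:
        raise DesignError(
            f"record horses absent from pedigree: {sorted(missing)[:10]}"
        )

    y = records["speed"].to_numpy(dtype=float)
    n = len(y)
    blocks = [np.ones((n, 1))]
    labels = ["intercept"]
    transforms: dict[str, tuple[float, float]] = {}

    for fac in spec.factors:
        built, levels = _factor_columns(records[fac], fac)
        if built is None:
            logger.warning("factor %r has a single level (%r); dropped", fac,
                           levels[0] if levels else None)
            continue
        cols, labs = built
        blocks.append(cols)
        labels.extend(labs)

    if spec.covariate_terms:
        std: dict[str, np.ndarray] = {}
        for base in ("distance", "n_runners", "going"):
            raw = records[base].to_numpy(dtype=float)
            mu, sd = float(raw.mean()), float(raw.std())
            sd = sd if sd > 0 else 1.0
            std[base] = (raw - mu) / sd
            transforms[base] = (mu, sd)
        raw_year = records["year"].to_numpy(dtype=float)
        mu, sd = float(raw_year.mean()), float(raw_year.std())
        sd = sd if sd > 0 else 1.0
        std["year_c"] = (raw_year - mu) / sd
        transforms["year_c"] = (mu, sd)

        def term_values(term: str) -> np.ndarray:
            parts = term.split(":")
            out = np.ones(n)
            for p in parts:
                if p.endswith("^2"):
                    out = out * std[p[:-2]] ** 2
                else:
                    out = out * std[p]
            return out

        for term in spec.covariate_terms:
            blocks.append(term_values(term)[:, None])
            labels.append(term)

    X = np.hstack(blocks)
    if X.shape[1] == 0:
        raise DesignError("empty fixed-effect design")

    X, labels = _drop_rank_deficient(X, labels)

    # random-term maps
    animal_idx = ped.positions(records["horse"].astype(str))
    horses = np.array(sorted(records["horse"].astype(str).unique()), dtype=object)
    horse_pos = {h: k for k, h in enumerate(horses)}
    pe_idx = np.array([horse_pos[h] for h in records["horse"].astype(str)])
    trainers = np.array(sorted(records["trainer"].astype(str).unique()), dtype=object)
    tr_pos = {t: k for k, t in enumerate(trainers)}
    t_idx = np.array([tr_pos[t] for t in records["trainer"].astype(str)])

    return DesignMatrices(
        y=y,
        X=X,
        x_labels=labels,
        term_index={"animal": animal_idx, "pe": pe_idx, "trainer": t_idx},
        term_levels={"animal": ped.ids.copy(), "pe": horses, "trainer": trainers},
        ped=ped,
        transforms=transforms,
        spec_name=spec.name,
    )


def _drop_rank_deficient(X: np.ndarray, labels: list[str]):
    """Remove linearly dependent columns via pivoted QR (logged)."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dropped = sorted(piv[rank:])
        logger.warning(
            "dropping %d collinear fixed-effect columns: %s",
            len(dropped), [labels[j] for j in dropped],
        )
        keep = sorted(piv[:rank])
        X = X[:, keep]
        labels = [labels[j] for j in keep]
    return X, labels
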