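"""Trait coding, model configuration, and design-matrix construction.

Two codings of the angular hoof defects are supported: model A scores each
defect 0/1/2 (absent / minor / severe), model B collapses 1 and 2 into a
single "present" class.  SDFT (tendon diameter, 1-9) is Gaussian by default
with an ordinal option; the proportionality index PI is continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "TraitSpec",
    "ModelConfig",
    "DesignMatrices",
    "model_a_trait",
    "model_b_trait",
    "gaussian_trait",
    "ordinal_trait",
    "recode_modelA_to_modelB",
    "build_design",
    "read_phenotypes_csv",
]

DEFECTS = ("SFF", "PTF", "SFR", "PTR")


@dataclass(frozen=True)
class TraitSpec:
    """One analysed trait: ordinal with K consecutive categories starting at
    ``first_category``, or Gaussian."""

    name: str
    kind: str  # "ordinal" | "gaussian"
    n_categories: int = 0
    first_category: int = 0

    def __post_init__(self):
        if self.kind not in ("ordinal", "gaussian"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ordinal" and self.n_categories < 2:
            raise ValueError("ordinal traits need at least 2 categories")

    @property
    def categories(self) -> np.ndarray:
        return np.arange(self.first_category, self.first_category + self.n_categories)


def model_a_trait(name: str) -> TraitSpec:
    """0/1/2 defect scale (absent, minor, severe)."""
    return TraitSpec(name, "ordinal", 3, 0)


def model_b_trait(name: str) -> TraitSpec:
    """Dichotomous absent/present scale."""
    return TraitSpec(name, "ordinal", 2, 0)


def ordinal_trait(name: str, n_categories: int, first_category: int = 0) -> TraitSpec:
    return TraitSpec(name, "ordinal", n_categories, first_category)


def gaussian_trait(name: str) -> TraitSpec:
    return TraitSpec(name, "gaussian")


@dataclass(frozen=True)
class ModelConfig:
    """Model + sampler configuration shared by the simulator and the fitter.

    ``prior_df_g``/``prior_df_r`` default to ``n_traits + 2`` (weakly
    informative, proper); prior scale matrices are ``prior_scale_g * I`` and
    ``prior_scale_r * I``.
    """

    traits: tuple[TraitSpec, ...]
    fixed_effects: tuple[str, ...] = ("sex", "stud_size")
    covariates: tuple[str, ...] = ("age", "F")
    intercept: bool = True
    prior_df_g: float | None = None
    prior_scale_g: float = 0.2
    prior_df_r: float | None = None
    prior_scale_r: float = 0.8
    n_iter: int = 100_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    store_u: bool = False
    age_range: tuple[float, float] = (2.0, 23.0)

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        T = len(self.traits)
        for df, what in ((self.df_g, "G"), (self.df_r, "R")):
            if df <= T + 1:
                raise ValueError(f"prior df for {what} must exceed n_traits+1")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def df_g(self) -> float:
        return self.prior_df_g if self.prior_df_g is not None else self.n_traits + 2

    @property
    def df_r(self) -> float:
        return self.prior_df_r if self.prior_df_r is not None else self.n_traits + 2

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


def recode_modelA_to_modelB(scores) -> np.ndarray:
    """Collapse 0/1/2 defect scores to 0/1 (classes 1 and 2 joined).

    Missing values (NaN) are preserved.  Out-of-range scores raise.
    """
    arr = np.asarray(scores, dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        bad = arr[~ok][0]
        raise ValueError(f"score {bad!r} outside {{0,1,2,missing}}")
    out = arr.copy()
    out[arr >= 1.0] = 1.0
    return out


@dataclass(frozen=True)
class DesignMatrices:
    """Per-record design bundle consumed by the Gibbs sampler.

    ``X`` is shared by all traits (the study fits the same sex, stud-size,
    age and inbreeding terms to every trait); trait-wise missingness lives
    in ``observed``.  ``animal`` maps each record row to its pedigree index.
    """

    X: np.ndarray  # (n_records, p) fixed effects + centred covariates
    columns: tuple[str, ...]
    Y: np.ndarray  # (n_records, n_traits) float, NaN where missing
    observed: np.ndarray  # (n_records, n_traits) bool
    animal: np.ndarray  # (n_records,) pedigree indices
    traits: tuple[TraitSpec, ...]
    ids: np.ndarray  # external ids, record order
    covariate_means: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_effects(self) -> int:
        return self.X.shape[1]


_LEVEL_ORDER = {
    "sex": ["female", "male"],
    "stud_size": ["small", "medium", "large"],
}


def build_design(phen: pd.DataFrame, cfg: ModelConfig, ped) -> DesignMatrices:
    """Assemble full-rank fixed-effect design and per-trait responses.

    The reference level of each categorical effect is dropped (female and
    small stud by convention); covariates are centred.  Levels that are
    empty, or effects left with a single level, are dropped with a logged
    warning.  Every phenotyped animal must appear in the pedigree.
    """
    ids = phen["id"].astype(str).to_numpy()
    missing_ids = [a for a in ids if a not in ped._index]
    if missing_ids:
        raise ValueError(
            f"{len(missing_ids)} phenotyped animal(s) absent from pedigree: "
            f"{missing_ids[:10]}"
        )
    animal = np.array([ped.index_of(a) for a in ids], dtype=np.int64)

    cols: list[np.ndarray] = []
    names: list[str] = []
    if cfg.intercept:
        cols.append(np.ones(len(phen)))
        names.append("intercept")
    for eff in cfg.fixed_effects:
        levels = [str(v) for v in phen[eff]]
        order = _LEVEL_ORDER.get(eff)
        present = list(dict.fromkeys(levels))
        if order is not None:
            ordered = [lv for lv in order if lv in present]
            ordered += [lv for lv in present if lv not in order]
        else:
            ordered = sorted(present)
        if len(ordered) < 2:
            log.warning("fixed effect %r has a single level; dropped", eff)
            continue
        ref = ordered[0]
        for lv in ordered[1:]:
            cols.append(np.asarray([1.0 if v == lv else 0.0 for v in levels]))
            names.append(f"{eff}[{lv}]")
        log.debug("effect %r: reference level %r", eff, ref)
    cov_means: dict[str, float] = {}
    for cov in cfg.covariates:
        v = phen[cov].astype(float).to_numpy()
        if np.isnan(v).any():
            raise ValueError(f"covariate {cov!r} has missing values")
        m = float(v.mean())
        cov_means[cov] = m
        centred = v - m
        if np.allclose(centred, 0.0):
            log.warning("covariate %r is constant; dropped", cov)
            continue
        cols.append(centred)
        names.append(cov)
    X = np.column_stack(cols) if cols else np.zeros((len(phen), 0))
    if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")

    T = len(cfg.traits)
    Y = np.full((len(phen), T), np.nan)
    for k, tr in enumerate(cfg.traits):
        col = phen[tr.name].astype(float).to_numpy()
        obs = ~np.isnan(col)
        if tr.kind == "ordinal":
            valid = np.isin(col[obs], tr.categories.astype(float))
            if not valid.all():
                bad = col[obs][~valid][0]
                raise ValueError(
                    f"trait {tr.name!r}: score {bad} outside categories "
                    f"{tr.categories.tolist()}"
                )
        Y[:, k] = col
    observed = ~np.isnan(Y)
    return DesignMatrices(
        X=X,
        columns=tuple(names),
        Y=Y,
        observed=observed,
        animal=animal,
        traits=tuple(cfg.traits),
        ids=ids,
        covariate_means=cov_means,
    )


def read_phenotypes_csv(path) -> pd.DataFrame:
    """Phenotype CSV ``id,sex,stud_size,age,F,<trait columns...>`` with
    empty cells for missing scores."""
    df = pd.read_csv(path)
    df["id"] = df["id"].astype(str)
    return df
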