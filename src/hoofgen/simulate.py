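"""Synthetic pedigreed populations with known genetic parameters.

Emulates the structure of the studbook data behind the hoof-deviation
analysis: a multi-generation pedigree (non-overlapping generations, mating
within the previous generation), six traits with additive-genetic covariance
realised by gene dropping, fixed effects of sex and birth-stud size, linear
age and inbreeding covariates, ordinal phenotypes produced by thresholding
Gaussian liabilities, and trait-wise missingness mirroring the unequal
record counts of the real data.  Every other module is testable against the
stored ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import pedigree as pdg
from .model import TraitSpec, model_a_trait, model_b_trait, gaussian_trait

__all__ = [
    "SimTrait",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_pedigree",
    "gene_drop",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
    "read_truth",
    "study_defaults",
    "two_trait_recovery_config",
]


@dataclass(frozen=True)
class SimTrait:
    """True generative parameters for one trait.

    For ordinal traits the residual (environmental) liability variance is 1
    (the identified scale), so the true liability heritability is exactly
    ``genetic_variance / (genetic_variance + 1)``.  ``target_frequencies``
    (category shares, summing to 1), when given, override ``thresholds``:
    cutpoints are calibrated from the realised liability mean and s.d. by
    the normal inverse CDF.
    """

    spec: TraitSpec
    genetic_variance: float
    residual_variance: float = 1.0
    intercept: float = 0.0
    sex_effect: float = 0.0  # male minus female, on the liability scale
    stud_effects: tuple = (0.0, 0.0, 0.0)  # small, medium, large
    slope_age: float = 0.0
    slope_inbreeding: float = 0.0
    thresholds: tuple | None = None  # interior cutpoints, increasing
    target_frequencies: tuple | None = None
    missing_rate: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Population structure + true parameters of a synthetic study."""

    traits: tuple[SimTrait, ...]
    genetic_correlations: tuple = ()  # ((name_i, name_j, r), ...)
    n_founders: int = 80
    n_generations: int = 5
    n_per_generation: int = 400
    mating: str = "random"  # random | assortative_stud | full_sib_line
    n_studs: int = 10
    within_stud_prob: float = 0.8
    prob_male: float = 0.331  # study sex ratio: 16,920 / 51,134
    age_gamma_shape: float = 1.615  # shifted gamma: mean 4.86 y, s.d. 2.25
    age_gamma_scale: float = 1.771
    age_min: float = 2.0
    age_max: float = 23.0
    first_birth_year: int = 2000
    years_per_generation: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_generations < 1:
            raise ValueError("need at least one generation")
        G = self.true_G()
        np.linalg.cholesky(G)  # true G must be PD

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def trait_names(self) -> list[str]:
        return [t.spec.name for t in self.traits]

    def true_G(self) -> np.ndarray:
        names = self.trait_names()
        sd = np.sqrt([t.genetic_variance for t in self.traits])
        C = np.eye(self.n_traits)
        for ni, nj, r in self.genetic_correlations:
            i, j = names.index(ni), names.index(nj)
            C[i, j] = C[j, i] = r
        return C * np.outer(sd, sd)

    def true_R(self) -> np.ndarray:
        return np.diag([t.residual_variance for t in self.traits])

    def true_h2(self) -> dict:
        return {
            t.spec.name: t.genetic_variance
            / (t.genetic_variance + t.residual_variance)
            for t in self.traits
        }


@dataclass
class SyntheticDataset:
    pedigree: pdg.Pedigree
    u_true: np.ndarray  # (n_animals, n_traits) true breeding values
    phenotypes: pd.DataFrame
    config: SimulationConfig
    truth: dict = field(default_factory=dict)


def simulate_pedigree(cfg: SimulationConfig, rng=None) -> pdg.Pedigree:
    """Non-overlapping-generation pedigree; parents sampled from the
    previous generation.

    ``assortative_stud`` keeps most matings within a stud (raising
    inbreeding over generations); ``full_sib_line`` chains full-sib matings
    to reach high inbreeding.  Stud membership follows the sire.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ids, sires, dams, sexes, years, studs = [], [], [], [], [], []

    def add(animal_sire, animal_dam, gen, stud):
        i = len(ids)
        ids.append(f"H{i + 1:06d}")
        sires.append(animal_sire)
        dams.append(animal_dam)
        sexes.append("male" if rng.random() < cfg.prob_male else "female")
        years.append(cfg.first_birth_year + gen * cfg.years_per_generation
                     + int(rng.integers(cfg.years_per_generation)))
        studs.append(stud)
        return i

    for _ in range(cfg.n_founders):
        add(-1, -1, 0, int(rng.integers(cfg.n_studs)))
    prev = list(range(cfg.n_founders))
    for gen in range(1, cfg.n_generations):
        males = [i for i in prev if sexes[i] == "male"]
        females = [i for i in prev if sexes[i] == "female"]
        if not males or not females:  # degenerate draw: re-sex two animals
            sexes[prev[0]], sexes[prev[-1]] = "male", "female"
            males = [i for i in prev if sexes[i] == "male"]
            females = [i for i in prev if sexes[i] == "female"]
        cur = []
        if cfg.mating == "full_sib_line":
            # one full-sib pair per generation plus outbred fill
            s, d = males[0], females[0]
            boy = add(s, d, gen, studs[s])
            girl = add(s, d, gen, studs[s])
            sexes[boy], sexes[girl] = "male", "female"
            cur += [boy, girl]
            while len(cur) < cfg.n_per_generation:
                s = males[int(rng.integers(len(males)))]
                d = females[int(rng.integers(len(females)))]
                cur.append(add(s, d, gen, studs[s]))
        else:
            by_stud_m: dict[int, list] = {}
            by_stud_f: dict[int, list] = {}
            for i in males:
                by_stud_m.setdefault(studs[i], []).append(i)
            for i in females:
                by_stud_f.setdefault(studs[i], []).append(i)
            for _ in range(cfg.n_per_generation):
                s = males[int(rng.integers(len(males)))]
                if (
                    cfg.mating == "assortative_stud"
                    and rng.random() < cfg.within_stud_prob
                    and by_stud_f.get(studs[s])
                ):
                    pool = by_stud_f[studs[s]]
                    d = pool[int(rng.integers(len(pool)))]
                else:
                    d = females[int(rng.integers(len(females)))]
                cur.append(add(s, d, gen, studs[s]))
        prev = cur

    n = len(ids)
    ped = pdg.Pedigree(
        ids=np.array(ids, dtype=object),
        sire=np.array(sires, dtype=np.int64),
        dam=np.array(dams, dtype=np.int64),
        birth_year=np.array(years, dtype=np.int64),
        sex=np.array(sexes, dtype=object),
    )
    # stud bookkeeping rides along for phenotype simulation
    object.__setattr__(ped, "_stud", np.array(studs, dtype=np.int64))
    assert n == ped.n
    return ped


def gene_drop(ped: pdg.Pedigree, true_G: np.ndarray, rng) -> np.ndarray:
    """Drop breeding values through the pedigree.

    Founders are drawn from N(0, G); offspring get the parent average plus a
    Mendelian-sampling deviation with covariance ``d_i * G`` where ``d_i``
    is 0.5 - 0.25 (F_s + F_d) (the one-/no-known-parent analogues included),
    so Var(u_i) = (1 + F_i) * G_ii holds by construction.
    """
    true_G = np.atleast_2d(np.asarray(true_G, dtype=float))
    T = true_G.shape[0]
    F = pdg.inbreeding(ped)
    d = pdg.mendelian_sampling_variance(ped, F)
    cholG = np.linalg.cholesky(true_G)
    z = rng.standard_normal((ped.n, T))
    u = np.zeros((ped.n, T))
    for i in range(ped.n):
        m = np.sqrt(d[i]) * (cholG @ z[i])
        s, dm = ped.sire[i], ped.dam[i]
        pa = np.zeros(T)
        if s != pdg.UNKNOWN:
            pa += 0.5 * u[s]
        if dm != pdg.UNKNOWN:
            pa += 0.5 * u[dm]
        u[i] = pa + m
    return u


def _calibrated_cuts(tr: SimTrait, liab: np.ndarray) -> np.ndarray:
    """Interior cutpoints for one ordinal trait.

    With target frequencies: normal-inverse-CDF calibration on the realised
    liability mean/s.d. (an approximation, so realised prevalences match
    targets only up to the normality of the liability mixture).
    """
    from scipy.special import ndtri

    K = tr.spec.n_categories
    if tr.target_frequencies is not None:
        f = np.asarray(tr.target_frequencies, dtype=float)
        if f.size != K or not np.isclose(f.sum(), 1.0, atol=1e-3):
            raise ValueError(
                f"trait {tr.spec.name!r}: target frequencies must be {K} "
                "shares summing to 1"
            )
        cum = np.clip(np.cumsum(f)[:-1], 1e-9, 1 - 1e-9)
        return liab.mean() + liab.std() * ndtri(cum)
    if tr.thresholds is not None:
        t = np.asarray(tr.thresholds, dtype=float)
        if t.size != K - 1 or np.any(np.diff(t) <= 0):
            raise ValueError(
                f"trait {tr.spec.name!r}: need {K - 1} increasing thresholds"
            )
        return t
    return ndtri(np.linspace(0, 1, K + 1)[1:-1])  # equal shares fallback


def simulate_phenotypes(
    ped: pdg.Pedigree,
    u_true: np.ndarray,
    cfg: SimulationConfig,
    rng=None,
) -> tuple[pd.DataFrame, dict]:
    """Phenotype every animal: liabilities ``l = Xb + u + e`` thresholded to
    categories for ordinal traits, emitted directly for Gaussian traits,
    then trait-wise missingness applied.

    Returns the phenotype table and the realised truth record (cutpoints
    actually used, covariate means, etc.).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = ped.n
    F = pdg.inbreeding(ped)
    age = cfg.age_min + rng.gamma(cfg.age_gamma_shape, cfg.age_gamma_scale, n)
    age = np.clip(age, cfg.age_min, cfg.age_max)
    sex = ped.sex if ped.sex is not None else np.where(
        rng.random(n) < cfg.prob_male, "male", "female"
    )
    stud = getattr(ped, "_stud", None)
    if stud is None:
        stud = rng.integers(cfg.n_studs, size=n)
    # stud size class from stud census (thirds of the stud-size distribution)
    census = pd.Series(stud).value_counts()
    qs = census.quantile([1 / 3, 2 / 3]).to_numpy()
    size_of = {
        s: ("small" if c <= qs[0] else "medium" if c <= qs[1] else "large")
        for s, c in census.items()
    }
    stud_size = np.array([size_of[s] for s in stud], dtype=object)
    stud_level = {"small": 0, "medium": 1, "large": 2}

    R = cfg.true_R()
    e = rng.standard_normal((n, cfg.n_traits)) * np.sqrt(np.diag(R))
    is_male = (np.asarray(sex) == "male").astype(float)
    cols = {"id": ped.ids, "sex": sex, "stud_size": stud_size,
            "age": np.round(age, 2), "F": F}
    if ped.birth_year is not None:
        cols["birth_year"] = ped.birth_year
    truth_cuts = {}
    for k, tr in enumerate(cfg.traits):
        stud_eff = np.array(
            [tr.stud_effects[stud_level[sz]] for sz in stud_size]
        )
        eta = (
            tr.intercept
            + tr.sex_effect * is_male
            + stud_eff
            + tr.slope_age * (age - age.mean())
            + tr.slope_inbreeding * (F - F.mean())
        )
        liab = eta + u_true[:, k] + e[:, k]
        if tr.spec.kind == "gaussian":
            score = liab
        else:
            cuts = _calibrated_cuts(tr, liab)
            truth_cuts[tr.spec.name] = [float(c) for c in cuts]
            score = np.digitize(liab, cuts).astype(float) + tr.spec.first_category
        if tr.missing_rate > 0:
            score = np.where(rng.random(n) < tr.missing_rate, np.nan, score)
        cols[tr.spec.name] = score
    phen = pd.DataFrame(cols)
    truth = {
        "G": cfg.true_G().tolist(),
        "R": cfg.true_R().tolist(),
        "h2": cfg.true_h2(),
        "cutpoints": truth_cuts,
        "trait_names": cfg.trait_names(),
        "seed": cfg.seed,
    }
    return phen, truth


def simulate_dataset(cfg: SimulationConfig, seed: int | None = None) -> SyntheticDataset:
    """Full pipeline: pedigree -> gene drop -> phenotypes, with ground truth."""
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    u = gene_drop(ped, cfg.true_G(), rng)
    phen, truth = simulate_phenotypes(ped, u, cfg, rng)
    return SyntheticDataset(ped, u, phen, cfg, truth)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Emit pedigree CSV, phenotype CSV and a JSON truth file; returns the
    paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped = ds.pedigree
    ped_df = pd.DataFrame(
        {
            "id": ped.ids,
            "sire": [ped.ids[s] if s != pdg.UNKNOWN else "0" for s in ped.sire],
            "dam": [ped.ids[d] if d != pdg.UNKNOWN else "0" for d in ped.dam],
        }
    )
    if ped.birth_year is not None:
        ped_df["birth_year"] = ped.birth_year
    if ped.sex is not None:
        ped_df["sex"] = ped.sex
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    ped_df.to_csv(paths["pedigree"], index=False)
    ds.phenotypes.to_csv(paths["phenotypes"], index=False)
    truth = dict(ds.truth)
    truth["u_true_mean_by_trait"] = ds.u_true.mean(axis=0).tolist()
    truth["config"] = {
        k: v for k, v in asdict(ds.config).items() if not isinstance(v, tuple)
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return paths


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# -- canned configurations --------------------------------------------------


def study_defaults(
    n_founders: int = 400,
    n_generations: int = 5,
    n_per_generation: int = 1000,
    seed: int = 0,
) -> SimulationConfig:
    """Six-trait configuration mirroring the published study.

    Category shares, heritabilities, genetic correlations, record
    missingness, sex ratio and age distribution follow the printed
    descriptives: e.g. SFF shares (73.39, 20.61, 5.99)%, h2 0.18; SDFT
    Gaussian with mean 4.87, s.d. 1.083, h2 0.076; PI mean 99.80, s.d.
    2.379, h2 0.348.  Genetic correlations not printed (SFF-PTF, SFR-PTR,
    SDFT-PI) default to 0.  Covariate slopes and level effects are modest
    liability-scale values (the published slope units are software-scale
    conventions and do not transfer to the identified liability scale).
    """

    def defect(name, h2, freqs, miss, sex_eff, slope_age, slope_f):
        return SimTrait(
            spec=model_a_trait(name),
            genetic_variance=h2 / (1 - h2),
            residual_variance=1.0,
            sex_effect=sex_eff,
            stud_effects=(0.0, 0.03, 0.06),
            slope_age=slope_age,
            slope_inbreeding=slope_f,
            target_frequencies=freqs,
            missing_rate=miss,
        )

    traits = (
        defect("SFF", 0.18, (0.7339, 0.2061, 0.0600), 1 - 41614 / 51134,
               0.20, -0.010, 0.4),
        defect("PTF", 0.20, (0.7624, 0.0073, 0.2303), 1 - 40061 / 51134,
               -0.17, 0.015, 0.5),
        defect("SFR", 0.11, (0.2047, 0.5389, 0.2564), 1 - 50717 / 51134,
               0.01, -0.005, 0.6),
        defect("PTR", 0.31, (0.9614, 0.0316, 0.0070), 1 - 10797 / 51134,
               0.05, 0.002, 0.2),
        SimTrait(
            spec=gaussian_trait("SDFT"),
            genetic_variance=0.076 * 1.083**2,
            residual_variance=(1 - 0.076) * 1.083**2,
            intercept=4.87,
            missing_rate=0.05,
        ),
        SimTrait(
            spec=gaussian_trait("PI"),
            genetic_variance=0.348 * 2.379**2,
            residual_variance=(1 - 0.348) * 2.379**2,
            intercept=99.80,
            missing_rate=0.05,
        ),
    )
    correlations = (
        ("SFF", "PTR", 0.09),
        ("SFF", "SFR", 0.09),
        ("PTF", "PTR", 0.27),
        ("PTF", "SFR", -0.31),
        ("SFF", "SDFT", -0.081),
        ("PTF", "SDFT", 0.283),
        ("SFR", "SDFT", -0.113),
        ("PTR", "SDFT", 0.276),
        ("SFF", "PI", 0.212),
        ("PTF", "PI", -0.034),
        ("SFR", "PI", 0.124),
        ("PTR", "PI", -0.088),
    )
    return SimulationConfig(
        traits=traits,
        genetic_correlations=correlations,
        n_founders=n_founders,
        n_generations=n_generations,
        n_per_generation=n_per_generation,
        mating="assortative_stud",
        seed=seed,
    )


def two_trait_recovery_config(
    seed: int = 0,
    n_founders: int = 80,
    n_generations: int = 5,
    n_per_generation: int = 480,
) -> SimulationConfig:
    """Two-trait parameter-recovery setting: one binary defect (true
    liability h2 = 0.3) and one Gaussian trait (h2 = 0.4), genetic
    correlation 0.3, ~2,000 animals over 5 generations."""
    traits = (
        SimTrait(
            spec=model_b_trait("DEFECT"),
            genetic_variance=0.3 / 0.7,
            residual_variance=1.0,
            sex_effect=0.2,
            stud_effects=(0.0, 0.05, 0.10),
            slope_age=0.02,
            slope_inbreeding=0.5,
            thresholds=(0.0,),
        ),
        SimTrait(
            spec=gaussian_trait("INDEX"),
            genetic_variance=0.4,
            residual_variance=0.6,
            sex_effect=-0.1,
            stud_effects=(0.0, 0.05, 0.10),
            slope_age=0.01,
            slope_inbreeding=0.3,
        ),
    )
    return SimulationConfig(
        traits=traits,
        genetic_correlations=(("DEFECT", "INDEX", 0.3),),
        n_founders=n_founders,
        n_generations=n_generations,
        n_per_generation=n_per_generation,
        mating="assortative_stud",
        seed=seed,
    )
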