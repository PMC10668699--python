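"""Multi-trait Bayesian threshold animal model, estimated by Gibbs sampling.

Model per trait k and animal i (on the liability scale for ordinal traits):

    l_ik = x_i' b_k + u_ik + e_ik,      u ~ N(0, G (x) A),   e_i ~ N(0, R)

with ``A`` the numerator relationship matrix, ``G`` the additive-genetic and
``R`` the residual covariance across traits.  Ordinal scores arise by cutting
l at ordered thresholds; Gaussian traits are observed directly.

The sampler augments latent liabilities (including liabilities for
trait-wise missing cells, which keeps the R update conjugate), then cycles

    liabilities -> location (b, u) -> thresholds -> G -> R

with inverse-Wishart full conditionals for G and R and truncated-normal
draws for liabilities.  Identification of ordinal traits: the first
threshold is fixed at 0 and the trait's residual variance is rescaled to 1
at the end of every iteration (rescaling liabilities, u, b, thresholds and
the G/R rows and columns consistently); heritabilities are therefore
reported on the liability scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import ndtr, ndtri

from ._kernels import gauss_seidel_u
from .model import DesignMatrices, ModelConfig

log = logging.getLogger(__name__)

__all__ = ["PosteriorSamples", "ThresholdGibbsSampler", "gibbs_run", "compute_dic"]

_PROB_FLOOR = 1e-12


@dataclass
class PosteriorSamples:
    """Thinned posterior draws plus online accumulations.

    ``G``/``R`` are (S, T, T); ``b`` is (S, p, T); ``thresholds[name]`` holds
    the sampled interior cutpoints of that ordinal trait, (S, K-2).
    ``u_mean`` is the posterior-mean breeding value (EBV) per animal x trait,
    accumulated online over stored draws.  ``deviance`` is the observed-data
    deviance at each stored draw (liabilities integrated out per record),
    used for the DIC.
    """

    G: np.ndarray
    R: np.ndarray
    b: np.ndarray
    thresholds: dict
    deviance: np.ndarray
    u_mean: np.ndarray
    traits: tuple
    columns: tuple
    seed: int
    config: ModelConfig
    u: np.ndarray | None = None
    n_pd_redraws: int = 0

    @property
    def n_draws(self) -> int:
        return self.G.shape[0]

    def trait_index(self, name: str) -> int:
        for k, tr in enumerate(self.traits):
            if tr.name == name:
                return k
        raise KeyError(name)


def _sample_invwishart(rng, df, scale):
    """PD-checked inverse-Wishart draw via the Bartlett decomposition.

    If ``W ~ Wishart(df, scale^-1)`` then ``W^-1 ~ IW(df, scale)``.  Direct
    construction avoids per-draw scipy overhead inside the sampler; the
    scipy distribution serves as the independent cross-check in tests.
    Redraws (never eigenvalue-clips) on numerical PD failure.
    """
    scale = np.atleast_2d(scale)
    p = scale.shape[0]
    M = np.linalg.cholesky(np.linalg.inv(scale))
    for attempt in range(20):
        A = np.zeros((p, p))
        idx = np.tril_indices(p, -1)
        A[idx] = rng.standard_normal(len(idx[0]))
        A[np.diag_indices(p)] = np.sqrt(
            rng.chisquare(df - np.arange(p))
        )
        LA = M @ A  # chol factor of W
        try:
            S = np.linalg.inv(LA @ LA.T)
            np.linalg.cholesky(S)
            return 0.5 * (S + S.T), attempt
        except np.linalg.LinAlgError:  # pragma: no cover - extremely rare
            continue
    raise RuntimeError("could not draw a positive-definite covariance matrix")


class ThresholdGibbsSampler:
    """Gibbs sampler over (liabilities, b, u, thresholds, G, R).

    Deterministic given ``config.seed`` (or an explicitly passed generator).
    Sub-steps are exposed as methods so their full conditionals can be
    validated independently.
    """

    def __init__(
        self,
        design: DesignMatrices,
        a_inv: sparse.spmatrix,
        config: ModelConfig,
        rng: np.random.Generator | None = None,
    ):
        if len(design.traits) != config.n_traits:
            raise ValueError("design and config disagree on the trait list")
        self.design = design
        self.cfg = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.a_inv = a_inv.tocsr()
        self.n_anim = a_inv.shape[0]
        if design.n_records and design.animal.max() >= self.n_anim:
            raise ValueError("record refers to an animal outside A-inverse")
        T = config.n_traits
        self.T = T
        self.X = np.ascontiguousarray(design.X, dtype=np.float64)
        self.p = self.X.shape[1]
        self._xsq = (self.X**2).sum(axis=0)
        self.obs = design.observed
        self.n_rec = design.n_records

        # ordinal bookkeeping: integer category codes (-1 = missing)
        self.is_ordinal = np.array([t.kind == "ordinal" for t in design.traits])
        self.ycat = np.full((self.n_rec, T), -1, dtype=np.int64)
        for k, tr in enumerate(design.traits):
            if tr.kind == "ordinal":
                o = self.obs[:, k]
                self.ycat[o, k] = (
                    design.Y[o, k].astype(np.int64) - tr.first_category
                )

        # per-animal record map (at most one record per animal)
        self.has_rec = np.zeros(self.n_anim, dtype=np.bool_)
        vals, counts = np.unique(design.animal, return_counts=True)
        if np.any(counts > 1):
            raise ValueError("repeated records per animal are not supported")
        self.has_rec[design.animal] = True

        # priors
        self.S0g = config.prior_scale_g * np.eye(T)
        self.S0r = config.prior_scale_r * np.eye(T)

        self._init_state()
        self._warned_empty_category = set()

    # -- state initialisation ------------------------------------------------

    def _init_state(self):
        T, cfg = self.T, self.cfg
        self.G = self.S0g / max(cfg.df_g - T - 1, 1.0)
        self.R = self.S0r / max(cfg.df_r - T - 1, 1.0)
        for k in np.where(self.is_ordinal)[0]:
            self.R[k, k] = 1.0
        self.b = np.zeros((self.p, T))
        self.u = np.zeros((self.n_anim, T))
        # cuts[k]: full threshold vector (-inf, 0, t2..., +inf) for ordinal k
        self.cuts = []
        for k, tr in enumerate(self.design.traits):
            if tr.kind != "ordinal":
                self.cuts.append(None)
                continue
            K = tr.n_categories
            cut = np.empty(K + 1)
            cut[0], cut[-1] = -np.inf, np.inf
            cut[1] = 0.0
            if K > 2:
                # initialise interior cutpoints from observed category
                # frequencies so early liabilities are plausible
                o = self.ycat[:, k] >= 0
                if o.any():
                    freq = np.bincount(self.ycat[o, k], minlength=K) / o.sum()
                    cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
                    zq = ndtri(cum)
                    cut[1 : K] = np.maximum.accumulate(zq - zq[0]) + np.arange(K - 1) * 1e-6
                else:
                    cut[1:K] = np.arange(K - 1, dtype=float)
            self.cuts.append(cut)
        # liabilities: observed Gaussian cells = data; ordinal cells start at
        # their category's (finite-clipped) interval midpoint; missing at 0
        self.liab = np.zeros((self.n_rec, T))
        for k, tr in enumerate(self.design.traits):
            o = self.obs[:, k]
            if tr.kind == "gaussian":
                self.liab[o, k] = self.design.Y[o, k]
            else:
                cut = self.cuts[k]
                lo = np.clip(cut[self.ycat[o, k]], cut[1] - 1.0, None)
                hi = np.clip(cut[self.ycat[o, k] + 1], None, cut[-2] + 1.0)
                self.liab[o, k] = 0.5 * (lo + hi)
        self.n_pd_redraws = 0

    # -- sub-steps -----------------------------------------------------------

    def _eta(self) -> np.ndarray:
        return self.X @ self.b + self.u[self.design.animal]

    def sample_liabilities(self):
        """Draw latent liabilities: truncated normal within the observed
        category's threshold interval, conditioning on the other traits'
        residuals through R; missing cells unconstrained (data
        augmentation); observed Gaussian cells untouched."""
        if self.n_rec == 0:
            return
        Rinv = np.linalg.inv(self.R)
        eta = self._eta()
        for k, tr in enumerate(self.design.traits):
            cvar = 1.0 / Rinv[k, k]
            sd = np.sqrt(cvar)
            E = self.liab - eta
            m_all = E @ Rinv[:, k]
            cm = eta[:, k] - cvar * m_all + E[:, k]
            if tr.kind == "gaussian":
                miss = ~self.obs[:, k]
                if miss.any():
                    self.liab[miss, k] = cm[miss] + sd * self.rng.standard_normal(
                        int(miss.sum())
                    )
                continue
            y = self.ycat[:, k]
            o = y >= 0
            miss = ~o
            if miss.any():
                self.liab[miss, k] = cm[miss] + sd * self.rng.standard_normal(
                    int(miss.sum())
                )
            if not o.any():
                continue
            cut = self.cuts[k]
            lo = (cut[y[o]] - cm[o]) / sd
            hi = (cut[y[o] + 1] - cm[o]) / sd
            pa, pb = ndtr(lo), ndtr(hi)
            uu = pa + self.rng.random(int(o.sum())) * (pb - pa)
            z = ndtri(np.clip(uu, _PROB_FLOOR, 1 - _PROB_FLOOR))
            z = np.clip(z, lo, hi)  # guard degenerate intervals
            lk = cm[o] + sd * z
            if not np.all(np.isfinite(lk)):
                raise RuntimeError(
                    f"liability divergence for trait {tr.name!r}; aborting"
                )
            self.liab[o, k] = lk

    def sample_location(self):
        """Single-site draws of fixed effects then a Gauss-Seidel sampling
        sweep of breeding values from the mixed-model-equation full
        conditionals."""
        Rinv = np.linalg.inv(self.R)
        if self.p:
            cholR = np.linalg.cholesky(self.R)
            Eb = self.liab - self.X @ self.b - self.u[self.design.animal]
            for j in range(self.p):
                xj = self.X[:, j]
                sj = self._xsq[j]
                rsum = xj @ Eb + sj * self.b[j]
                mu = rsum / sj
                bnew = mu + (cholR @ self.rng.standard_normal(self.T)) / np.sqrt(sj)
                Eb -= np.outer(xj, bnew - self.b[j])
                self.b[j] = bnew
        Ginv = np.linalg.inv(self.G)
        ry = np.zeros((self.n_anim, self.T))
        if self.n_rec:
            ry[self.design.animal] = (self.liab - self.X @ self.b) @ Rinv
        z = self.rng.standard_normal((self.n_anim, self.T))
        gauss_seidel_u(
            self.u,
            self.a_inv.indptr,
            self.a_inv.indices,
            self.a_inv.data,
            np.ascontiguousarray(Ginv),
            np.ascontiguousarray(Rinv),
            ry,
            self.has_rec,
            z,
        )

    def sample_thresholds(self):
        """Uniform draws of interior cutpoints between the extreme
        liabilities of adjacent observed categories (first cutpoint fixed at
        0 for identification; binary traits have nothing to sample)."""
        for k, tr in enumerate(self.design.traits):
            if tr.kind != "ordinal" or tr.n_categories <= 2:
                continue
            cut = self.cuts[k]
            y = self.ycat[:, k]
            o = y >= 0
            lk = self.liab[o, k]
            yk = y[o]
            for m in range(2, tr.n_categories):
                below = lk[yk == m - 1]
                above = lk[yk == m]
                lo = below.max() if below.size else cut[m - 1]
                hi = above.min() if above.size else cut[m + 1]
                if not below.size or not above.size:
                    if (tr.name, m) not in self._warned_empty_category:
                        log.warning(
                            "trait %s: empty category adjacent to cutpoint %d; "
                            "using neighbouring thresholds as bounds",
                            tr.name,
                            m,
                        )
                        self._warned_empty_category.add((tr.name, m))
                if not np.isfinite(hi):
                    hi = lo + 3.0
                if not np.isfinite(lo):
                    lo = hi - 3.0
                cut[m] = lo + self.rng.random() * (hi - lo)

    def sample_G(self):
        """Inverse-Wishart full conditional with scale u' A^-1 u + prior."""
        W = self.a_inv @ self.u
        Sg = self.u.T @ W
        self.G, extra = _sample_invwishart(
            self.rng, self.cfg.df_g + self.n_anim, self.S0g + Sg
        )
        self.n_pd_redraws += extra

    def sample_R(self):
        """Inverse-Wishart full conditional from (augmented-complete)
        residual cross-products."""
        if self.n_rec:
            E = self.liab - self._eta()
            Sr = E.T @ E
        else:
            Sr = np.zeros((self.T, self.T))
        self.R, extra = _sample_invwishart(
            self.rng, self.cfg.df_r + self.n_rec, self.S0r + Sr
        )
        self.n_pd_redraws += extra

    def rescale(self):
        """Identify ordinal traits: rescale so each ordinal trait's residual
        variance is exactly 1, transforming liabilities, u, b, thresholds and
        the G/R rows/columns consistently.  Correlations are invariant."""
        if not self.is_ordinal.any():
            return
        d = np.ones(self.T)
        ord_idx = np.where(self.is_ordinal)[0]
        d[ord_idx] = 1.0 / np.sqrt(np.diag(self.R)[ord_idx])
        self.liab *= d
        self.u *= d
        if self.p:
            self.b *= d
        for k in ord_idx:
            cut = self.cuts[k]
            finite = np.isfinite(cut)
            cut[finite] *= d[k]
        self.G = self.G * d[:, None] * d[None, :]
        self.R = self.R * d[:, None] * d[None, :]
        self.R[ord_idx, ord_idx] = 1.0

    def sweep(self):
        """One full Gibbs iteration in the fixed update order."""
        self.sample_liabilities()
        self.sample_location()
        self.sample_thresholds()
        self.sample_G()
        self.sample_R()
        self.rescale()

    # -- deviance / run ------------------------------------------------------

    def _deviance(self, b=None, u=None, cuts=None, R=None) -> float:
        return observed_data_deviance(
            self.design,
            self.b if b is None else b,
            self.u if u is None else u,
            self.cuts if cuts is None else cuts,
            self.R if R is None else R,
        )

    def run(self) -> PosteriorSamples:
        cfg = self.cfg
        S = cfg.n_saved
        T, p = self.T, self.p
        out_G = np.empty((S, T, T))
        out_R = np.empty((S, T, T))
        out_b = np.empty((S, p, T))
        out_dev = np.empty(S)
        out_cut = {
            tr.name: np.empty((S, tr.n_categories - 2))
            for tr in self.design.traits
            if tr.kind == "ordinal" and tr.n_categories > 2
        }
        out_u = np.empty((S, self.n_anim, T)) if cfg.store_u else None
        u_sum = np.zeros((self.n_anim, T))
        s = 0
        for it in range(cfg.n_iter):
            self.sweep()
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                out_G[s] = self.G
                out_R[s] = self.R
                out_b[s] = self.b
                out_dev[s] = self._deviance()
                for k, tr in enumerate(self.design.traits):
                    if tr.name in out_cut:
                        out_cut[tr.name][s] = self.cuts[k][2 : tr.n_categories]
                if out_u is not None:
                    out_u[s] = self.u
                u_sum += self.u
                s += 1
        if self.n_pd_redraws:
            log.info("covariance PD redraws: %d", self.n_pd_redraws)
        return PosteriorSamples(
            G=out_G[:s],
            R=out_R[:s],
            b=out_b[:s],
            thresholds={k: v[:s] for k, v in out_cut.items()},
            deviance=out_dev[:s],
            u_mean=u_sum / max(s, 1),
            traits=self.design.traits,
            columns=self.design.columns,
            seed=cfg.seed,
            config=cfg,
            u=out_u[:s] if out_u is not None else None,
            n_pd_redraws=self.n_pd_redraws,
        )


def observed_data_deviance(design: DesignMatrices, b, u, cuts, R) -> float:
    """-2 log likelihood of the observed records, liabilities integrated out
    marginally per trait (normal CDF differences for ordinal categories,
    normal density for Gaussian traits).  Zero-probability categories are
    floored at 1e-12."""
    if design.n_records == 0:
        return 0.0
    eta = design.X @ b + u[design.animal]
    ll = 0.0
    for k, tr in enumerate(design.traits):
        o = design.observed[:, k]
        if not o.any():
            continue
        sd = np.sqrt(R[k, k])
        if tr.kind == "gaussian":
            resid = design.Y[o, k] - eta[o, k]
            ll += float(
                -0.5 * np.sum(resid**2) / R[k, k]
                - 0.5 * o.sum() * np.log(2 * np.pi * R[k, k])
            )
        else:
            y = design.Y[o, k].astype(np.int64) - tr.first_category
            cut = cuts[k]
            prob = ndtr((cut[y + 1] - eta[o, k]) / sd) - ndtr(
                (cut[y] - eta[o, k]) / sd
            )
            n_floor = int((prob < _PROB_FLOOR).sum())
            if n_floor:
                log.warning(
                    "trait %s: %d record(s) with near-zero category "
                    "probability floored",
                    tr.name,
                    n_floor,
                )
            ll += float(np.log(np.clip(prob, _PROB_FLOOR, None)).sum())
    return -2.0 * ll


def gibbs_run(
    design: DesignMatrices,
    a_inv: sparse.spmatrix,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> PosteriorSamples:
    """Run the threshold-model Gibbs sampler and return thinned draws."""
    return ThresholdGibbsSampler(design, a_inv, config, rng=rng).run()


def compute_dic(samples: PosteriorSamples, design: DesignMatrices) -> float:
    """Deviance information criterion: ``2 mean(D) - D(posterior means)``.

    The plug-in deviance evaluates the observed-data likelihood at the
    posterior means of b, u, thresholds and R.
    """
    if samples.n_draws < 100:
        raise ValueError("DIC needs at least 100 stored draws")
    cuts = []
    for k, tr in enumerate(samples.traits):
        if tr.kind != "ordinal":
            cuts.append(None)
            continue
        K = tr.n_categories
        cut = np.empty(K + 1)
        cut[0], cut[-1] = -np.inf, np.inf
        cut[1] = 0.0
        if K > 2:
            cut[2:K] = samples.thresholds[tr.name].mean(axis=0)
        cuts.append(cut)
    plug = observed_data_deviance(
        design,
        samples.b.mean(axis=0),
        samples.u_mean,
        cuts,
        samples.R.mean(axis=0),
    )
    return float(2.0 * samples.deviance.mean() - plug)
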