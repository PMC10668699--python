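"""Descriptive epidemiology of the defect scores and the risk-factor screen.

Covers the per-trait descriptive statistics, category prevalences and
severe-category co-occurrence, trend tables by birth year and inbreeding
bin, the studbook breeder-eligibility severity rule, and a multinomial
(or binary) logit screen of sex, stud size, age and inbreeding fitted by
Newton-Raphson maximum likelihood with likelihood-ratio p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "descriptive_stats",
    "prevalence_by_category",
    "cooccurrence_cat2",
    "share_without_defect",
    "trend_tables",
    "breeder_eligibility",
    "fit_multinomial_logit",
    "glz_risk_screen",
    "MultinomialLogitFit",
    "DEFAULT_F_BINS",
]

#: inbreeding bins: [0, 1/16], (1/16, 1/8], (1/8, 1/4], (1/4, 1)
DEFAULT_F_BINS = (0.0, 0.0625, 0.125, 0.25, 1.0)


def descriptive_stats(scores: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-trait N, mean (s.e.), s.d. (N-1), mode (lowest on ties) and the
    normal-approximation 95% CI of the mean.

    Empty columns yield an N = 0 row with NaN statistics and a ``degenerate``
    flag rather than an exception.
    """
    traits = list(traits) if traits is not None else list(scores.columns)
    rows = []
    for t in traits:
        x = scores[t].dropna().astype(float).to_numpy()
        n = x.size
        if n == 0:
            rows.append(
                dict(trait=t, N=0, mean=np.nan, se=np.nan, sd=np.nan,
                     mode=np.nan, ci95_lower=np.nan, ci95_upper=np.nan,
                     degenerate=True)
            )
            continue
        mean = x.mean()
        sd = x.std(ddof=1) if n > 1 else 0.0
        se = sd / np.sqrt(n)
        vals, counts = np.unique(x, return_counts=True)
        mode = vals[counts == counts.max()].min()
        rows.append(
            dict(trait=t, N=n, mean=mean, se=se, sd=sd, mode=mode,
                 ci95_lower=mean - 1.96 * se, ci95_upper=mean + 1.96 * se,
                 degenerate=n < 2)
        )
    return pd.DataFrame(rows)


def prevalence_by_category(scores, categories=None) -> pd.Series:
    """Percentage share per category over non-missing records."""
    x = pd.Series(scores).dropna().astype(float)
    if categories is None:
        categories = sorted(x.unique())
    shares = x.value_counts(normalize=True) * 100.0
    return pd.Series([shares.get(float(c), 0.0) for c in categories],
                     index=list(categories), name="percent")


def cooccurrence_cat2(scores_i, scores_j, category: int = 2) -> float:
    """Percentage of animals scored on both traits that are at the severe
    category on both (pairwise-complete denominator)."""
    a = pd.Series(scores_i).astype(float)
    b = pd.Series(scores_j).astype(float)
    both = a.notna() & b.notna()
    if both.sum() == 0:
        return np.nan
    hit = (a[both] == category) & (b[both] == category)
    return 100.0 * hit.mean()


def share_without_defect(scores: pd.DataFrame, traits) -> float:
    """Percentage of animals with no observed defect (> 0) on any trait."""
    sub = scores[list(traits)].astype(float)
    any_defect = (sub > 0).any(axis=1)
    return 100.0 * float((~any_defect).mean())


def trend_tables(
    phen: pd.DataFrame,
    traits,
    f_bins=DEFAULT_F_BINS,
    year_col: str = "birth_year",
    f_col: str = "F",
) -> dict:
    """Affected percentage (score > 0) per birth year and per inbreeding bin.

    The first F bin is closed on the left (F = 0 included); empty cells are
    NaN, not zero.
    """
    out = {}
    affected = {
        t: (phen[t].astype(float) > 0).where(phen[t].notna()) for t in traits
    }
    aff = pd.DataFrame(affected)
    by_year = aff.groupby(phen[year_col]).mean() * 100.0
    by_year.index.name = "birth_year"
    out["by_birth_year"] = by_year
    edges = np.asarray(f_bins, dtype=float)
    labels = [f"({edges[i]:g}, {edges[i+1]:g}]" for i in range(len(edges) - 1)]
    labels[0] = f"[{edges[0]:g}, {edges[1]:g}]"
    binned = pd.cut(phen[f_col].astype(float), bins=edges,
                    include_lowest=True, labels=labels)
    by_f = aff.groupby(binned, observed=False).mean() * 100.0
    by_f.index.name = "F_bin"
    out["by_inbreeding"] = by_f
    return out


def breeder_eligibility(very_severe_count: int, severe_count: int) -> bool:
    """Studbook rule: a horse with more than 2 very severe defects or more
    than 4 severe defects cannot be registered as a breeder."""
    if very_severe_count < 0 or severe_count < 0:
        raise ValueError("defect counts must be non-negative")
    return not (very_severe_count > 2 or severe_count > 4)


# -- multinomial logit risk screen -----------------------------------------


@dataclass
class MultinomialLogitFit:
    """Baseline-category (category 0) logit fit."""

    coef: np.ndarray  # (p, K-1)
    loglik: float
    n_iter: int
    converged: bool
    separation: bool
    classes: np.ndarray


def fit_multinomial_logit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> MultinomialLogitFit:
    """Multinomial (binary as K=2) logit by full Newton-Raphson.

    Baseline category = lowest observed class.  Raises on non-convergence;
    flags (without raising) likely complete separation.
    """
    X = np.asarray(X, dtype=float)
    classes, yi = np.unique(np.asarray(y), return_inverse=True)
    K = classes.size
    if K < 2:
        raise ValueError("outcome is degenerate (single class)")
    n, p = X.shape
    Yind = np.zeros((n, K))
    Yind[np.arange(n), yi] = 1.0
    B = np.zeros((p, K - 1))
    ll_old = -np.inf
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ B
        m = np.maximum(eta.max(axis=1, keepdims=True), 0.0)
        expo = np.exp(eta - m)
        denom = np.exp(-m[:, 0]) + expo.sum(axis=1)
        P = expo / denom[:, None]  # (n, K-1), non-baseline probabilities
        ll = float(np.sum(eta[np.arange(n), yi - 1] * (yi > 0))) - float(
            np.sum(np.log(denom) + m[:, 0])
        )
        grad = X.T @ (Yind[:, 1:] - P)  # (p, K-1)
        grad_norm = float(np.abs(grad).max())
        if abs(ll - ll_old) < tol and grad_norm < 1e-6:
            break
        ll_old = ll
        H = np.zeros((p * (K - 1), p * (K - 1)))
        for a in range(K - 1):
            for b_ in range(a, K - 1):
                w = P[:, a] * ((1.0 if a == b_ else 0.0) - P[:, b_])
                blk = X.T @ (X * w[:, None])
                H[a * p:(a + 1) * p, b_ * p:(b_ + 1) * p] = blk
                if a != b_:
                    H[b_ * p:(b_ + 1) * p, a * p:(a + 1) * p] = blk
        H[np.diag_indices_from(H)] += 1e-10  # numerical ridge
        step = np.linalg.solve(H, grad.T.ravel())
        B = B + step.reshape(K - 1, p).T
        if np.abs(B).max() > 25.0:  # diverging: likely complete separation
            break
    else:
        raise RuntimeError(
            f"multinomial logit did not converge in {max_iter} iterations "
            f"(last gradient max-norm {grad_norm:.3e})"
        )
    separation = bool(np.abs(B).max() > 25.0)
    if separation:
        warnings.warn(
            "possible complete separation: very large logit coefficients",
            RuntimeWarning,
            stacklevel=2,
        )
    return MultinomialLogitFit(B, ll, it, True, separation, classes)


def _design_for_screen(phen, effects, covariates):
    cols = [np.ones(len(phen))]
    names = ["intercept"]
    groups: dict[str, list[int]] = {}
    from .model import _LEVEL_ORDER

    for eff in effects:
        levels = [str(v) for v in phen[eff]]
        order = _LEVEL_ORDER.get(eff)
        present = list(dict.fromkeys(levels))
        if order is not None:
            ordered = [lv for lv in order if lv in present]
            ordered += [lv for lv in present if lv not in order]
        else:
            ordered = sorted(present)
        groups[eff] = []
        for lv in ordered[1:]:
            groups[eff].append(len(cols))
            cols.append(np.asarray([1.0 if v == lv else 0.0 for v in levels]))
            names.append(f"{eff}[{lv}]")
    for cov in covariates:
        v = phen[cov].astype(float).to_numpy()
        groups[cov] = [len(cols)]
        cols.append(v - v.mean())
        names.append(cov)
    return np.column_stack(cols), names, groups


def glz_risk_screen(
    phen: pd.DataFrame,
    outcome: str,
    effects=("sex", "stud_size"),
    covariates=("age", "F"),
) -> dict:
    """Multinomial-logit association screen of one defect against its risk
    factors.

    Returns the coefficient table, a per-effect likelihood-ratio test table
    (full model vs the model without that effect) and the affected
    percentage per level of each categorical effect.
    """
    sub = phen.dropna(subset=[outcome]).reset_index(drop=True)
    y = sub[outcome].astype(float).to_numpy().astype(int)
    X, names, groups = _design_for_screen(sub, effects, covariates)
    full = fit_multinomial_logit(X, y)
    lr_rows = []
    for eff, idx in groups.items():
        keep = [j for j in range(X.shape[1]) if j not in idx]
        red = fit_multinomial_logit(X[:, keep], y)
        lr = 2.0 * (full.loglik - red.loglik)
        df = len(idx) * (full.classes.size - 1)
        lr_rows.append(
            dict(effect=eff, lr_stat=max(lr, 0.0), df=df,
                 p_value=float(stats.chi2.sf(max(lr, 0.0), df)))
        )
    coef = pd.DataFrame(
        full.coef,
        index=names,
        columns=[f"logit[{int(c)} vs {int(full.classes[0])}]"
                 for c in full.classes[1:]],
    )
    pct = {}
    for eff in effects:
        lv = sub.groupby(sub[eff].astype(str))[outcome].apply(
            lambda s: 100.0 * (s.astype(float) > 0).mean()
        )
        pct[eff] = lv
    return {
        "coefficients": coef,
        "lr_tests": pd.DataFrame(lr_rows),
        "affected_percent": pct,
        "separation": full.separation,
        "loglik": full.loglik,
    }
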