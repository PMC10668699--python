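"""Post-Gibbs chain summaries: HPD intervals, Geweke Z, Monte Carlo standard
errors, heritabilities, genetic correlations with sign probabilities, and
the model A/B EBV percentile-overlap comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gibbs import PosteriorSamples

__all__ = [
    "heritability",
    "genetic_correlation",
    "hpd_interval",
    "geweke_z",
    "mcse",
    "sign_probability",
    "ebv_percentile_overlap",
    "summarize",
]


def heritability(sigma_u, sigma_e):
    """Liability-scale heritability h^2 = sigma_u^2 / (sigma_u^2 + sigma_e^2).

    Accepts scalars or aligned chains; both variances must be positive.
    """
    su = np.asarray(sigma_u, dtype=float)
    se = np.asarray(sigma_e, dtype=float)
    if np.any(su <= 0) or np.any(se <= 0):
        raise ValueError("variance components must be positive")
    out = su / (su + se)
    return float(out) if out.ndim == 0 else out


def genetic_correlation(G, i: int, j: int):
    """r_g = G_ij / sqrt(G_ii G_jj) for a single draw (T,T) or a chain
    (S,T,T)."""
    G = np.asarray(G, dtype=float)
    if G.ndim == 2:
        G = G[None]
        squeeze = True
    else:
        squeeze = False
    dii, djj = G[:, i, i], G[:, j, j]
    if np.any(dii <= 0) or np.any(djj <= 0):
        raise ValueError("zero or negative diagonal in G")
    r = G[:, i, j] / np.sqrt(dii * djj)
    return float(r[0]) if squeeze else r


def hpd_interval(chain, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` sorted draws
    (leftmost window on ties)."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(chain, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 draws for an HPD interval")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _spectral0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via Bartlett-windowed
    autocovariances (lag window ~ sqrt(n))."""
    n = x.size
    xc = x - x.mean()
    g0 = float(xc @ xc) / n
    L = max(int(np.sqrt(n)), 1)
    s = g0
    for lag in range(1, min(L, n - 1) + 1):
        g = float(xc[lag:] @ xc[:-lag]) / n
        s += 2.0 * (1.0 - lag / (L + 1.0)) * g
    return max(s, 1e-30)


def geweke_z(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence Z: early-window mean minus late-window mean,
    scaled by spectral-density variance estimates of each window."""
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("Geweke diagnostic needs at least 100 draws")
    if np.allclose(x, x[0]):
        raise ValueError("constant chain has no Geweke diagnostic")
    a = x[: int(first * n)]
    b = x[n - int(last * n) :]
    va = _spectral0(a) / a.size
    vb = _spectral0(b) / b.size
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def mcse(chain) -> float:
    """Batch-means Monte Carlo standard error with floor(sqrt(n)) batches."""
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("MCSE needs at least 100 draws")
    nb = int(np.sqrt(n))
    m = n // nb
    means = x[: nb * m].reshape(nb, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))


def sign_probability(chain) -> float:
    """Posterior mass on the dominant sign: max(share > 0, share < 0)."""
    x = np.asarray(chain, dtype=float)
    return float(max((x > 0).mean(), (x < 0).mean()))


def ebv_percentile_overlap(ebv_1: dict, ebv_2: dict, q: float = 0.8) -> float:
    """Percentage of the first model's top-(1-q) animals that also rank in
    the second model's top set.

    ``top`` = animals strictly above the q-quantile of each EBV vector; the
    denominator is the first model's top-set size.
    """
    if set(ebv_1) != set(ebv_2):
        raise ValueError("EBV dictionaries cover different animal sets")
    ids = sorted(ebv_1)
    v1 = np.array([ebv_1[a] for a in ids], dtype=float)
    v2 = np.array([ebv_2[a] for a in ids], dtype=float)
    top1 = {a for a, v in zip(ids, v1) if v > np.quantile(v1, q)}
    top2 = {a for a, v in zip(ids, v2) if v > np.quantile(v2, q)}
    if not top1:
        raise ValueError("empty top set; lower q")
    return 100.0 * len(top1 & top2) / len(top1)


def _chain_row(name, trait_i, trait_j, chain, mass=0.95):
    chain = np.asarray(chain, dtype=float)
    lo, hi = hpd_interval(chain, mass) if chain.size >= 20 else (np.nan, np.nan)
    try:
        z = geweke_z(chain)
    except ValueError:
        z = np.nan
    try:
        se = mcse(chain)
    except ValueError:
        se = np.nan
    return {
        "parameter": name,
        "trait": trait_i,
        "trait2": trait_j,
        "mean": float(chain.mean()),
        "median": float(np.median(chain)),
        "sd": float(chain.std(ddof=1)) if chain.size > 1 else 0.0,
        "hpd95_lower": lo,
        "hpd95_upper": hi,
        "geweke_z": z,
        "mcse": se,
        "p_sign": sign_probability(chain),
    }


def summarize(samples: PosteriorSamples) -> pd.DataFrame:
    """Tidy posterior summary table: variance components, covariate slopes,
    heritabilities, genetic correlations and sampled thresholds, each with
    mean/median/sd, 95% HPD, Geweke Z, MCSE and sign probability."""
    rows = []
    traits = samples.traits
    T = len(traits)
    for k, tr in enumerate(traits):
        su = samples.G[:, k, k]
        se_ = samples.R[:, k, k]
        rows.append(_chain_row("sigma2_u", tr.name, "", su))
        rows.append(_chain_row("sigma2_e", tr.name, "", se_))
        rows.append(_chain_row("h2", tr.name, "", heritability(su, se_)))
    for i in range(T):
        for j in range(i + 1, T):
            rg = genetic_correlation(samples.G, i, j)
            rows.append(_chain_row("r_g", traits[i].name, traits[j].name, rg))
    for jcol, col in enumerate(samples.columns):
        for k, tr in enumerate(traits):
            rows.append(_chain_row(f"b[{col}]", tr.name, "", samples.b[:, jcol, k]))
    for name, cutchain in samples.thresholds.items():
        for m in range(cutchain.shape[1]):
            rows.append(_chain_row(f"threshold_{m + 2}", name, "", cutchain[:, m]))
    return pd.DataFrame(rows)
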