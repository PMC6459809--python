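"""Per-region two-group differential expression with moderated t statistics.

For each brain region, the selected line is compared with its founder
stock gene-by-gene using an empirical-Bayes moderated t: per-gene pooled
variances s_g^2 (d_g residual df) are shrunk toward a common prior
variance s0^2 with prior df d0, both estimated by the method of moments on
log s_g^2 through digamma/trigamma relations.  The moderated statistic

    t_g = delta_g / (s_post,g * sqrt(1/n1 + 1/n2)),
    s_post,g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

is referred to a t distribution on d0 + d_g degrees of freedom.  Masked
values are excluded, with per-gene degrees of freedom adjusting
accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.cluster import KMeans

from .datasets import CONTROL, SELECTED, ExpressionDataset

#: prior df above this value is treated as infinite
D0_CAP = 1e6


# ---------------------------------------------------------------------------
# hyperparameter estimation (method of moments on log s^2)
# ---------------------------------------------------------------------------
def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = special.polygamma(1, x) - y
        fprime = special.polygamma(2, x)
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * abs(x):
            return x_new
        x = x_new
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s0^2) from per-gene variances and their df.

    e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2) has mean log s0^2 +
    digamma(d0/2) - log(d0/2) and variance trigamma(d_g/2) +
    trigamma(d0/2); solving the excess variance for d0 inverts the
    trigamma function.  Non-finite or nonpositive variances are ignored.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need at least two genes with positive variance")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, df / 2.0).mean()
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        if d0 > D0_CAP:
            d0 = np.inf
            s0_2 = float(np.exp(emean))
        else:
            s0_2 = float(np.exp(
                emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


# ---------------------------------------------------------------------------
# the per-region test
# ---------------------------------------------------------------------------
@dataclass
class DEResult:
    """Per-gene differential expression results for one region."""

    region: str
    table: pd.DataFrame  # per-gene columns, see moderated_t_test
    prior_df: float
    prior_variance: float

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def deg_set(self, alpha: float = 0.05, direction: str | None = None,
                use_q: bool = False) -> set[str]:
        """Genes significant at ``alpha``; optionally one direction only.

        ``use_q=False`` thresholds the raw p-values (the convention used
        for downstream module over-representation); ``use_q=True``
        thresholds BH q-values instead.
        """
        col = "q" if use_q else "p"
        sel = self.table[col] < alpha
        if direction is not None:
            sel &= self.table["direction"] == direction
        return set(self.table.index[sel])


def _group_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NaN-aware per-row n, mean and sum of squared deviations."""
    n = np.sum(~np.isnan(x), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=1)
        ss = np.nansum((x - mean[:, None]) ** 2, axis=1)
    return n, mean, ss


def moderated_t_test(
    ds: ExpressionDataset,
    region: str,
    genes: pd.Index | None = None,
    prior_df: float | None = None,
) -> DEResult:
    """Moderated two-group t test for one region.

    ``prior_df`` overrides the estimated d0 (``0`` reproduces the ordinary
    pooled t exactly; ``np.inf`` uses the prior variance alone).  Genes
    with fewer than 2 unmasked values in either group get NaN statistics
    and are excluded from hyperparameter estimation.
    """
    sel_cols = ds.group_samples(region, SELECTED)
    ctl_cols = ds.group_samples(region, CONTROL)
    if len(sel_cols) < 2 or len(ctl_cols) < 2:
        raise ValueError(
            f"region {region!r} needs >= 2 samples per genotype "
            f"(got {len(sel_cols)} selected, {len(ctl_cols)} control)")
    values = ds.masked_values()
    if genes is not None:
        values = values.loc[genes]
    x1 = values[sel_cols].to_numpy(dtype=float)
    x2 = values[ctl_cols].to_numpy(dtype=float)
    n1, m1, ss1 = _group_stats(x1)
    n2, m2, ss2 = _group_stats(x2)
    valid = (n1 >= 2) & (n2 >= 2)
    dg = np.where(valid, n1 + n2 - 2, 0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(dg > 0, (ss1 + ss2) / np.maximum(dg, 1), np.nan)
    delta = m1 - m2

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2[valid], dg[valid])
    elif prior_df == 0:
        d0, s0_2 = 0.0, float(np.nanmedian(s2[valid]))
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2[valid], dg[valid])

    if np.isinf(d0):
        s_post2 = np.full_like(s2, s0_2)
        df_total = np.full_like(dg, np.inf)
    else:
        s_post2 = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(s_post2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tmod = delta / se
        tord = delta / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(tmod)),
        2.0 * stats.t.sf(np.abs(tmod), np.maximum(df_total, 1e-12)),
    )
    # zero variance and zero delta: no evidence of change
    p = np.where(np.isnan(tmod) & valid & (delta == 0), 1.0, p)
    tmod = np.where(np.isnan(tmod) & valid & (delta == 0), 0.0, tmod)
    p = np.where(valid, p, np.nan)

    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    fc = np.sign(delta) * np.power(2.0, np.abs(delta))
    fc = np.where(delta == 0, 1.0, fc)
    table = pd.DataFrame({
        "mean_selected": m1,
        "mean_control": m2,
        "delta": delta,
        "fold_change": fc,
        "ordinary_t": tord,
        "moderated_t": tmod,
        "df": df_total,
        "p": p,
        "q": q,
        "direction": np.where(delta >= 0, "up", "down"),
    }, index=values.index)
    return DEResult(region=region, table=table, prior_df=d0, prior_variance=s0_2)


def de_all_regions(
    ds: ExpressionDataset,
    detected: dict[str, pd.Index] | None = None,
    prior_df: float | None = None,
) -> dict[str, DEResult]:
    """Run the moderated t per region, restricted to detected genes."""
    out: dict[str, DEResult] = {}
    for region in ds.regions:
        genes = None if detected is None else detected[region]
        out[region] = moderated_t_test(ds, region, genes=genes,
                                       prior_df=prior_df)
    return out


# ---------------------------------------------------------------------------
# supporting statistics
# ---------------------------------------------------------------------------
def degs_vs_chance(n_deg: int, n_detected: int,
                   alpha: float = 0.05) -> tuple[float, float]:
    """Chi-square test of the DEG count against the chance expectation.

    Two cells (significant / not significant), expected proportions
    (alpha, 1 - alpha), 1 df, no continuity correction.
    """
    if n_detected <= 0:
        raise ValueError("n_detected must be positive")
    if n_deg > n_detected:
        raise ValueError("n_deg cannot exceed n_detected")
    exp_sig = alpha * n_detected
    exp_not = (1.0 - alpha) * n_detected
    stat = ((n_deg - exp_sig) ** 2 / exp_sig
            + (n_detected - n_deg - exp_not) ** 2 / exp_not)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input.

    q_(i) = min_{j >= i} min(1, n p_(j) / j) over the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, n + 1, dtype=float)
    raw = n * p[order] / ranks
    q_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def t_value_matrix(results: dict[str, "DEResult"]) -> pd.DataFrame:
    """Combined genes x regions matrix of moderated t values (NaN where a
    gene was not tested in a region)."""
    cols = {region: res.table["moderated_t"] for region, res in results.items()}
    return pd.DataFrame(cols)


def cluster_t_values(
    t_matrix: pd.DataFrame,
    results: dict[str, "DEResult"] | None = None,
    k: int = 6,
    p_cut: float = 1e-3,
    seed: int = 0,
    n_init: int = 25,
) -> tuple[pd.Series, np.ndarray]:
    """K-means clustering of per-gene t-value profiles across regions.

    When ``results`` is given, rows are first restricted to genes with raw
    p below ``p_cut`` in at least one region.  Returns (labels, centroids).
    """
    tm = t_matrix
    if results is not None:
        keep = pd.Series(False, index=tm.index)
        for res in results.values():
            sig = res.table.index[res.table["p"] < p_cut]
            keep.loc[keep.index.intersection(sig)] = True
        tm = tm.loc[keep[keep].index]
    tm = tm.dropna()
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(tm) < k:
        raise ValueError(f"only {len(tm)} rows available for k = {k} clusters")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(tm.to_numpy())
    return pd.Series(labels, index=tm.index, name="cluster"), km.cluster_centers_
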