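"""Filtering and normalization of expression datasets.

The full pipeline mirrors a standard bead-array workflow: transform and
quantile-normalize, drop region-level outlier samples (distance to the
region's average profile > 2x the median distance), re-normalize the
remaining samples, keep genes detected (p < 0.05) in at least 75% of a
region's samples, and mask per-gene outlier values with iterated Grubbs
tests within genotype x region groups.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset, GENOTYPE_COL, REGION_COL


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------
def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across samples (columns).

    Each sample's sorted values are replaced by the mean of sorted values
    across samples, mapped back by rank; ties receive the mean of their
    tied positions (fractional ranks are linearly interpolated).
    """
    x = values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples == 1:
        return values.copy()
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n_genes + 1, dtype=float)
    for j in range(n_samples):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize(ds: ExpressionDataset, log2_transform: bool = True) -> ExpressionDataset:
    """log2(x + 1) variance-stabilizing transform + quantile normalization.

    The log step is a documented stand-in for a bead-level variance
    stabilizing transform, which needs per-bead variance data that a plain
    matrix does not carry.  Set ``log2_transform=False`` when the input is
    already on a log-like scale.
    """
    values = ds.values
    if log2_transform:
        bad = values.to_numpy() <= 0
        if bad.any():
            gi, si = np.nonzero(bad)
            cells = [f"({values.index[g]}, {values.columns[s]})"
                     for g, s in zip(gi[:5], si[:5])]
            raise ValueError(
                f"nonpositive intensities at {bad.sum()} cells, e.g. "
                + ", ".join(cells))
        values = np.log2(values + 1.0)
    return dataclasses.replace(ds, values=quantile_normalize(values))


# ---------------------------------------------------------------------------
# sample outliers
# ---------------------------------------------------------------------------
def remove_outlier_samples(
    ds: ExpressionDataset, threshold_factor: float = 2.0
) -> tuple[ExpressionDataset, list[str]]:
    """Drop region-level outlier samples (single pass).

    Within each region, each sample's Euclidean distance to the region's
    mean expression profile is computed; samples whose distance strictly
    exceeds ``threshold_factor`` x the median distance are removed.
    """
    flagged: list[str] = []
    for region in ds.regions:
        cols = ds.region_samples(region)
        if len(cols) < 3:
            warnings.warn(
                f"region {region!r} has fewer than 3 samples; outlier "
                "detection skipped")
            continue
        sub = ds.values[cols].to_numpy()
        center = sub.mean(axis=1, keepdims=True)
        dist = np.sqrt(((sub - center) ** 2).sum(axis=0))
        cutoff = threshold_factor * np.median(dist)
        flagged.extend(cols[dist > cutoff])
    keep = [s for s in ds.samples if s not in set(flagged)]
    return ds.subset_samples(keep), flagged


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------
@dataclass
class DetectionResult:
    """Per-region detected gene sets and the cross-region network universe."""

    per_region: dict[str, pd.Index]
    network_universe: pd.Index

    def region_dataset(self, ds: ExpressionDataset, region: str) -> ExpressionDataset:
        return ds.subset_genes(self.per_region[region])


def detection_filter(
    ds: ExpressionDataset,
    detection_alpha: float = 0.05,
    min_fraction: float = 0.75,
) -> DetectionResult:
    """Per-region detection filtering.

    A gene is retained in a region when its detection p-value is below
    ``detection_alpha`` in at least ``min_fraction`` of that region's
    samples (boundary inclusive).  The network universe is the set of
    genes passing in all regions; per-region universes serve per-region
    differential expression.
    """
    if ds.detection is None:
        raise ValueError(
            "dataset has no detection p-values; skip the detection filter "
            "stage for data without them")
    per_region: dict[str, pd.Index] = {}
    universe: pd.Index | None = None
    for region in ds.regions:
        cols = ds.region_samples(region)
        det = ds.detection[cols].to_numpy() < detection_alpha
        frac = det.mean(axis=1)
        passed = ds.genes[frac >= min_fraction]
        per_region[region] = passed
        universe = passed if universe is None else universe.intersection(passed)
    return DetectionResult(per_region=per_region,
                           network_universe=universe.sort_values())


# ---------------------------------------------------------------------------
# Grubbs per-gene outlier masking
# ---------------------------------------------------------------------------
def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """One-outlier Grubbs critical value for sample size ``n``.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n - 2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_mask_values(values: np.ndarray, alpha: float = 0.05,
                       min_n: int = 3) -> np.ndarray:
    """Iterated Grubbs test on a single 1-d group.

    Returns a boolean mask of removed values.  At each round the most
    extreme value is removed if G = max|x - mean|/sd exceeds the critical
    value; iteration stops when no outlier is found, when fewer than
    ``min_n`` values remain, or when half the group has been masked.
    """
    x = np.asarray(values, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    max_masked = len(x) // 2
    while mask.sum() < max_masked:
        live = ~mask
        n = int(live.sum())
        if n < max(min_n, 3):
            break
        xm = x[live]
        sd = xm.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(xm - xm.mean())
        g = dev.max() / sd
        if g <= grubbs_critical_value(n, alpha):
            break
        idx = np.flatnonzero(live)[np.argmax(dev)]
        mask[idx] = True
    return mask


def grubbs_filter(
    ds: ExpressionDataset, alpha: float = 0.05, min_group_size: int = 6
) -> ExpressionDataset:
    """Mask per-gene outliers within genotype x region groups.

    Vectorized across genes: per group, each round computes G for every
    gene at once and masks the extreme value where G exceeds the critical
    value for the gene's current unmasked count; rounds repeat until no
    gene changes.  Groups (or genes) with fewer than ``min_group_size``
    unmasked values are not tested further; zero within-group variance
    means no test.  At most half the values of a group are ever masked.
    """
    mask = (ds.mask.copy() if ds.mask is not None
            else pd.DataFrame(False, index=ds.genes, columns=ds.samples))
    meta = ds.metadata
    for (region, genotype), sub in meta.groupby([REGION_COL, GENOTYPE_COL],
                                                sort=False):
        cols = sub.index
        if len(cols) < min_group_size:
            continue
        x = ds.values[cols].to_numpy(dtype=float)
        m = mask[cols].to_numpy()
        max_masked = len(cols) // 2
        # caps per-gene iteration; each round masks at most one value/gene
        for _ in range(max_masked):
            xm = np.where(m, np.nan, x)
            n = (~m).sum(axis=1)
            testable = n >= max(min_group_size, 3)
            testable &= (len(cols) - n) < max_masked
            if not testable.any():
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(xm, axis=1)
                sd = np.nanstd(xm, axis=1, ddof=1)
            dev = np.abs(xm - mean[:, None])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                g = np.nanmax(dev, axis=1) / sd
            ns = np.unique(n[testable])
            crit = {int(k): grubbs_critical_value(int(k), alpha) for k in ns}
            crit_arr = np.array([crit.get(int(k), np.inf) for k in n])
            hit = testable & (sd > 0) & (g > crit_arr)
            if not hit.any():
                break
            rows = np.flatnonzero(hit)
            argm = np.nanargmax(np.where(m[rows], -np.inf, dev[rows]), axis=1)
            m[rows, argm] = True
        mask.loc[:, cols] = m
    return ds.with_mask(mask)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------
@dataclass
class PreprocessResult:
    dataset: ExpressionDataset
    detection: DetectionResult
    flagged_samples: list[str]


def preprocess_pipeline(
    ds: ExpressionDataset,
    log2_transform: bool = True,
    detection_alpha: float = 0.05,
    min_fraction: float = 0.75,
    grubbs_alpha: float = 0.05,
) -> PreprocessResult:
    """normalize -> drop outlier samples -> re-normalize the survivors ->
    detection filter -> Grubbs masking."""
    raw = ds
    norm = normalize(ds, log2_transform=log2_transform)
    norm, flagged = remove_outlier_samples(norm)
    # re-normalize from the raw data of the remaining samples
    keep = [s for s in raw.samples if s not in set(flagged)]
    norm = normalize(raw.subset_samples(keep), log2_transform=log2_transform)
    detection = (detection_filter(norm, detection_alpha, min_fraction)
                 if norm.detection is not None
                 else DetectionResult(
                     per_region={r: norm.genes for r in norm.regions},
                     network_universe=norm.genes))
    masked = grubbs_filter(norm, alpha=grubbs_alpha)
    return PreprocessResult(dataset=masked, detection=detection,
                            flagged_samples=flagged)
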