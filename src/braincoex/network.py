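"""Signed weighted coexpression network construction and module detection.

Pipeline: Pearson correlation (pairwise-complete over masked values) ->
signed similarity S = (1 + cor)/2 -> soft-threshold adjacency a = S^beta
(beta chosen for approximate scale-free topology) -> topological overlap
matrix (TOM) -> average-linkage clustering of 1 - TOM -> dynamic tree cut
(static cut plus recursive branch splitting) -> module eigengenes,
intramodular connectivity, hub genes and hub-module scores.

Modules are named by the conventional size-ranked color palette; "grey"
collects unassigned genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

GREY = "grey"

#: size-ranked module color names (largest module first), following the
#: conventional WGCNA ordering
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
    "sienna3", "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2",
)


def module_color_names(n: int) -> list[str]:
    names = list(MODULE_COLORS[:n])
    names += [f"module{i}" for i in range(len(names) + 1, n + 1)]
    return names


# ---------------------------------------------------------------------------
# similarity and adjacency
# ---------------------------------------------------------------------------
def signed_similarity(expr: pd.DataFrame) -> pd.DataFrame:
    """S_ij = (1 + cor(x_i, x_j)) / 2 on a genes x samples matrix.

    NaN entries (masked values) are handled pairwise-complete.  Genes with
    zero variance get correlation 0 (similarity 0.5) with a warning.
    Diagonal is 1 by convention.
    """
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate genes")
    if np.isnan(x).any():
        cor = expr.T.corr(min_periods=3).to_numpy()
    else:
        sd = x.std(axis=1)
        cor = np.corrcoef(x)
        if (sd == 0).any():
            warnings.warn(
                f"{int((sd == 0).sum())} zero-variance genes; their "
                "correlations set to 0")
        cor[~np.isfinite(cor)] = 0.0
    cor = np.nan_to_num(cor, nan=0.0)
    np.clip(cor, -1.0, 1.0, out=cor)
    s = (1.0 + cor) / 2.0
    np.fill_diagonal(s, 1.0)
    s = (s + s.T) / 2.0
    return pd.DataFrame(s, index=expr.index, columns=expr.index)


def adjacency(similarity: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Soft-threshold adjacency a_ij = S_ij^beta, unit diagonal."""
    a = np.power(similarity.to_numpy(dtype=float), beta)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=similarity.index, columns=similarity.columns)


@dataclass
class SoftThresholdResult:
    beta: float
    fit_table: pd.DataFrame  # per candidate beta: fit index, mean k, slope
    reached_target: bool


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 x sign(-slope) of log10 p(k) vs log10 mean(k) over equal-width
    connectivity bins.  Returns (index, slope)."""
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        raise ValueError("all-constant connectivity: scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        freqs.append(sel.mean())
        means.append(k[sel].mean())
    logf = np.log10(np.asarray(freqs))
    logk = np.log10(np.maximum(np.asarray(means), 1e-12))
    if len(logf) < 3:
        raise ValueError("too few occupied connectivity bins")
    slope, intercept = np.polyfit(logk, logf, 1)
    pred = slope * logk + intercept
    ss_res = ((logf - pred) ** 2).sum()
    ss_tot = ((logf - logf.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2 * np.sign(-slope)), float(slope)


def pick_soft_threshold(
    similarity: pd.DataFrame,
    candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    target_r2: float = 0.8,
    tie_tolerance: float = 0.1,
) -> SoftThresholdResult:
    """Smallest candidate power whose network is approximately scale-free.

    For each beta the whole-network connectivity k_i = sum_j S_ij^beta
    (j != i) is binned and the scale-free fit index computed; the smallest
    beta with index >= ``target_r2`` is returned.  When no candidate
    reaches the target, the fit profile is typically a noisy plateau
    (differences within binning noise), so the fallback returns the
    LARGEST beta whose index lies within ``tie_tolerance`` of the
    maximum — stronger soft-thresholding sharpens the intra/inter-module
    contrast of a signed network — with a warning.
    """
    candidates = list(candidate_betas)
    if not candidates:
        raise ValueError("candidate_betas must be non-empty")
    s = similarity.to_numpy(dtype=float)
    rows = []
    for beta in candidates:
        a = np.power(s, beta)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        idx, slope = scale_free_fit_index(k)
        rows.append((beta, idx, float(k.mean()), slope))
    table = pd.DataFrame(rows, columns=["beta", "fit_index", "mean_k", "slope"])
    hit = table[table["fit_index"] >= target_r2]
    if len(hit):
        beta = float(hit.iloc[0]["beta"])
        return SoftThresholdResult(beta=beta, fit_table=table,
                                   reached_target=True)
    max_index = table["fit_index"].max()
    near = table[table["fit_index"] >= max_index - tie_tolerance]
    best = near.loc[near["beta"].idxmax()]
    warnings.warn(
        f"no candidate beta reached fit index {target_r2}; using "
        f"beta = {best['beta']:g} (index {best['fit_index']:.3f}, "
        f"max {max_index:.3f})")
    return SoftThresholdResult(beta=float(best["beta"]), fit_table=table,
                               reached_target=False)


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------
def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1,
    with l_ij the shared-neighbor sum and k_i the connectivity."""
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# dendrogram + dynamic tree cut
# ---------------------------------------------------------------------------
@dataclass
class ModuleDetection:
    labels: pd.Series            # gene -> color name ("grey" = unassigned)
    linkage: np.ndarray          # scipy merge list
    genes: pd.Index
    cut_height: float
    min_module_size: int

    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels != GREY].value_counts()

    def module_gene_sets(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for color in self.labels.unique():
            if color == GREY:
                continue
            out[color] = list(self.labels.index[self.labels == color])
        return out

    def dendrogram_json(self, path: str | Path) -> None:
        payload = {
            "genes": list(self.genes),
            "merges": [[int(a), int(b), float(h), int(c)]
                       for a, b, h, c in self.linkage],
            "cut_height": self.cut_height,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _subtree_heights(node, out: list[float]) -> None:
    if node.is_leaf():
        return
    out.append(node.dist)
    _subtree_heights(node.left, out)
    _subtree_heights(node.right, out)


def _deep_split(node, min_size: int) -> list:
    """Recursively split a branch at merges whose height exceeds the
    branch's median merge height and whose children are both large enough."""
    if node.is_leaf() or node.count < 2 * min_size:
        return [node]
    heights: list[float] = []
    _subtree_heights(node, heights)
    med = float(np.median(heights))
    if (node.dist > med and node.left.count >= min_size
            and node.right.count >= min_size):
        return _deep_split(node.left, min_size) + _deep_split(node.right, min_size)
    return [node]


def _gap_trim(node, min_gap: float, min_size: int) -> list:
    """Cut a branch at a dominant internal merge-height gap.

    Loosely attached genes join a tight branch core through chains of
    late merges just below the static cut, leaving a height gap above
    the core's own merge heights.  The branch is re-cut just below the
    widest gap located in the upper half of its merge-height
    distribution, provided the gap is pronounced (wider than ``min_gap``
    and than 15% of the height range) and at least one resulting
    component keeps ``min_size`` leaves (so a homogeneous branch is
    never fragmented).  Components are re-trimmed recursively: accretion
    can be layered.
    """
    if node.is_leaf():
        return [node]
    heights: list[float] = []
    _subtree_heights(node, heights)
    if len(heights) < 4:
        return [node]
    hs = np.sort(np.asarray(heights))
    span = hs[-1] - hs[0]
    gaps = np.diff(hs)
    upper = np.arange(len(gaps)) >= len(hs) // 2  # gap above the median
    if not upper.any():
        return [node]
    masked = np.where(upper, gaps, -np.inf)
    i = int(np.argmax(masked))
    if masked[i] < max(min_gap, 0.15 * span):
        return [node]
    h_cut = (hs[i] + hs[i + 1]) / 2.0
    comps: list = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf() or n.dist <= h_cut:
            comps.append(n)
        else:
            stack.extend([n.left, n.right])
    if max(c.count for c in comps) < min_size:
        return [node]
    out: list = []
    for c in comps:
        out.extend(_gap_trim(c, min_gap, min_size) if c.count > 3 else [c])
    return out


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 80,
    cut_height: float = 0.995,
    deep_split: bool = True,
    trim_gap: float = 0.01,
) -> ModuleDetection:
    """Average-linkage clustering of 1 - TOM with a dynamic tree cut.

    A static cut at ``cut_height`` yields candidate branches; with
    ``deep_split`` each branch is recursively split at high internal
    merges whose children both have at least ``min_module_size`` leaves,
    and each resulting branch is trimmed at its dominant internal
    merge-height gap (``trim_gap`` sets the minimum absolute gap width;
    0 disables trimming).  Branches below the minimum size are labeled
    grey.  Deterministic.
    """
    genes = tom.index
    n = len(genes)
    if min_module_size > n:
        warnings.warn("min_module_size exceeds gene count; all genes grey")
        labels = pd.Series(GREY, index=genes, name="module")
        z = hierarchy.average(squareform(1.0 - tom.to_numpy(), checks=False))
        return ModuleDetection(labels, z, genes, cut_height, min_module_size)

    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.average(squareform(dist, checks=False))
    root = hierarchy.to_tree(z)

    # candidate branches: maximal subtrees whose root merge height is
    # below the cut height
    candidates = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf() or node.dist <= cut_height:
            candidates.append(node)
        else:
            stack.extend([node.left, node.right])

    branches = []
    for node in candidates:
        split = _deep_split(node, min_module_size) if deep_split else [node]
        if deep_split and trim_gap > 0:
            trimmed = []
            for b in split:
                trimmed.extend(_gap_trim(b, trim_gap, min_module_size))
            split = trimmed
        branches.extend(split)

    clusters = [b.pre_order(lambda leaf: leaf.id) for b in branches]
    clusters = [c for c in clusters if len(c) >= min_module_size]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    names = module_color_names(len(clusters))
    arr = np.array([GREY] * n, dtype=object)
    for name, members in zip(names, clusters):
        arr[members] = name
    labels = pd.Series(arr, index=genes, name="module")
    return ModuleDetection(labels=labels, linkage=z, genes=genes,
                           cut_height=cut_height,
                           min_module_size=min_module_size)


# ---------------------------------------------------------------------------
# module summaries
# ---------------------------------------------------------------------------
@dataclass
class ModuleProfile:
    """Per-module summaries: eigengene, variance explained, connectivity."""

    eigengenes: pd.DataFrame       # modules x samples, unit-norm rows
    variance_explained: pd.Series  # per module
    kin: pd.Series                 # per gene, intramodular connectivity
    hub_genes: dict[str, list[str]] = field(default_factory=dict)
    hub_module_scores: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.index)


def module_eigengene(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component per module of gene-standardized expression.

    Eigengenes have unit norm and are sign-oriented so their correlation
    with the module's mean standardized expression profile is >= 0.
    Returns (eigengenes modules x samples, variance explained).
    """
    eig = {}
    varexp = {}
    for color in sorted(labels.unique()):
        if color == GREY:
            continue
        sub = expr.loc[labels.index[labels == color]].to_numpy(dtype=float)
        if sub.shape[0] < 2:
            raise ValueError(f"module {color!r} has fewer than 2 genes")
        # standardize genes over samples; NaN (masked) -> 0 after centering
        mean = np.nanmean(sub, axis=1, keepdims=True)
        sd = np.nanstd(sub, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        zed = (sub - mean) / sd
        zed = np.nan_to_num(zed, nan=0.0)
        try:
            _, svals, vt = np.linalg.svd(zed, full_matrices=False)
            e = vt[0]
            ve = float(svals[0] ** 2 / (svals ** 2).sum())
        except np.linalg.LinAlgError:
            warnings.warn(f"SVD failed for module {color!r}; "
                          "using standardized mean profile")
            e = zed.mean(axis=0)
            e = e / np.linalg.norm(e)
            ve = float("nan")
        mean_profile = zed.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eig[color] = e
        varexp[color] = ve
    eigengenes = pd.DataFrame(eig, index=expr.columns).T
    return eigengenes, pd.Series(varexp, name="variance_explained")


def intramodular_connectivity_and_hubs(
    adj: pd.DataFrame, labels: pd.Series, top_fraction: float = 0.2
) -> tuple[pd.Series, dict[str, list[str]]]:
    """K_in(g) = sum of adjacencies of g with the other genes of its
    module; hub genes are the top ceil(top_fraction x size) by K_in, ties
    broken by gene id."""
    if list(adj.index) != list(labels.index):
        raise ValueError("labels must align with adjacency rows")
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    kin = np.zeros(len(labels))
    hubs: dict[str, list[str]] = {}
    lab = labels.to_numpy()
    for color in sorted(labels.unique()):
        members = np.flatnonzero(lab == color)
        block = a[np.ix_(members, members)]
        kin[members] = block.sum(axis=1)
        if color == GREY:
            continue
        n_hub = int(np.ceil(top_fraction * len(members)))
        member_ids = labels.index[members]
        order = sorted(zip(-kin[members], member_ids))
        hubs[color] = [g for _, g in order[:n_hub]]
    return pd.Series(kin, index=labels.index, name="kin"), hubs


def hub_module_scores(
    adj: pd.DataFrame, labels: pd.Series, edge_density: float = 0.01
) -> pd.DataFrame:
    """Between-module edge counts per member gene, for edges above the
    (1 - edge_density) adjacency quantile.

    ``score_all`` counts every retained edge with exactly one endpoint in
    the module; ``score_topq`` restricts to edges whose weight lies in the
    top quartile of retained edge weights.  The module maximizing
    ``score_all`` is the hub module.
    """
    colors = [c for c in labels.unique() if c != GREY]
    if len(colors) < 2:
        raise ValueError("need at least two non-grey modules")
    a = adj.to_numpy(dtype=float)
    iu = np.triu_indices(a.shape[0], k=1)
    w = a[iu]
    if np.allclose(w, w[0]):
        raise ValueError(
            "all adjacency weights are equal; the edge threshold is "
            "degenerate - lower beta or supply a different edge rule")
    tau = np.quantile(w, 1.0 - edge_density)
    keep = w >= tau
    ii, jj, ww = iu[0][keep], iu[1][keep], w[keep]
    top_w = np.quantile(ww, 0.75) if ww.size else np.inf
    lab = labels.to_numpy()
    li, lj = lab[ii], lab[jj]
    cross = li != lj
    rows = []
    for color in colors:
        size = int((lab == color).sum())
        inc = cross & ((li == color) | (lj == color))
        # grey endpoints still count: the edge leaves the module
        rows.append((color, size, int(inc.sum()),
                     inc.sum() / size,
                     (inc & (ww >= top_w)).sum() / size))
    df = pd.DataFrame(rows, columns=["module", "size", "n_cross_edges",
                                     "score_all", "score_topq"])
    df = df.set_index("module").sort_values("score_all", ascending=False)
    df["is_hub_module"] = False
    if len(df):
        df.iloc[0, df.columns.get_loc("is_hub_module")] = True
    return df


# ---------------------------------------------------------------------------
# one-call network construction
# ---------------------------------------------------------------------------
@dataclass
class CoexpressionNetwork:
    genes: pd.Index
    similarity: pd.DataFrame
    beta: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    detection: ModuleDetection

    @property
    def labels(self) -> pd.Series:
        return self.detection.labels


def build_network(
    expr: pd.DataFrame,
    beta: float | None = None,
    candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    target_r2: float = 0.8,
    min_module_size: int = 80,
    cut_height: float = 0.995,
    deep_split: bool = True,
) -> CoexpressionNetwork:
    """Similarity -> (optionally picked) beta -> adjacency -> TOM -> modules."""
    s = signed_similarity(expr)
    if beta is None:
        beta = pick_soft_threshold(s, candidate_betas, target_r2).beta
    a = adjacency(s, beta)
    tom = topological_overlap(a)
    det = detect_modules(tom, min_module_size=min_module_size,
                         cut_height=cut_height, deep_split=deep_split)
    return CoexpressionNetwork(genes=expr.index, similarity=s, beta=beta,
                               adjacency=a, tom=tom, detection=det)


def export_edge_list(
    adj: pd.DataFrame, path: str | Path, min_weight: float | None = None,
    edge_density: float = 0.01,
) -> pd.DataFrame:
    """Thresholded edge list (gene_a, gene_b, weight), e.g. for Cytoscape."""
    a = adj.to_numpy(dtype=float)
    iu = np.triu_indices(a.shape[0], k=1)
    w = a[iu]
    if min_weight is None:
        min_weight = float(np.quantile(w, 1.0 - edge_density))
    keep = w >= min_weight
    df = pd.DataFrame({
        "gene_a": adj.index[iu[0][keep]],
        "gene_b": adj.index[iu[1][keep]],
        "weight": w[keep],
    })
    df.to_csv(path, sep="\t", index=False)
    return df
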