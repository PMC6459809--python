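"""Module characterization: over-representation and region dependence.

All enrichment runs through one machinery: the upper-tail hypergeometric
test of a module's overlap with a query gene set on a fixed universe (the
genes used to build the network), with Benjamini-Hochberg correction
applied once per analysis family (all module x set tests jointly).

Selection-responsive modules are those over-represented with
differentially expressed genes from at least one (region, direction)
list; cell types are assigned from marker-set enrichment; region
dependence of a module is a one-way ANOVA of its eigengene across brain
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GeneSetCollection, REGION_COL
from .de import DEResult, bh_fdr
from .network import GREY


@dataclass
class EnrichmentResult:
    module: str
    query: str
    universe_size: int   # N
    module_size: int     # n
    query_size: int      # K
    overlap: int         # k
    p: float
    q: float | None = None


def hypergeometric_enrichment(
    module_genes, query_genes, universe
) -> EnrichmentResult:
    """Upper-tail hypergeometric p for the module/query overlap.

    p = P(X >= k) for X ~ Hypergeometric(N, K, n), including the observed
    overlap.  Module and query must be subsets of the universe.
    """
    universe = set(universe)
    module_genes = set(module_genes)
    query_genes = set(query_genes)
    for name, s in (("module", module_genes), ("query", query_genes)):
        extra = s - universe
        if extra:
            raise ValueError(
                f"{name} genes outside the universe: "
                + ", ".join(sorted(extra)[:5])
                + ("..." if len(extra) > 5 else ""))
    big_n, big_k, n = len(universe), len(query_genes), len(module_genes)
    k = len(module_genes & query_genes)
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    return EnrichmentResult(module="", query="", universe_size=big_n,
                            module_size=n, query_size=big_k, overlap=k,
                            p=min(max(p, 0.0), 1.0))


def _enrichment_table(
    module_sets: dict[str, set[str]],
    query_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    rows = []
    for mod, mgenes in module_sets.items():
        for qname, qgenes in query_sets.items():
            r = hypergeometric_enrichment(mgenes, qgenes, universe)
            rows.append((mod, qname, r.universe_size, r.module_size,
                         r.query_size, r.overlap, r.p))
    df = pd.DataFrame(rows, columns=["module", "set", "N", "n", "K", "k", "p"])
    # one BH correction across the whole family of tests
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


def _module_sets(labels: pd.Series, universe: set[str],
                 include_grey: bool = False) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for color in sorted(labels.unique()):
        if color == GREY and not include_grey:
            continue
        out[color] = set(labels.index[labels == color]) & universe
    return out


# ---------------------------------------------------------------------------
# selection-responsive modules
# ---------------------------------------------------------------------------
def deg_lists_by_direction(
    results: dict[str, DEResult], alpha: float = 0.05, use_q: bool = False,
) -> dict[str, set[str]]:
    """(region, direction) -> DEG set, keys like ``'BLA_up'``."""
    lists = {}
    for region, res in results.items():
        for direction in ("up", "down"):
            lists[f"{region}_{direction}"] = res.deg_set(
                alpha=alpha, direction=direction, use_q=use_q)
    return lists


def selection_responsive_modules(
    labels: pd.Series,
    deg_lists: dict[str, set[str]],
    universe,
    q_threshold: float = 0.05,
    include_grey: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Over-representation of per-region, per-direction DEG lists.

    Returns (full enrichment table, per-module boolean flag: any test with
    q below ``q_threshold``).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    mods = _module_sets(labels, universe, include_grey)
    queries = {name: set(genes) & universe for name, genes in deg_lists.items()}
    table = _enrichment_table(mods, queries, universe)
    table["significant"] = table["q"] < q_threshold
    flags = (table.groupby("module")["significant"].any()
             .reindex(mods.keys(), fill_value=False)
             .rename("selection_responsive"))
    return table, flags


# ---------------------------------------------------------------------------
# cell types and generic gene sets
# ---------------------------------------------------------------------------
def cell_type_assignment(
    labels: pd.Series,
    markers: GeneSetCollection,
    universe,
    q_threshold: float = 0.05,
    include_grey: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-set enrichment and cell-type assignment per module.

    Marker genes absent from the universe are dropped (with a count in the
    table's attrs).  Returns (enrichment table, assignment table with one
    row per module: assigned cell types and the cell-type-specific flag).
    """
    universe = set(universe)
    mods = _module_sets(labels, universe, include_grey)
    queries, dropped = {}, {}
    for name, genes in markers.sets.items():
        inside = set(genes) & universe
        dropped[name] = len(genes) - len(inside)
        queries[name] = inside
    table = _enrichment_table(mods, queries, universe)
    table.attrs["markers_dropped"] = dropped
    table["significant"] = table["q"] < q_threshold
    rows = []
    for mod in mods:
        sig = table[(table["module"] == mod) & table["significant"]]
        types = sorted(sig["set"])
        rows.append((mod, ";".join(types), bool(types)))
    assign = pd.DataFrame(rows, columns=["module", "cell_types",
                                         "cell_type_specific"])
    return table, assign.set_index("module")


def geneset_enrichment(
    labels: pd.Series,
    collection: GeneSetCollection,
    universe,
    q_threshold: float = 0.05,
    include_grey: bool = False,
) -> pd.DataFrame:
    """Generic gene-set over-representation (same machinery, arbitrary GMT)."""
    universe = set(universe)
    mods = _module_sets(labels, universe, include_grey)
    queries = {name: set(genes) & universe
               for name, genes in collection.sets.items()}
    if not queries:
        return pd.DataFrame(
            columns=["module", "set", "N", "n", "K", "k", "p", "q",
                     "significant"])
    table = _enrichment_table(mods, queries, universe)
    table["significant"] = table["q"] < q_threshold
    return table


# ---------------------------------------------------------------------------
# eigengene region ANOVA
# ---------------------------------------------------------------------------
def eigengene_region_anova(
    eigengenes: pd.DataFrame, metadata: pd.DataFrame, p_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of each module eigengene across regions.

    A constant eigengene yields F = 0, p = 1 by convention.  Returns a
    table (module, F, p, region_dependent).
    """
    regions = list(dict.fromkeys(metadata[REGION_COL]))
    if len(regions) < 2:
        raise ValueError("need at least 2 regions for the eigengene ANOVA")
    groups_idx = {r: metadata.index[metadata[REGION_COL] == r] for r in regions}
    for r, idx in groups_idx.items():
        if len(idx) < 2:
            raise ValueError(f"region {r!r} has fewer than 2 samples")
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod]
        groups = [e[idx].to_numpy() for idx in groups_idx.values()]
        if np.allclose(np.concatenate(groups), e.iloc[0]):
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*groups)
            if not np.isfinite(f):
                f, p = 0.0, 1.0
        rows.append((mod, float(f), float(p), p < p_threshold))
    return pd.DataFrame(rows, columns=["module", "F", "p", "region_dependent"]
                        ).set_index("module")


# ---------------------------------------------------------------------------
# combined characterization
# ---------------------------------------------------------------------------
@dataclass
class ModuleCharacterization:
    deg_enrichment: pd.DataFrame
    selection_responsive: pd.Series
    marker_enrichment: pd.DataFrame
    cell_types: pd.DataFrame
    anova: pd.DataFrame
    geneset_tables: dict[str, pd.DataFrame]

    def flags_table(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "selection_responsive": self.selection_responsive,
        })
        out = out.join(self.cell_types, how="left")
        out = out.join(self.anova[["F", "p", "region_dependent"]], how="left")
        return out


def characterize_modules(
    labels: pd.Series,
    de_results: dict[str, DEResult],
    markers: GeneSetCollection,
    universe,
    eigengenes: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_sets: dict[str, GeneSetCollection] | None = None,
    deg_alpha: float = 0.05,
    deg_use_q: bool = False,
    q_threshold: float = 0.05,
) -> ModuleCharacterization:
    """Run the full characterization battery on one labeling."""
    degs = deg_lists_by_direction(de_results, alpha=deg_alpha, use_q=deg_use_q)
    deg_table, flags = selection_responsive_modules(
        labels, degs, universe, q_threshold=q_threshold)
    marker_table, cell_types = cell_type_assignment(
        labels, markers, universe, q_threshold=q_threshold)
    anova = eigengene_region_anova(eigengenes, metadata)
    gs_tables = {}
    for name, coll in (gene_sets or {}).items():
        gs_tables[name] = geneset_enrichment(labels, coll, universe,
                                             q_threshold=q_threshold)
    return ModuleCharacterization(
        deg_enrichment=deg_table,
        selection_responsive=flags,
        marker_enrichment=marker_table,
        cell_types=cell_types,
        anova=anova,
        geneset_tables=gs_tables,
    )
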