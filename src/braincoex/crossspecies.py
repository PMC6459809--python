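"""Cross-species (or cross-study) comparison of module networks.

Two labelings are compared on a shared ortholog universe: for every module
pair across the two networks, the membership overlap is tested with the
upper-tail hypergeometric distribution, and significant pairs (raw
p below a threshold, default 0.001) form the edges of a bipartite
meta-network weighted by -log10 p.  A module is "conserved" when it keeps
at least one edge.  Conserved modules are then prioritized by four
criteria: selection-responsive, conserved, cell-type-specific, and
connected to a partner module that is both alcohol-related and
cell-type-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datasets import OrthologMap
from .network import GREY

#: floor for p-values when taking -log10 (p = 0 from underflow)
MIN_P = 1e-300


@dataclass
class MappingReport:
    n_input: int
    n_mapped: int
    n_unmapped: int
    n_ambiguous_dropped: int


def map_orthologs(
    gene_ids, ortholog_map: OrthologMap
) -> tuple[dict[str, str], MappingReport]:
    """Translate ids through the map after one-to-one resolution.

    Returns (source -> target for the mappable inputs, report counting
    unmapped inputs and pairs dropped as ambiguous).
    """
    if len(ortholog_map) == 0:
        raise ValueError("empty ortholog map")
    resolved = ortholog_map.resolve_one_to_one()
    lookup = dict(resolved.pairs)
    gene_ids = list(gene_ids)
    mapped = {g: lookup[g] for g in gene_ids if g in lookup}
    report = MappingReport(
        n_input=len(gene_ids),
        n_mapped=len(mapped),
        n_unmapped=len(gene_ids) - len(mapped),
        n_ambiguous_dropped=resolved.n_ambiguous,
    )
    return mapped, report


@dataclass
class OverlapNetwork:
    """Bipartite module-module meta-network between two labelings."""

    graph: nx.Graph
    edges: pd.DataFrame        # module_a, module_b, k, n_a, n_b, p, weight
    all_pairs: pd.DataFrame    # every tested pair (pre-threshold)
    universe_size: int
    p_threshold: float
    network_ids: tuple[str, str] = ("A", "B")
    mapping_report: MappingReport | None = None

    def conserved_modules(self, network_id: str) -> list[str]:
        col = "module_a" if network_id == self.network_ids[0] else "module_b"
        return sorted(self.edges[col].unique())

    def top_partner(self, network_id: str, module: str) -> str | None:
        """Partner module with the largest edge weight, or None."""
        a_first = network_id == self.network_ids[0]
        col, other = ("module_a", "module_b") if a_first else ("module_b",
                                                               "module_a")
        sub = self.edges[self.edges[col] == module]
        if sub.empty:
            return None
        return sub.loc[sub["weight"].idxmax(), other]

    def write_edge_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def module_overlap_network(
    labels_a: pd.Series,
    labels_b: pd.Series,
    ortholog_map: OrthologMap | None = None,
    p_threshold: float = 1e-3,
    network_ids: tuple[str, str] = ("A", "B"),
    species: tuple[str, str] = ("mouse", "human"),
    node_flags: dict[tuple[str, str], dict] | None = None,
    correct_fdr: bool = False,
) -> OverlapNetwork:
    """Hypergeometric internetwork module overlap on the shared universe.

    ``labels_a`` ids are translated through the ortholog map (identity if
    None); the shared universe is the intersection of the mapped A genes
    with the B genes, and each (module a, module b) pair is tested for
    membership overlap.  Edges with p below ``p_threshold`` are retained
    with weight -log10 p.  ``correct_fdr=True`` thresholds BH q instead of
    raw p.  ``node_flags`` attaches attributes (e.g. cell_type_specific,
    alcohol_related) to (network id, module) nodes.
    """
    report = None
    if ortholog_map is not None:
        mapped, report = map_orthologs(labels_a.index, ortholog_map)
        labels_a = pd.Series(
            {mapped[g]: m for g, m in labels_a.items() if g in mapped},
            name=labels_a.name)
    shared = labels_a.index.intersection(labels_b.index)
    if len(shared) == 0:
        raise ValueError("empty shared universe after ortholog mapping")
    la = labels_a.loc[shared]
    lb = labels_b.loc[shared]
    big_n = len(shared)

    mods_a = {m: set(la.index[la == m]) for m in sorted(la.unique())
              if m != GREY}
    mods_b = {m: set(lb.index[lb == m]) for m in sorted(lb.unique())
              if m != GREY}
    rows = []
    for ma, ga in mods_a.items():
        for mb, gb in mods_b.items():
            k = len(ga & gb)
            p = float(stats.hypergeom.sf(k - 1, big_n, len(gb), len(ga)))
            rows.append((ma, mb, len(ga), len(gb), k, min(max(p, 0.0), 1.0)))
    pairs = pd.DataFrame(
        rows, columns=["module_a", "module_b", "n_a", "n_b", "k", "p"])
    if correct_fdr and len(pairs):
        from .de import bh_fdr
        pairs["q"] = bh_fdr(pairs["p"].to_numpy())
        retained = pairs[pairs["q"] < p_threshold].copy()
    else:
        retained = pairs[pairs["p"] < p_threshold].copy()
    retained["weight"] = -np.log10(np.maximum(retained["p"], MIN_P))
    retained = retained.sort_values("weight", ascending=False,
                                    kind="mergesort").reset_index(drop=True)

    g = nx.Graph()
    ia, ib = network_ids
    for m in mods_a:
        g.add_node(f"{ia}:{m}", network=ia, module=m, species=species[0])
    for m in mods_b:
        g.add_node(f"{ib}:{m}", network=ib, module=m, species=species[1])
    for (net, mod), attrs in (node_flags or {}).items():
        node = f"{net}:{mod}"
        if node in g:
            for key, val in attrs.items():
                g.nodes[node][key] = (bool(val) if isinstance(val, (bool, np.bool_))
                                      else val)
    for _, row in retained.iterrows():
        g.add_edge(f"{ia}:{row.module_a}", f"{ib}:{row.module_b}",
                   weight=float(row.weight), overlap=int(row.k),
                   p=float(row.p))
    return OverlapNetwork(graph=g, edges=retained, all_pairs=pairs,
                          universe_size=big_n, p_threshold=p_threshold,
                          network_ids=network_ids, mapping_report=report)


# ---------------------------------------------------------------------------
# four-criteria prioritization
# ---------------------------------------------------------------------------
@dataclass
class PrioritizedModule:
    module: str
    selection_responsive: bool
    conserved: bool
    cell_type_specific: bool
    cell_types: str
    partner_evidence: list[str] = field(default_factory=list)

    @property
    def passes(self) -> bool:
        return (self.selection_responsive and self.conserved
                and self.cell_type_specific and bool(self.partner_evidence))


def prioritize_conserved_modules(
    flags: pd.DataFrame,
    overlap: OverlapNetwork,
    partner_flags: pd.DataFrame,
) -> tuple[list[PrioritizedModule], pd.DataFrame]:
    """Modules satisfying all four criteria, with per-criterion evidence.

    ``flags`` indexes the first network's modules and must carry
    ``selection_responsive``, ``cell_type_specific`` and ``cell_types``
    columns; ``partner_flags`` indexes the partner network's modules and
    must carry ``alcohol_related`` and ``cell_type_specific``.  A partner
    edge counts as evidence when the partner module has both flags.
    """
    for col in ("selection_responsive", "cell_type_specific"):
        if col not in flags.columns:
            raise ValueError(f"flags table is missing column {col!r}")
    for col in ("alcohol_related", "cell_type_specific"):
        if col not in partner_flags.columns:
            raise ValueError(f"partner_flags table is missing column {col!r}")
    conserved = set(overlap.conserved_modules(overlap.network_ids[0]))
    records = []
    for module, row in flags.iterrows():
        partners = overlap.edges.loc[
            overlap.edges["module_a"] == module, "module_b"]
        evidence = []
        for p in partners:
            if p in partner_flags.index:
                prow = partner_flags.loc[p]
                if bool(prow["alcohol_related"]) and bool(
                        prow["cell_type_specific"]):
                    evidence.append(p)
        records.append(PrioritizedModule(
            module=module,
            selection_responsive=bool(row["selection_responsive"]),
            conserved=module in conserved,
            cell_type_specific=bool(row["cell_type_specific"]),
            cell_types=str(row.get("cell_types", "")),
            partner_evidence=sorted(evidence),
        ))
    table = pd.DataFrame([{
        "module": r.module,
        "selection_responsive": r.selection_responsive,
        "conserved": r.conserved,
        "cell_type_specific": r.cell_type_specific,
        "alcohol_related_partners": ";".join(r.partner_evidence),
        "passes_all": r.passes,
    } for r in records]).set_index("module")
    selected = [r for r in records if r.passes]
    return selected, table
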