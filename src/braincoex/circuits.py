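"""Circuit-level hypotheses from multi-region module regulation patterns.

A neuron-specific, selection-responsive module regulated in two or more
brain regions suggests either a direct anatomical connection between
those regions or a common upstream driver.  Each module is first given a
per-region regulation call (up / down / mixed / none) from its per-region,
per-direction DEG over-representation q-values; ordered region pairs that
are both regulated and present as edges in an anatomical connectivity
table become ranked circuit hypotheses, scored by the combined enrichment
evidence -log10 q(r1) - log10 q(r2).  Co-regulated pairs absent from the
table are emitted separately as common-upstream candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import REGION_COL

#: floor for q-values when taking -log10
MIN_Q = 1e-300


# ---------------------------------------------------------------------------
# anatomical connectivity table
# ---------------------------------------------------------------------------
@dataclass
class ConnectivityTable:
    """Directed region -> region edges with free-text annotation."""

    edges: pd.DataFrame  # source, target, annotation, citation

    def __post_init__(self) -> None:
        need = {"source", "target"}
        if not need.issubset(self.edges.columns):
            raise ValueError("connectivity table needs 'source' and 'target'")
        for col in ("annotation", "citation"):
            if col not in self.edges.columns:
                self.edges[col] = ""

    def has_edge(self, source: str, target: str) -> bool:
        e = self.edges
        return bool(((e["source"] == source) & (e["target"] == target)).any())

    def edge_annotation(self, source: str, target: str) -> str:
        e = self.edges
        sel = (e["source"] == source) & (e["target"] == target)
        if not sel.any():
            return ""
        return str(e.loc[sel, "annotation"].iloc[0])

    def regions(self) -> set[str]:
        return set(self.edges["source"]) | set(self.edges["target"])

    def validate_regions(self, vocabulary) -> None:
        unknown = self.regions() - set(vocabulary)
        if unknown:
            raise ValueError(
                "connectivity table references regions outside the dataset "
                "vocabulary: " + ", ".join(sorted(unknown)))

    def write_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ConnectivityTable":
        return cls(edges=pd.read_csv(path, sep="\t", dtype=str).fillna(""))

    @classmethod
    def default(cls) -> "ConnectivityTable":
        """The editable fixture table shipped for the seven study regions."""
        with resources.files("braincoex.data").joinpath(
                "connectivity_default.tsv").open() as fh:
            return cls(edges=pd.read_csv(fh, sep="\t", dtype=str).fillna(""))


# ---------------------------------------------------------------------------
# per-module, per-region regulation profiles
# ---------------------------------------------------------------------------
@dataclass
class ModuleRegionProfile:
    """Regulation call and relative expression per region for one module."""

    module: str
    #: region -> call in {"up", "down", "mixed", "none"}
    calls: dict[str, str]
    #: region -> best (smallest) significant q, NaN if none
    best_q: dict[str, float]
    #: region -> rank of region-mean eigengene (1 = highest expression)
    expression_rank: dict[str, int]
    #: genes that are both hubs of the module and DEGs somewhere
    marker_genes: list[str] = field(default_factory=list)

    def regulated_regions(self) -> list[str]:
        return [r for r, c in self.calls.items() if c != "none"]


def _call_one(q_up: float, q_down: float, threshold: float) -> tuple[str, float]:
    up = q_up < threshold
    down = q_down < threshold
    if up and down:
        if q_up == q_down:
            return "mixed", q_up
        return ("up", q_up) if q_up < q_down else ("down", q_down)
    if up:
        return "up", q_up
    if down:
        return "down", q_down
    return "none", float("nan")


def module_region_profiles(
    deg_enrichment: pd.DataFrame,
    eigengenes: pd.DataFrame,
    metadata: pd.DataFrame,
    hub_genes: dict[str, list[str]] | None = None,
    deg_union: set[str] | None = None,
    q_threshold: float = 0.05,
) -> dict[str, ModuleRegionProfile]:
    """Derive per-region regulation calls and expression ranks per module.

    ``deg_enrichment`` is the module x (region_direction) table from
    ``selection_responsive_modules`` (columns module, set, q with set
    names like ``'BLA_up'``).  The call per region: the direction with the
    more significant q wins when below the threshold; both directions
    significant with equal q gives "mixed".  Expression rank is the
    descending rank of the region-mean eigengene.  Marker genes are the
    module's hub genes that are DEGs anywhere (``deg_union``).
    """
    regions = list(dict.fromkeys(metadata[REGION_COL]))
    split = deg_enrichment["set"].str.rsplit("_", n=1)
    region_col = split.str[0]
    direction_col = split.str[1]
    profiles: dict[str, ModuleRegionProfile] = {}
    for module in sorted(deg_enrichment["module"].unique()):
        sub = deg_enrichment["module"] == module
        calls, best_q = {}, {}
        for region in regions:
            q_up = q_down = float("inf")
            m_up = sub & (region_col == region) & (direction_col == "up")
            m_down = sub & (region_col == region) & (direction_col == "down")
            if m_up.any():
                q_up = float(deg_enrichment.loc[m_up, "q"].iloc[0])
            if m_down.any():
                q_down = float(deg_enrichment.loc[m_down, "q"].iloc[0])
            calls[region], best_q[region] = _call_one(q_up, q_down,
                                                      q_threshold)
        rank: dict[str, int] = {}
        if module in eigengenes.index:
            e = eigengenes.loc[module]
            means = pd.Series(
                {r: e[metadata.index[metadata[REGION_COL] == r]].mean()
                 for r in regions})
            ranked = means.rank(ascending=False, method="first").astype(int)
            rank = ranked.to_dict()
        markers: list[str] = []
        if hub_genes and module in hub_genes:
            hubs = hub_genes[module]
            markers = (sorted(set(hubs) & deg_union)
                       if deg_union is not None else list(hubs))
        profiles[module] = ModuleRegionProfile(
            module=module, calls=calls, best_q=best_q,
            expression_rank=rank, marker_genes=markers)
    return profiles


# ---------------------------------------------------------------------------
# hypotheses
# ---------------------------------------------------------------------------
@dataclass
class CircuitHypothesis:
    module: str
    source: str
    target: str
    score: float
    source_call: str
    target_call: str
    marker_genes: list[str]
    annotation: str = ""
    #: free-text slot for manual upstream-regulator notes
    upstream_note: str = ""
    kind: str = "connection"  # or "common_upstream"


def candidate_connections(
    profiles: dict[str, ModuleRegionProfile],
    table: ConnectivityTable | None,
    neuron_flags: pd.Series | None = None,
    selection_flags: pd.Series | None = None,
) -> tuple[list[CircuitHypothesis], list[CircuitHypothesis]]:
    """Ranked circuit hypotheses for neuron-flagged, selection-responsive
    modules.

    For each eligible module and each ordered region pair (r1, r2) with
    both regions regulated and a table edge r1 -> r2, a hypothesis is
    emitted with score -log10 q(r1) - log10 q(r2).  Co-regulated
    (unordered) pairs with no table edge in either direction become
    common-upstream candidates.  Both lists are sorted by descending
    score with deterministic tie-breaks.
    """
    if table is not None and table.edges.empty:
        table = None
    if table is None:
        warnings.warn("empty connectivity table: only common-upstream "
                      "candidates will be produced")
    hypotheses: list[CircuitHypothesis] = []
    upstream: list[CircuitHypothesis] = []
    for module in sorted(profiles):
        if neuron_flags is not None and not bool(
                neuron_flags.get(module, False)):
            continue
        if selection_flags is not None and not bool(
                selection_flags.get(module, False)):
            continue
        prof = profiles[module]
        regs = prof.regulated_regions()
        seen_unordered: set[frozenset] = set()
        for r1 in regs:
            for r2 in regs:
                if r1 == r2:
                    continue
                score = float(-np.log10(max(prof.best_q[r1], MIN_Q))
                              - np.log10(max(prof.best_q[r2], MIN_Q)))
                if table is not None and table.has_edge(r1, r2):
                    hypotheses.append(CircuitHypothesis(
                        module=module, source=r1, target=r2, score=score,
                        source_call=prof.calls[r1],
                        target_call=prof.calls[r2],
                        marker_genes=prof.marker_genes,
                        annotation=table.edge_annotation(r1, r2)))
                else:
                    pair = frozenset((r1, r2))
                    direct = table is not None and (
                        table.has_edge(r1, r2) or table.has_edge(r2, r1))
                    if pair not in seen_unordered and not direct:
                        seen_unordered.add(pair)
                        a, b = sorted(pair)
                        upstream.append(CircuitHypothesis(
                            module=module, source=a, target=b, score=score,
                            source_call=prof.calls[a],
                            target_call=prof.calls[b],
                            marker_genes=prof.marker_genes,
                            kind="common_upstream"))
    key = lambda h: (-h.score, h.module, h.source, h.target)
    return sorted(hypotheses, key=key), sorted(upstream, key=key)


def hypotheses_table(hypotheses, upstream=()) -> pd.DataFrame:
    rows = [{
        "module": h.module, "source": h.source, "target": h.target,
        "score": h.score, "source_call": h.source_call,
        "target_call": h.target_call,
        "marker_genes": ";".join(h.marker_genes),
        "annotation": h.annotation, "upstream_note": h.upstream_note,
        "kind": h.kind,
    } for h in list(hypotheses) + list(upstream)]
    return pd.DataFrame(rows, columns=[
        "module", "source", "target", "score", "source_call", "target_call",
        "marker_genes", "annotation", "upstream_note", "kind"])


def region_graph(
    hypotheses, table: ConnectivityTable | None = None
) -> nx.MultiDiGraph:
    """Region-level directed graph with one edge per hypothesis."""
    g = nx.MultiDiGraph()
    if table is not None:
        for r in sorted(table.regions()):
            g.add_node(r)
    for h in hypotheses:
        g.add_edge(h.source, h.target, module=h.module, score=float(h.score),
                   source_call=h.source_call, target_call=h.target_call,
                   kind=h.kind)
    return g
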