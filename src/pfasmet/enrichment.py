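"""Pathway over-representation analysis and topology impact.

Works against a user-supplied pathway library (pathway -> member compound
ids over a background of all detectable compounds, optionally with a
per-pathway reaction graph).  Enrichment is the one-sided Fisher
(hypergeometric tail) test with Benjamini-Hochberg correction; the
topology impact of a pathway is the fraction of its total betweenness
centrality carried by the matched compounds.  No pathway database content
is bundled — database versions and background choice dominate printed
p-values, so the library is an explicit input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats as sps

from .stats import benjamini_hochberg


@dataclass
class PathwayLibrary:
    """Pathways, their optional graphs, and the detectable background."""

    pathways: dict                      # pathway id -> set of compound ids
    background: set
    graphs: dict = field(default_factory=dict)  # pathway id -> nx.Graph

    def __post_init__(self) -> None:
        self.pathways = {k: set(v) for k, v in self.pathways.items()}
        self.background = set(self.background)
        for pid, members in self.pathways.items():
            extra = members - self.background
            if extra:
                raise ValueError(f"pathway {pid} has members outside the "
                                 f"background: {sorted(extra)[:5]}")

    @classmethod
    def from_json(cls, path) -> "PathwayLibrary":
        payload = json.loads(Path(path).read_text())
        graphs = {}
        for pid, edges in payload.get("edges", {}).items():
            g = nx.Graph()
            g.add_nodes_from(payload["pathways"][pid])
            g.add_edges_from(edges)
            graphs[pid] = g
        return cls(pathways=payload["pathways"],
                   background=payload["background"], graphs=graphs)

    def to_json(self, path) -> None:
        payload = {
            "pathways": {k: sorted(v) for k, v in self.pathways.items()},
            "background": sorted(self.background),
            "edges": {pid: sorted(map(sorted, g.edges()))
                      for pid, g in self.graphs.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class EnrichmentResult:
    pathway: str
    overlap: int
    size: int
    p: float
    fdr: float = float("nan")
    impact: float = float("nan")
    significant: bool = False


def ora_fisher(selected, library: PathwayLibrary, *, fdr_alpha: float = 0.05,
               impact_threshold: float = 0.2, with_topology: bool = False
               ) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation of the selected compounds.

    Per pathway the p-value is the hypergeometric upper tail
    P(overlap >= observed) over the background; BH correction runs across
    pathways.  With topology requested, a pathway is significant when
    FDR < 0.05 and impact > 0.2; otherwise FDR < 0.05 alone.
    """
    selected = set(selected)
    stray = selected - library.background
    if stray:
        warnings.warn(f"{len(stray)} selected compounds outside the background "
                      "were dropped")
        selected &= library.background
    M = len(library.background)
    N = len(selected)
    results = []
    for pid, members in library.pathways.items():
        K = len(members)
        k = len(selected & members)
        # upper tail at the observed overlap; equals 1 when k == 0
        p = float(sps.hypergeom.sf(k - 1, M, K, N)) if N else 1.0
        impact = float("nan")
        if with_topology and pid in library.graphs:
            impact = topology_impact(library.graphs[pid], selected & members)
        results.append(EnrichmentResult(pathway=pid, overlap=k, size=K, p=p,
                                        impact=impact))
    qs = benjamini_hochberg([r.p for r in results])
    for r, q in zip(results, qs):
        r.fdr = float(q)
        if with_topology and np.isfinite(r.impact):
            r.significant = bool(q < fdr_alpha and r.impact > impact_threshold)
        else:
            r.significant = bool(q < fdr_alpha)
    return results


def topology_impact(graph: nx.Graph, matched) -> float:
    """Fraction of the pathway graph's betweenness carried by matched nodes.

    Betweenness is computed exactly on the undirected unweighted graph;
    graphs whose total centrality is zero (e.g. complete or trivial graphs)
    return 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("pathway graph is empty")
    matched = set(matched)
    stray = matched - set(graph.nodes)
    if stray:
        warnings.warn(f"{len(stray)} matched compounds absent from the pathway "
                      "graph were ignored")
        matched &= set(graph.nodes)
    bc = nx.betweenness_centrality(graph, normalized=True)
    total = sum(bc.values())
    if total == 0:
        return 0.0
    return float(sum(bc[n] for n in matched) / total)
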