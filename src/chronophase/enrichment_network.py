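"""Over-representation analysis and interaction-network neighbourhoods.

Gene-set enrichment of a hit list is scored with the upper-tail
hypergeometric test (the classic ORA), adjusted across sets with
Benjamini-Hochberg.  Protein-protein interaction tables in PSI-MI TAB
(mitab) format, as distributed by BioGRID, are parsed into an undirected
graph from which the first-neighbour subnetwork around a seed list (e.g.
differentially expressed genes) can be cut out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "InteractionGraph",
    "OraResult",
    "hypergeometric_ora",
    "bh_fdr",
    "parse_mitab",
    "read_gmt",
    "first_neighbor_subnetwork",
]


@dataclass(frozen=True)
class GeneSet:
    """A named annotation category (GO term, pathway, ...) with its members."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass
class InteractionGraph:
    """Undirected gene/protein interaction network.

    Edges are deduplicated unordered pairs without self-loops;
    ``n_self_loops_dropped`` and ``n_rows_skipped`` carry parse provenance.
    """

    graph: nx.Graph
    n_self_loops_dropped: int = 0
    n_rows_skipped: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class OraResult:
    set_id: str
    overlap: int
    set_size: int
    n_hits: int
    universe_size: int
    p_value: float
    fold_enrichment: float


def hypergeometric_ora(
    hits: Iterable[str], annotation: GeneSet, universe: Iterable[str]
) -> OraResult:
    """Upper-tail hypergeometric enrichment of *annotation* in *hits*.

    With universe size N, annotation size K (after intersecting with the
    universe), draw size n = |hits| and overlap k, the p-value is the
    inclusive tail P(X >= k); fold enrichment is (k/n)/(K/N).
    """
    hits = set(hits)
    universe = set(universe)
    stray = hits - universe
    if stray:
        raise ValueError(f"hits not in universe: {sorted(stray)}")
    members = set(annotation.members) & universe
    N, K, n = len(universe), len(members), len(hits)
    k = len(hits & members)
    # sf(k-1) = P(X >= k); P(X >= 0) = 1 by convention
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return OraResult(
        set_id=annotation.set_id,
        overlap=k,
        set_size=K,
        n_hits=n,
        universe_size=N,
        p_value=min(p, 1.0),
        fold_enrichment=fold,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(source: TextIO) -> list[GeneSet]:
    """Parse GMT lines ``set_id <tab> description <tab> gene1 <tab> gene2 ...``."""
    sets = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: need id, name and >= 1 member")
        sets.append(
            GeneSet(set_id=fields[0], name=fields[1], members=frozenset(f for f in fields[2:] if f))
        )
    return sets


def _mitab_identifier(field_value: str, strip_db_prefix: bool) -> str | None:
    field_value = field_value.strip()
    if not field_value or field_value == "-":
        return None
    first = field_value.split("|")[0]
    if strip_db_prefix and ":" in first:
        first = first.split(":", 1)[1]
    return first or None


def parse_mitab(
    source: TextIO,
    id_columns: tuple[int, int] = (0, 1),
    strip_db_prefix: bool = True,
) -> InteractionGraph:
    """Parse a PSI-MI TAB 2.5 stream into an :class:`InteractionGraph`.

    *id_columns* selects which mitab columns provide the two interactor
    identifiers (0/1 = unique ids, 2/3 = alternative ids, 4/5 = aliases —
    the BioGRID dialect puts gene identifiers in the alternative-id columns).
    Database prefixes like ``entrez gene/locuslink:`` are stripped by
    default; when a field lists several identifiers the first is used.
    Duplicate pairs collapse to one undirected edge; self-interactions are
    dropped and counted; rows lacking either identifier are skipped and
    counted.
    """
    g = nx.Graph()
    self_loops = 0
    skipped = 0
    ca, cb = id_columns
    for line in source:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) <= max(ca, cb):
            skipped += 1
            continue
        a = _mitab_identifier(fields[ca], strip_db_prefix)
        b = _mitab_identifier(fields[cb], strip_db_prefix)
        if a is None or b is None:
            skipped += 1
            continue
        if a == b:
            self_loops += 1
            continue
        g.add_edge(a, b)
    return InteractionGraph(graph=g, n_self_loops_dropped=self_loops, n_rows_skipped=skipped)


def first_neighbor_subnetwork(
    graph: InteractionGraph | nx.Graph, seeds: Iterable[str]
) -> dict:
    """Induced subgraph on the seeds present in the graph plus their direct
    neighbours.

    Returns the subgraph together with the counts conventionally reported for
    such networks: seed nodes found, distinct first neighbours, and edges of
    the induced subgraph (all parent-graph edges among the selected nodes,
    including neighbour-neighbour edges).  Seeds absent from the graph are
    allowed and simply contribute nothing.
    """
    g = graph.graph if isinstance(graph, InteractionGraph) else graph
    seeds = set(seeds)
    present = seeds & set(g.nodes)
    neighbors: set[str] = set()
    for s in present:
        neighbors.update(g.neighbors(s))
    neighbors -= present
    nodes = present | neighbors
    sub = g.subgraph(nodes).copy()
    return {
        "subgraph": sub,
        "n_seed_nodes_present": len(present),
        "n_first_neighbors": len(neighbors),
        "n_edges": sub.number_of_edges(),
    }
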