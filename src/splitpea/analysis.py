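"""Summary statistics, multi-network consensus, and gene ranking.

Conventions (documented because the quantities have no single standard
definition):

* **degree** counts distinct incident rewired edges; a self-loop adds 1
  (the gene "interacts with itself" once).
* **normalized degree** defaults to degree / total number of edges in the
  network (``norm="edges"``); ``norm="nodes"`` divides by (n_nodes − 1)
  instead.
* **edge composition** is the per-gene count of incident gain/loss/chaos
  edges; it sums to the gene's degree.
* consensus edge identity is the unordered gene pair only — categories may
  differ between networks and are reported per network, never merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .exceptions import SplitpeaError
from .rewire import CHAOS, GAIN, LOSS, RewiredNetwork

logger = logging.getLogger("splitpea")

_CATEGORIES = (GAIN, LOSS, CHAOS)


@dataclass
class NetworkStats:
    """Edge counts by category plus per-gene degree/composition table.

    ``per_gene`` columns: degree, normalized_degree, gain, loss, chaos;
    rows sorted by degree descending, then gene id ascending.
    """

    edge_counts: dict[str, int]
    per_gene: pd.DataFrame
    n_nodes: int = 0

    @property
    def total_edges(self) -> int:
        return sum(self.edge_counts.values())


def network_stats(net: RewiredNetwork,
                  norm: Literal["edges", "nodes"] = "edges") -> NetworkStats:
    """Exact summary counts for a rewired network (zeros + warning if empty)."""
    counts = net.counts_by_category()
    total = sum(counts.values())
    if total == 0:
        logger.warning("network_stats: empty network")
        empty = pd.DataFrame(columns=["degree", "normalized_degree", *_CATEGORIES])
        empty.index.name = "gene"
        return NetworkStats(counts, empty, 0)
    rows: dict[str, dict[str, float]] = {}
    for edge in net.edges.values():
        for gene in set(edge.pair):  # self-loop touches its gene once
            rec = rows.setdefault(gene, {"degree": 0, GAIN: 0, LOSS: 0, CHAOS: 0})
            rec["degree"] += 1
            rec[edge.category] += 1
    per_gene = pd.DataFrame.from_dict(rows, orient="index")
    denom = total if norm == "edges" else max(len(rows) - 1, 1)
    per_gene["normalized_degree"] = per_gene["degree"] / denom
    per_gene = per_gene[["degree", "normalized_degree", *_CATEGORIES]]
    per_gene = per_gene.sort_values(["degree"], ascending=False, kind="mergesort")
    per_gene = per_gene.loc[
        sorted(per_gene.index, key=lambda g: (-per_gene.at[g, "degree"], g))]
    per_gene.index.name = "gene"
    return NetworkStats(counts, per_gene, len(rows))


@dataclass
class ConsensusNetwork:
    """Union of edges across networks with per-edge conservation counts.

    ``table`` is indexed by the unordered gene pair with columns ``count``
    (number of networks containing the pair) and ``categories`` (the
    per-network category, ``None`` where absent).  ``filtered`` restricts
    to pairs with count >= ``min_count``.
    """

    table: pd.DataFrame
    n_networks: int
    min_count: int = 2
    _filtered: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def filtered(self) -> pd.DataFrame:
        if self._filtered is None:
            self._filtered = self.table[self.table["count"] >= self.min_count]
        return self._filtered


def consensus(nets: Sequence[RewiredNetwork], min_count: int = 2) -> ConsensusNetwork:
    """Tally edge conservation across >=2 rewired networks."""
    if len(nets) < 2:
        raise SplitpeaError("consensus requires at least two networks")
    pairs = sorted({pair for net in nets for pair in net.edges})
    rows = []
    for pair in pairs:
        cats = tuple(net.edges[pair].category if pair in net.edges else None
                     for net in nets)
        rows.append({"gene_a": pair[0], "gene_b": pair[1],
                     "count": sum(c is not None for c in cats),
                     "categories": cats})
    table = pd.DataFrame(rows)
    table = table.set_index(pd.MultiIndex.from_frame(table[["gene_a", "gene_b"]]))
    table = table[["count", "categories"]]
    return ConsensusNetwork(table, n_networks=len(nets), min_count=min_count)


def rank_genes(net: RewiredNetwork, by: Literal["gain", "loss"],
               include_zero: bool = False,
               norm: Literal["edges", "nodes"] = "edges") -> list[str]:
    """Rank genes by their count of gain (or loss) edges.

    Descending by the chosen count; ties broken by normalized degree
    (descending), then raw degree (descending), then gene id (ascending)
    for full determinism.  Genes with zero edges of the chosen category
    are appended only when ``include_zero`` is set.
    """
    if by not in (GAIN, LOSS):
        raise ValueError("rank_genes: 'by' must be 'gain' or 'loss'")
    stats = network_stats(net, norm=norm)
    df = stats.per_gene
    if df.empty:
        return []
    genes = list(df.index) if include_zero else [g for g in df.index if df.at[g, by] > 0]
    return sorted(genes, key=lambda g: (-df.at[g, by],
                                        -df.at[g, "normalized_degree"],
                                        -df.at[g, "degree"],
                                        g))
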