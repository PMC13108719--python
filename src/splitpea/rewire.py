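"""Core rewiring algorithm: exons → affected Pfam domains → rewired PPI edges.

The pipeline, in order:

1. **Exon → domain mapping.**  Each significance-filtered skipped-exon
   event is intersected (half-open, strand-aware, ≥1 shared base) with the
   genomic footprints of Pfam domain instances.  When several exons hit
   the same (gene, domain) the domain receives the *signed minimum* of
   their ΔPSI values — the most-negative change dominates, on the
   rationale that even partial loss of a domain can impair its
   interaction capacity.  (``agg="max-abs"`` keeps the largest-magnitude
   change instead, for sensitivity analyses.)

2. **DDI mediation.**  A reference PPI between genes A and B is
   *domain-mediated* if some Pfam pair (d_a ∈ domains(A), d_b ∈
   domains(B)) is in the DDI catalog.  Only mediating pairs can transmit
   a splicing change onto the edge.

3. **Edge classification and weighting.**  An edge is reported when at
   least one mediating pair involves an affected domain.  The
   contributing ΔPSI values are those of every affected domain that
   participates in ≥1 mediating pair of the edge — each affected domain
   counted once per edge by default (``per_pair_weighting=True`` counts
   it once per mediating pair instead).  The edge is a **gain** if all
   contributions are positive, a **loss** if all are negative, **chaos**
   if mixed; its weight is the arithmetic mean of the contributions.
   Domains whose aggregated ΔPSI is exactly zero are directionless and
   never contribute.

Self-interactions (homodimer PPIs) are computed and stored; their
exclusion is a plotting/export concern.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .exceptions import SplitpeaError
from .reference_data import DDICatalog, DomainIndex, PPINetwork, unordered
from .splice_io import SpliceEvent

logger = logging.getLogger("splitpea")

GAIN, LOSS, CHAOS = "gain", "loss", "chaos"

Category = Literal["gain", "loss", "chaos"]


@dataclass(frozen=True)
class AffectedDomain:
    """A (gene, Pfam) pair hit by ≥1 significant skipped-exon event.

    ``delta_psi`` is the aggregate over contributing exon-level values
    (signed minimum by default); ``contributing_events`` records each
    event id with its exon-level ΔPSI.
    """

    gene_id: str
    pfam_id: str
    delta_psi: float
    contributing_events: tuple[tuple[str, float], ...]


@dataclass
class RewiredEdge:
    """One classified, weighted PPI edge (gene pair stored sorted)."""

    gene_a: str
    gene_b: str
    category: Category
    weight: float
    mediating_pairs: tuple[tuple[str, str], ...] = ()
    contributing_deltas: tuple[tuple[str, str, float], ...] = ()  # (gene, pfam, ΔPSI)
    n_contributing: int = 0

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    @property
    def is_self_loop(self) -> bool:
        return self.gene_a == self.gene_b


@dataclass
class RewiredNetwork:
    """Rewired, weighted PPI network plus run metadata and report counts."""

    edges: dict[tuple[str, str], RewiredEdge] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges.values():
            out.update(e.pair)
        return out

    def add(self, edge: RewiredEdge) -> None:
        key = unordered(edge.gene_a, edge.gene_b)
        if key in self.edges:
            raise SplitpeaError(f"duplicate rewired edge {key}")
        self.edges[key] = edge

    def counts_by_category(self) -> dict[str, int]:
        counts = {GAIN: 0, LOSS: 0, CHAOS: 0}
        for e in self.edges.values():
            counts[e.category] += 1
        return counts

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Step 1: exon → domain mapping
# ---------------------------------------------------------------------------

def map_events_to_domains(events: Iterable[SpliceEvent], index: DomainIndex,
                          agg: Literal["min", "max-abs"] = "min") -> list[AffectedDomain]:
    """Map events onto domain annotations by genomic overlap and aggregate
    per (gene, Pfam) group.

    An event contributes to every annotation whose (chrom, strand) matches
    and whose any coding segment overlaps the skipped exon.  ``agg="min"``
    assigns the signed minimum exon-level ΔPSI; ``"max-abs"`` the value of
    largest magnitude (ties to the more negative).
    """
    groups: dict[tuple[str, str], list[tuple[str, float]]] = defaultdict(list)
    n_no_overlap = 0
    for ev in events:
        hits = index.query(ev.chrom, ev.strand, ev.exon_start, ev.exon_end)
        if not hits:
            n_no_overlap += 1
            continue
        seen: set[tuple[str, str]] = set()
        for ann in hits:
            key = (ann.gene_id, ann.pfam_id)
            if key in seen:  # several instances of one domain family in a gene
                continue
            seen.add(key)
            groups[key].append((ev.event_id, ev.delta_psi))
    out = []
    for (gene, pfam), contribs in sorted(groups.items()):
        deltas = [d for _, d in contribs]
        if agg == "min":
            agg_delta = min(deltas)
        elif agg == "max-abs":
            agg_delta = min(deltas, key=lambda d: (-abs(d), d))
        else:
            raise ValueError(f"unknown aggregation {agg!r}")
        out.append(AffectedDomain(gene, pfam, agg_delta, tuple(contribs)))
    if n_no_overlap:
        logger.info("map_events_to_domains: %d events overlapped no domain", n_no_overlap)
    return out


# ---------------------------------------------------------------------------
# Step 2: DDI mediation
# ---------------------------------------------------------------------------

def mediating_pairs(gene_a_domains: set[str], gene_b_domains: set[str],
                    ddi: DDICatalog) -> list[tuple[str, str]]:
    """All Pfam pairs (d_a from gene A's complement, d_b from gene B's) found
    in the DDI catalog, as sorted unordered pairs without duplicates.  An
    empty result means the PPI is not domain-mediated."""
    found = {
        unordered(da, db)
        for da in gene_a_domains
        for db in gene_b_domains
        if (da, db) in ddi
    }
    return sorted(found)


# ---------------------------------------------------------------------------
# Step 3: classification and weighting
# ---------------------------------------------------------------------------

def classify_edge(contributing_deltas: Sequence[float]) -> Category:
    """gain if all ΔPSI > 0, loss if all < 0, chaos when signs mix."""
    if not contributing_deltas:
        raise ValueError("classify_edge requires a non-empty list")
    if all(d > 0 for d in contributing_deltas):
        return GAIN
    if all(d < 0 for d in contributing_deltas):
        return LOSS
    return CHAOS


def edge_weight(contributing_deltas: Sequence[float]) -> float:
    """Arithmetic mean of the contributing domain-level ΔPSI values."""
    if not contributing_deltas:
        raise ValueError("edge_weight requires a non-empty list")
    return sum(contributing_deltas) / len(contributing_deltas)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def build_rewired_network(events: Sequence[SpliceEvent], ppi: PPINetwork,
                          ddi: DDICatalog, index: DomainIndex,
                          agg: Literal["min", "max-abs"] = "min",
                          per_pair_weighting: bool = False,
                          metadata: dict | None = None) -> RewiredNetwork:
    """Assemble the rewired network from filtered events and the references.

    For each reference PPI edge where at least one mediating DDI pair
    involves an affected domain, the edge is reported with its category and
    mean-ΔPSI weight.  ``report`` carries run counts: input events, events
    overlapping domains, affected domains, candidate (domain-mediated,
    affected) PPIs and reported edges by category.
    """
    if not ppi.edges:
        raise SplitpeaError("empty PPI reference")
    if not ddi.pairs:
        raise SplitpeaError("empty DDI catalog")
    if len(index) == 0:
        raise SplitpeaError("empty domain-coordinate index")

    affected = map_events_to_domains(events, index, agg=agg)
    # zero aggregate ΔPSI is directionless: never contributes
    delta_of: dict[tuple[str, str], float] = {
        (d.gene_id, d.pfam_id): d.delta_psi for d in affected if d.delta_psi != 0.0
    }
    affected_by_gene: dict[str, set[str]] = defaultdict(set)
    for gene, pfam in delta_of:
        affected_by_gene[gene].add(pfam)

    net = RewiredNetwork(metadata=dict(metadata or {}))
    n_candidate = 0
    for gene_a, gene_b in sorted(ppi.edges):
        if not (affected_by_gene.get(gene_a) or affected_by_gene.get(gene_b)):
            continue
        comp_a = index.domains_of(gene_a)
        comp_b = index.domains_of(gene_b)
        pairs = mediating_pairs(comp_a, comp_b, ddi)
        if not pairs:
            continue
        contribs: list[tuple[str, str, float]] = []
        used_pairs: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for da, db in pairs:
            # a pair mediates only in orientations placing one member in each gene
            participants: set[tuple[str, str]] = set()
            if da in comp_a and db in comp_b:
                participants.update({(gene_a, da), (gene_b, db)})
            if db in comp_a and da in comp_b:
                participants.update({(gene_a, db), (gene_b, da)})
            pair_hits = sorted(p for p in participants if p in delta_of)
            if not pair_hits:
                continue
            used_pairs.append((da, db))
            for gene, dom in pair_hits:
                if per_pair_weighting:
                    contribs.append((gene, dom, delta_of[(gene, dom)]))
                elif (gene, dom) not in seen:
                    seen.add((gene, dom))
                    contribs.append((gene, dom, delta_of[(gene, dom)]))
        if not used_pairs:
            continue
        n_candidate += 1
        deltas = [d for _, _, d in contribs]
        net.add(RewiredEdge(
            gene_a=gene_a, gene_b=gene_b,
            category=classify_edge(deltas),
            weight=edge_weight(deltas),
            mediating_pairs=tuple(used_pairs),
            contributing_deltas=tuple(contribs),
            n_contributing=len(contribs),
        ))

    n_events = len(events)
    overlapping = {e for d in affected for e, _ in d.contributing_events}
    net.report = {
        "n_input_events": n_events,
        "n_events_overlapping_domains": len(overlapping),
        "n_events_without_domain_overlap": n_events - len(overlapping),
        "n_affected_domains": len(affected),
        "n_candidate_ppis": n_candidate,
        "n_edges": net.counts_by_category(),
    }
    net.metadata.setdefault("agg", agg)
    net.metadata.setdefault("per_pair_weighting", per_pair_weighting)
    return net
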