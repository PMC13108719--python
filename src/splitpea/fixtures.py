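"""Deterministic toy data: reference sets, rMATS/SUPPA2 files with a planted
truth plan, and an independent brute-force oracle network.

The generators are pure functions of their :class:`ToyConfig` (same config
=> byte-identical files), which makes them usable both as pytest fixtures
and as a tutorial/demo data source (``splitpea fixtures``).

The toy genome places each gene on its own chromosome so that any
interval-arithmetic bug produces obviously wrong cross-gene overlaps
instead of silently plausible ones.  Coordinates follow the package
convention (0-based half-open) in the reference files and the rMATS
dialect, and are converted to SUPPA2's 1-based inclusive convention when
writing ``.dpsi`` event ids.

:func:`oracle_network` restates the whole rewiring computation as
exhaustive nested loops over the in-memory toy structures — including its
own Benjamini–Hochberg adjustment — sharing no code with the pipeline
modules, so agreement between the two is a genuine cross-implementation
check rather than a tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


# ---------------------------------------------------------------------------
# Configuration and toy structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyConfig:
    """Knobs for the toy generator; all outputs are functions of this."""

    n_genes: int = 12
    domains_per_gene: tuple[int, int] = (1, 3)
    segments_per_domain: tuple[int, int] = (1, 2)
    n_pfam: int = 8
    ppi_density: float = 0.35
    ddi_density: float = 0.35
    n_self_ppi: int = 0
    n_events: int = 20
    n_na: int = 0
    frac_significant: float = 0.85
    domain_hit_fraction: float = 0.7
    dpsi_range: tuple[float, float] = (0.06, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_events < 0 or self.n_pfam <= 0:
            raise ValueError("counts must be positive")
        for d in (self.ppi_density, self.ddi_density, self.frac_significant,
                  self.domain_hit_fraction):
            if not 0.0 <= d <= 1.0:
                raise ValueError("densities/fractions must be in [0,1]")


@dataclass(frozen=True)
class ToyGene:
    idx: int
    symbol: str
    entrez: str
    ensembl: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class ToyDomain:
    gene_idx: int
    pfam: str
    segments: tuple[tuple[int, int], ...]  # 0-based half-open, sorted, disjoint


@dataclass
class ToyReferences:
    genes: list[ToyGene]
    domains: list[ToyDomain]
    ppi_pairs: list[tuple[str, str]]  # gene symbols, unordered (sorted)
    ddi_pairs: list[tuple[str, str]]  # Pfam accessions, unordered (sorted)

    def gene(self, idx: int) -> ToyGene:
        return self.genes[idx]


@dataclass(frozen=True)
class PlannedEvent:
    """One planted skipped-exon event; ``dpsi=None`` encodes an NA row."""

    event_id: str
    gene_idx: int
    exon: tuple[int, int]
    upstream: tuple[int, int]
    downstream: tuple[int, int]
    dpsi: float | None
    p_value: float | None
    significant: bool


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

_GENE_SPAN = 30_000
_DOMAIN_ZONE_OFFSET = 1_000


def make_toy_references(cfg: ToyConfig, outdir: str | Path | None = None) -> ToyReferences:
    """Build the toy reference set; optionally write the four TSVs to ``outdir``
    (``ppi.tsv``, ``ddi.tsv``, ``domains.tsv``, ``idmap.tsv``)."""
    rng = np.random.default_rng([cfg.seed, 0])
    genes = []
    for i in range(cfg.n_genes):
        genes.append(ToyGene(
            idx=i,
            symbol=f"GENE{i + 1}",
            entrez=str(1001 + i),
            ensembl=f"ENSG{i + 1:011d}",
            chrom=f"chr{i + 1}",
            strand="+" if rng.random() < 0.5 else "-",
            start=1_000,
            end=1_000 + _GENE_SPAN,
        ))

    pfam_pool = [f"PF{i + 1:05d}" for i in range(cfg.n_pfam)]
    domains: list[ToyDomain] = []
    for g in genes:
        n_dom = int(rng.integers(cfg.domains_per_gene[0], cfg.domains_per_gene[1] + 1))
        cursor = g.start + _DOMAIN_ZONE_OFFSET
        for _ in range(n_dom):
            pfam = pfam_pool[int(rng.integers(len(pfam_pool)))]
            n_seg = int(rng.integers(cfg.segments_per_domain[0],
                                     cfg.segments_per_domain[1] + 1))
            segs = []
            for _ in range(n_seg):
                cursor += int(rng.integers(50, 300))
                length = int(rng.integers(150, 500))
                segs.append((cursor, cursor + length))
                cursor += length
            domains.append(ToyDomain(g.idx, pfam, tuple(segs)))

    ppi_pairs = []
    for i in range(cfg.n_genes):
        for j in range(i + 1, cfg.n_genes):
            if rng.random() < cfg.ppi_density:
                ppi_pairs.append((genes[i].symbol, genes[j].symbol))
    if not ppi_pairs and cfg.ppi_density > 0 and cfg.n_genes >= 2:
        ppi_pairs.append((genes[0].symbol, genes[1].symbol))  # never an empty reference
    for _ in range(cfg.n_self_ppi):
        g = genes[int(rng.integers(cfg.n_genes))]
        if (g.symbol, g.symbol) not in ppi_pairs:
            ppi_pairs.append((g.symbol, g.symbol))

    ddi_pairs = []
    for i in range(cfg.n_pfam):
        for j in range(i, cfg.n_pfam):
            if rng.random() < cfg.ddi_density:
                ddi_pairs.append((pfam_pool[i], pfam_pool[j]))
    if not ddi_pairs and cfg.ddi_density > 0:
        ddi_pairs.append((pfam_pool[0], pfam_pool[min(1, cfg.n_pfam - 1)]))

    toy = ToyReferences(genes, domains, ppi_pairs, ddi_pairs)
    if outdir is not None:
        write_toy_references(toy, outdir)
    return toy


def write_toy_references(toy: ToyReferences, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.tsv" for name in ("ppi", "ddi", "domains", "idmap")}

    with open(paths["idmap"], "w") as fh:
        fh.write("raw_id\tgene_id\n")
        for g in toy.genes:
            fh.write(f"{g.symbol}\t{g.entrez}\n")
            fh.write(f"{g.ensembl}\t{g.entrez}\n")
            fh.write(f"{g.entrez}\t{g.entrez}\n")

    with open(paths["ppi"], "w") as fh:
        fh.write("gene_a\tgene_b\tsource\n")
        for a, b in toy.ppi_pairs:
            fh.write(f"{a}\t{b}\ttoy\n")

    with open(paths["ddi"], "w") as fh:
        fh.write("pfam_a\tpfam_b\n")
        for i, (a, b) in enumerate(toy.ddi_pairs):
            # a versioned accession now and then exercises suffix stripping
            fh.write(f"{a}{'.2' if i % 3 == 0 else ''}\t{b}\n")

    with open(paths["domains"], "w") as fh:
        fh.write("gene_id\tpfam_id\tchrom\tstrand\tintervals\n")
        for d in toy.domains:
            g = toy.gene(d.gene_idx)
            ivl = ",".join(f"{s}-{e}" for s, e in d.segments)
            fh.write(f"{g.symbol}\t{d.pfam}\t{g.chrom}\t{g.strand}\t{ivl}\n")
    return paths


def make_truth_plan(cfg: ToyConfig, toy: ToyReferences) -> list[PlannedEvent]:
    """Plant ``cfg.n_events`` scored events (exactly
    ``round(frac_significant * n_events)`` of which pass the default
    ΔPSI/FDR filters) plus ``cfg.n_na`` NA rows."""
    rng = np.random.default_rng([cfg.seed, 1])
    n_sig = round(cfg.frac_significant * cfg.n_events)
    flags = [True] * n_sig + [False] * (cfg.n_events - n_sig)
    rng.shuffle(flags)

    domains_by_gene: dict[int, list[ToyDomain]] = {}
    for d in toy.domains:
        domains_by_gene.setdefault(d.gene_idx, []).append(d)
    max_dom_end = {gi: max(e for d in ds for _, e in d.segments)
                   for gi, ds in domains_by_gene.items()}

    plan: list[PlannedEvent] = []
    for i in range(cfg.n_events + cfg.n_na):
        gene = toy.genes[int(rng.integers(len(toy.genes)))]
        hit_domain = (gene.idx in domains_by_gene
                      and rng.random() < cfg.domain_hit_fraction)
        if hit_domain:
            doms = domains_by_gene[gene.idx]
            seg_s, seg_e = doms[int(rng.integers(len(doms)))].segments[0]
            start = max(gene.start, seg_s - int(rng.integers(0, 100)))
            end = start + int(rng.integers(80, 300))
            end = max(end, seg_s + 1)  # guarantee >=1 shared base
        else:
            base = max_dom_end.get(gene.idx, gene.start + _DOMAIN_ZONE_OFFSET) + 200
            start = base + int(rng.integers(0, 500))
            end = start + int(rng.integers(80, 300))
        upstream = (max(0, start - 400), start - 200)
        downstream = (end + 200, end + 400)

        if i >= cfg.n_events:  # NA row
            plan.append(PlannedEvent(f"ev{i}", gene.idx, (start, end), upstream,
                                     downstream, None, None, False))
            continue
        significant = flags[i]
        sign = -1.0 if rng.random() < 0.5 else 1.0
        if significant:
            dpsi = sign * float(rng.uniform(*cfg.dpsi_range))
            p = float(rng.uniform(1e-6, 1e-4))
        elif rng.random() < 0.5:  # fails the |ΔPSI| filter
            dpsi = sign * float(rng.uniform(0.005, 0.045))
            p = float(rng.uniform(1e-6, 1e-4))
        else:  # fails the FDR filter
            dpsi = sign * float(rng.uniform(*cfg.dpsi_range))
            p = float(rng.uniform(0.5, 1.0))
        plan.append(PlannedEvent(f"ev{i}", gene.idx, (start, end), upstream,
                                 downstream, dpsi, p, significant))
    return plan


# ---------------------------------------------------------------------------
# Splicing-file writers (rMATS JCEC dialect, SUPPA2 dpsi/psivec)
# ---------------------------------------------------------------------------

_RMATS_COLUMNS = ["ID", "GeneID", "geneSymbol", "chr", "strand",
                  "exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
                  "downstreamES", "downstreamEE", "PValue", "FDR",
                  "IncLevel1", "IncLevel2", "IncLevelDifference"]


def make_toy_rmats(cfg: ToyConfig, plan: list[PlannedEvent], toy: ToyReferences,
                   path: str | Path) -> Path:
    """Write the plan as an rMATS SE (JCEC dialect) table.

    The FDR column is the BH adjustment of the non-NA rows' p-values, as
    rMATS itself reports adjusted values.
    """
    path = Path(path)
    fdrs = _bh_by_id({ev.event_id: ev.p_value for ev in plan if ev.p_value is not None})
    with open(path, "w") as fh:
        fh.write("\t".join(_RMATS_COLUMNS) + "\n")
        for ev in plan:
            g = toy.gene(ev.gene_idx)
            if ev.dpsi is None:
                pv = fdr = inc = "NA"
            else:
                pv = repr(ev.p_value)
                fdr = repr(fdrs[ev.event_id])
                inc = repr(ev.dpsi)
            fh.write("\t".join([
                ev.event_id, f'"{g.ensembl}"', f'"{g.symbol}"', g.chrom, g.strand,
                str(ev.exon[0]), str(ev.exon[1]),
                str(ev.upstream[0]), str(ev.upstream[1]),
                str(ev.downstream[0]), str(ev.downstream[1]),
                pv, fdr, "0.5", "0.5", inc,
            ]) + "\n")
    return path


def suppa_event_id(ev: PlannedEvent, toy: ToyReferences) -> str:
    g = toy.gene(ev.gene_idx)
    # 1-based inclusive junction coordinates
    return (f"{g.ensembl};SE:{g.chrom}:{ev.upstream[1]}-{ev.exon[0] + 1}"
            f":{ev.exon[1]}-{ev.downstream[0] + 1}:{g.strand}")


def make_toy_suppa(cfg: ToyConfig, plan: list[PlannedEvent], toy: ToyReferences,
                   outdir: str | Path, n_non_se: int = 0) -> tuple[Path, Path]:
    """Write the plan as SUPPA2 ``diffSplice`` outputs (.dpsi + .psivec).

    ``n_non_se`` appends that many non-SE (A5) rows to the dpsi file to
    exercise event-class filtering.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dpsi_path = outdir / "toy.dpsi"
    psivec_path = outdir / "toy.psivec"
    rng = np.random.default_rng([cfg.seed, 2])
    with open(dpsi_path, "w") as fh:
        fh.write("case-control_dPSI\tcase-control_p-val\n")
        for ev in plan:
            sid = suppa_event_id(ev, toy)
            if ev.dpsi is None:
                fh.write(f"{sid}\tnan\tnan\n")
            else:
                fh.write(f"{sid}\t{ev.dpsi!r}\t{ev.p_value!r}\n")
        for k in range(n_non_se):
            g = toy.genes[k % len(toy.genes)]
            fh.write(f"{g.ensembl};A5:{g.chrom}:100-200:100-300:{g.strand}\t0.2\t0.5\n")
    with open(psivec_path, "w") as fh:
        fh.write("case_1\tcase_2\tcontrol_1\tcontrol_2\n")
        for ev in plan:
            psis = "\t".join(f"{rng.uniform():.4f}" for _ in range(4))
            fh.write(f"{suppa_event_id(ev, toy)}\t{psis}\n")
    return dpsi_path, psivec_path


# ---------------------------------------------------------------------------
# The independent brute-force oracle
# ---------------------------------------------------------------------------

def _bh_by_id(pvals: dict[str, float]) -> dict[str, float]:
    """Hand-rolled Benjamini–Hochberg (kept independent of statsmodels)."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj: dict[str, float] = {}
    running = 1.0
    for rank in range(m, 0, -1):
        key, p = items[rank - 1]
        running = min(running, p * m / rank)
        adj[key] = running
    return adj


@dataclass(frozen=True)
class OracleEdge:
    category: str
    weight: float
    deltas: tuple[float, ...]  # sorted contributing domain-level ΔPSI


def oracle_network(cfg: ToyConfig, toy: ToyReferences, plan: list[PlannedEvent],
                   dpsi_threshold: float = 0.05,
                   fdr_threshold: float = 0.05) -> dict[tuple[str, str], OracleEdge]:
    """Expected rewired network by exhaustive nested loops over the toy plan.

    Keys are unordered canonical-id (Entrez) pairs.  Deliberately
    O(everything²) and free of any pipeline code.
    """
    fdr = _bh_by_id({ev.event_id: ev.p_value for ev in plan if ev.p_value is not None})
    kept = [ev for ev in plan
            if ev.dpsi is not None
            and abs(ev.dpsi) >= dpsi_threshold
            and fdr[ev.event_id] < fdr_threshold]

    # exon -> domain, grouped signed minimum
    affected: dict[tuple[str, str], float] = {}
    for ev in kept:
        g = toy.gene(ev.gene_idx)
        for dom in toy.domains:
            dg = toy.gene(dom.gene_idx)
            if (dg.chrom, dg.strand) != (g.chrom, g.strand):
                continue
            overlap = False
            for s, e in dom.segments:
                if s < ev.exon[1] and ev.exon[0] < e:
                    overlap = True
            if not overlap:
                continue
            key = (dg.entrez, dom.pfam)
            if key not in affected or ev.dpsi < affected[key]:
                affected[key] = ev.dpsi
    affected = {k: v for k, v in affected.items() if v != 0.0}

    sym2gene = {g.symbol: g for g in toy.genes}
    ddi = set()
    for a, b in toy.ddi_pairs:
        ddi.add((a, b))
        ddi.add((b, a))
    complements: dict[str, set[str]] = {}
    for dom in toy.domains:
        complements.setdefault(toy.gene(dom.gene_idx).entrez, set()).add(dom.pfam)

    edges: dict[tuple[str, str], OracleEdge] = {}
    for sym_a, sym_b in toy.ppi_pairs:
        ga, gb = sym2gene[sym_a].entrez, sym2gene[sym_b].entrez
        participants = set()
        for dom_a in complements.get(ga, ()):
            for dom_b in complements.get(gb, ()):
                if (dom_a, dom_b) not in ddi:
                    continue
                if (ga, dom_a) in affected:
                    participants.add((ga, dom_a))
                if (gb, dom_b) in affected:
                    participants.add((gb, dom_b))
        if not participants:
            continue
        deltas = sorted(affected[p] for p in sorted(participants))
        if all(d > 0 for d in deltas):
            cat = "gain"
        elif all(d < 0 for d in deltas):
            cat = "loss"
        else:
            cat = "chaos"
        key = (ga, gb) if ga <= gb else (gb, ga)
        edges[key] = OracleEdge(cat, sum(deltas) / len(deltas), tuple(deltas))
    return edges


def compare_network_to_oracle(net, oracle: dict[tuple[str, str], OracleEdge],
                              tol: float = 1e-12) -> list[str]:
    """Differences between a pipeline RewiredNetwork and the oracle (empty
    list means exact agreement: edge set, categories, weights, deltas)."""
    problems = []
    if set(net.edges) != set(oracle):
        problems.append(f"edge sets differ: only-pipeline={set(net.edges) - set(oracle)}, "
                        f"only-oracle={set(oracle) - set(net.edges)}")
        return problems
    for key, expect in oracle.items():
        got = net.edges[key]
        if got.category != expect.category:
            problems.append(f"{key}: category {got.category} != {expect.category}")
        if not math.isclose(got.weight, expect.weight, rel_tol=0.0, abs_tol=tol):
            problems.append(f"{key}: weight {got.weight} != {expect.weight}")
        got_deltas = tuple(sorted(d for _, _, d in got.contributing_deltas))
        if len(got_deltas) != len(expect.deltas) or any(
                abs(a - b) > tol for a, b in zip(got_deltas, expect.deltas)):
            problems.append(f"{key}: deltas {got_deltas} != {expect.deltas}")
    return problems


def flip_plan(plan: list[PlannedEvent]) -> list[PlannedEvent]:
    """Negate every planted ΔPSI (for antisymmetry checks)."""
    return [replace(ev, dpsi=None if ev.dpsi is None else -ev.dpsi) for ev in plan]
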