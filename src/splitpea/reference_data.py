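"""Reference inputs: PPI network, DDI catalog, Pfam genomic coordinates, identifier map.

All reference files are plain TSV.  Genomic coordinates throughout are
**0-based, half-open** (like BED and rMATS ``exonStart_0base``).  Gene
identifiers are canonicalized to a single stable id space (Entrez-style
integer ids in the bundled files) through an :class:`IdMap`; Pfam and
Ensembl version suffixes are stripped before any comparison.

Bundled toy reference files ship under ``splitpea/data`` and are used when
no explicit path is given.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from .exceptions import InputFormatError, SplitpeaError

logger = logging.getLogger("splitpea")

PFAM_RE = re.compile(r"^PF\d{5}$")
_ENS_VERSION_RE = re.compile(r"^(ENS[A-Z]*[GTP]\d+)\.\d+$")


def strip_pfam_version(acc: str) -> str:
    """``PF00001.12`` -> ``PF00001``; non-versioned accessions pass through."""
    return acc.split(".", 1)[0].strip()


def strip_ensembl_version(raw: str) -> str:
    m = _ENS_VERSION_RE.match(raw)
    return m.group(1) if m else raw


def unordered(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered pair."""
    return (a, b) if a <= b else (b, a)


def bundled_path(name: str) -> Path:
    """Path to a bundled toy reference file (``ppi.tsv``, ``ddi.tsv``,
    ``domains.tsv``, ``idmap.tsv``)."""
    return Path(resources.files("splitpea").joinpath("data", name))  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# IdMap
# ---------------------------------------------------------------------------

@dataclass
class IdMap:
    """Maps raw gene identifiers (symbols, Ensembl gene ids, Entrez ids) onto
    one canonical gene-id space.

    Lookup is case-insensitive for gene symbols and case-sensitive for
    accessions (anything matching an Ensembl pattern or consisting of
    digits).  Ensembl version suffixes are stripped.  The mapping is a
    function: one canonical id per raw key; collisions found at load time
    are logged and the first mapping wins.
    """

    accessions: dict[str, str] = field(default_factory=dict)
    symbols: dict[str, str] = field(default_factory=dict)  # keys uppercased
    n_collisions: int = 0

    @staticmethod
    def _is_accession(raw: str) -> bool:
        return raw.isdigit() or raw.startswith("ENS")

    def add(self, raw: str, canonical: str) -> None:
        raw = strip_ensembl_version(raw.strip())
        canonical = canonical.strip()
        if self._is_accession(raw):
            table, key = self.accessions, raw
        else:
            table, key = self.symbols, raw.upper()
        if key in table:
            if table[key] != canonical:
                self.n_collisions += 1
                logger.warning(
                    "id-map collision for %r: keeping %s, ignoring %s",
                    raw, table[key], canonical,
                )
            return
        table[key] = canonical

    def resolve(self, raw: str) -> str | None:
        """Canonical id for ``raw``, or ``None`` when unknown."""
        raw = strip_ensembl_version(raw.strip())
        if self._is_accession(raw):
            return self.accessions.get(raw)
        return self.symbols.get(raw.upper())

    def __len__(self) -> int:
        return len(self.accessions) + len(self.symbols)


def load_id_map(path: str | Path | None = None) -> IdMap:
    """Load a two-column TSV ``raw_id<TAB>gene_id`` (optional header)."""
    path = Path(path) if path is not None else bundled_path("idmap.tsv")
    if not path.exists():
        raise SplitpeaError(f"id-map file not found: {path}")
    idmap = IdMap()
    for lineno, parts in _tsv_rows(path):
        if lineno == 1 and parts[0].lower() in {"raw_id", "alias"}:
            continue
        if len(parts) < 2:
            logger.warning("%s:%d: expected 2 columns, got %d; skipped", path, lineno, len(parts))
            continue
        idmap.add(parts[0], parts[1])
    if len(idmap) == 0:
        raise SplitpeaError(f"id-map file {path} yielded no mappings")
    return idmap


def resolve_gene(raw_id: str, id_map: IdMap) -> str | None:
    """Deterministic canonical-id lookup; ``None`` signals a miss."""
    return id_map.resolve(raw_id)


def _tsv_rows(path: Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (row number among non-comment rows, fields); '#' lines skipped."""
    row = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            row += 1
            yield row, line.split("\t")


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    """Gene-level reference PPI network: unordered canonical-id pairs.

    Self-pairs (homodimers) are stored and flagged in ``self_pairs``.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)
    node_ids: set[str] = field(default_factory=set)
    source_tags: dict[tuple[str, str], str] = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def self_pairs(self) -> set[tuple[str, str]]:
        return {e for e in self.edges if e[0] == e[1]}

    def add_edge(self, a: str, b: str, source: str = "") -> None:
        e = unordered(a, b)
        if e not in self.edges:
            self.edges.add(e)
            if source:
                self.source_tags[e] = source
        self.node_ids.update(e)


def load_ppi(path: str | Path | None = None, id_map: IdMap | None = None) -> PPINetwork:
    """Load a PPI edge list: ``gene_a<TAB>gene_b[<TAB>source]``.

    Identifiers are canonicalized through ``id_map``; duplicate and
    reversed-duplicate rows collapse to one unordered edge; rows with an
    unmappable endpoint are skipped with a warning counter.
    """
    path = Path(path) if path is not None else bundled_path("ppi.tsv")
    if not path.exists():
        raise SplitpeaError(f"PPI file not found: {path}")
    if id_map is None:
        id_map = load_id_map()
    net = PPINetwork()
    for lineno, parts in _tsv_rows(path):
        if lineno == 1 and parts[0].lower() in {"gene_a", "protein_a"}:
            continue
        if len(parts) < 2:
            net.n_dropped += 1
            continue
        a = id_map.resolve(parts[0])
        b = id_map.resolve(parts[1])
        if a is None or b is None:
            net.n_dropped += 1
            continue
        net.add_edge(a, b, parts[2] if len(parts) > 2 else "")
    if net.n_dropped:
        logger.warning("load_ppi: skipped %d unmappable/short rows", net.n_dropped)
    if not net.edges:
        raise SplitpeaError(f"PPI file {path} yielded zero mappable edges")
    return net


# ---------------------------------------------------------------------------
# DDI catalog
# ---------------------------------------------------------------------------

@dataclass
class DDICatalog:
    """Unordered Pfam-accession pairs with a reported physical interaction."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return unordered(*pair) in self.pairs

    def add(self, a: str, b: str) -> None:
        self.pairs.add(unordered(a, b))


def load_ddi(path: str | Path | None = None) -> DDICatalog:
    """Load a DDI catalog: two Pfam-accession columns, version suffixes allowed."""
    path = Path(path) if path is not None else bundled_path("ddi.tsv")
    if not path.exists():
        raise SplitpeaError(f"DDI file not found: {path}")
    cat = DDICatalog()
    n_bad = 0
    for lineno, parts in _tsv_rows(path):
        if lineno == 1 and parts[0].lower() in {"pfam_a", "domain_a"}:
            continue
        if len(parts) < 2:
            n_bad += 1
            continue
        a = strip_pfam_version(parts[0])
        b = strip_pfam_version(parts[1])
        if not (PFAM_RE.match(a) and PFAM_RE.match(b)):
            n_bad += 1
            logger.warning("%s:%d: malformed Pfam accession pair (%s, %s); skipped",
                           path, lineno, parts[0], parts[1])
            continue
        cat.add(a, b)
    if not cat.pairs:
        raise SplitpeaError(f"DDI file {path} yielded zero valid pairs")
    if n_bad:
        logger.warning("load_ddi: skipped %d malformed rows", n_bad)
    return cat


# ---------------------------------------------------------------------------
# Domain genomic footprints and the interval index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainAnnotation:
    """Genomic footprint of one Pfam domain instance in one gene.

    ``intervals`` are the coding segments of the domain: 0-based half-open,
    sorted, non-overlapping.
    """

    gene_id: str
    pfam_id: str
    chrom: str
    strand: str
    intervals: tuple[tuple[int, int], ...]

    def overlaps(self, start: int, end: int) -> bool:
        """Half-open overlap (>=1 shared base) with any coding segment."""
        return any(s < end and start < e for s, e in self.intervals)


class DomainIndex:
    """Per-(chrom, strand) interval index over all domain coding segments.

    A query returns exactly the annotations a brute-force linear scan over
    all segments would return, each annotation at most once.
    """

    def __init__(self, annotations: Iterable[DomainAnnotation] = ()):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._annotations: list[DomainAnnotation] = []
        self._by_gene: dict[str, set[str]] = {}
        for ann in annotations:
            self.add(ann)

    def add(self, ann: DomainAnnotation) -> None:
        self._annotations.append(ann)
        tree = self._trees.setdefault((ann.chrom, ann.strand), IntervalTree())
        for s, e in ann.intervals:
            tree.addi(s, e, ann)
        self._by_gene.setdefault(ann.gene_id, set()).add(ann.pfam_id)

    @property
    def annotations(self) -> list[DomainAnnotation]:
        return list(self._annotations)

    def __len__(self) -> int:
        return len(self._annotations)

    def query(self, chrom: str, strand: str, start: int, end: int) -> list[DomainAnnotation]:
        """All annotations with >=1 segment overlapping ``[start, end)`` on
        the given chromosome and strand, in insertion order."""
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        hits = {id(iv.data): iv.data for iv in tree.overlap(start, end)}
        return [ann for ann in self._annotations if id(ann) in hits]

    def domains_of(self, gene_id: str) -> set[str]:
        """Full Pfam complement (affected or not) annotated for a gene."""
        return set(self._by_gene.get(gene_id, ()))

    @property
    def genes(self) -> set[str]:
        return set(self._by_gene)


def _parse_interval_list(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        try:
            s_str, e_str = token.split("-")
            out.append((int(s_str), int(e_str)))
        except ValueError as exc:
            raise InputFormatError(f"bad interval token {token!r}") from exc
    return tuple(sorted(out))


def load_domain_coords(path: str | Path | None = None,
                       id_map: IdMap | None = None) -> DomainIndex:
    """Load Pfam domain genomic coordinates into a :class:`DomainIndex`.

    Format: ``gene_id<TAB>pfam_id<TAB>chrom<TAB>strand<TAB>intervals`` where
    ``intervals`` is a comma-separated list of ``start-end`` segments,
    0-based half-open.  Annotations with an invalid strand, an empty or
    degenerate interval (start >= end), overlapping segments, or an
    unmappable gene are skipped with a warning.
    """
    path = Path(path) if path is not None else bundled_path("domains.tsv")
    if not path.exists():
        raise SplitpeaError(f"domain-coordinate file not found: {path}")
    if id_map is None:
        id_map = load_id_map()
    index = DomainIndex()
    n_skipped = 0
    for lineno, parts in _tsv_rows(path):
        if lineno == 1 and parts[0].lower() in {"gene_id", "gene"}:
            continue
        if len(parts) < 5:
            n_skipped += 1
            continue
        raw_gene, pfam, chrom, strand, ivl_text = parts[:5]
        if strand not in {"+", "-"}:
            logger.warning("%s:%d: unknown strand %r; skipped", path, lineno, strand)
            n_skipped += 1
            continue
        try:
            intervals = _parse_interval_list(ivl_text)
        except InputFormatError:
            n_skipped += 1
            continue
        if not intervals or any(s >= e for s, e in intervals):
            logger.warning("%s:%d: empty/degenerate interval list; skipped", path, lineno)
            n_skipped += 1
            continue
        if any(intervals[i][1] > intervals[i + 1][0] for i in range(len(intervals) - 1)):
            logger.warning("%s:%d: overlapping segments; skipped", path, lineno)
            n_skipped += 1
            continue
        gene = id_map.resolve(raw_gene)
        if gene is None:
            n_skipped += 1
            continue
        index.add(DomainAnnotation(gene, strip_pfam_version(pfam), chrom, strand, intervals))
    if n_skipped:
        logger.warning("load_domain_coords: skipped %d rows", n_skipped)
    if len(index) == 0:
        raise SplitpeaError(f"domain-coordinate file {path} yielded zero annotations")
    return index
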