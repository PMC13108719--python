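"""Parse rMATS and SUPPA2 skipped-exon (SE) outputs into a uniform event stream.

Internal conventions
--------------------
* Exon coordinates are 0-based half-open.  rMATS ``exonStart_0base`` /
  ``exonEnd`` already follow this convention and are taken unchanged;
  SUPPA2 event ids carry 1-based inclusive junction coordinates and are
  converted at parse time (skipped exon ``[e2start-1, e2end)``).
* ``delta_psi`` means PSI(condition of interest) − PSI(reference), in
  [−1, 1].  rMATS ``IncLevelDifference`` is sample1 − sample2; pass
  ``flip_sign=True`` when sample1 is the reference group.
* SUPPA2 ``.dpsi`` files carry raw p-values; a Benjamini–Hochberg
  adjustment across the retained SE events supplies an FDR-comparable
  quantity so one FDR cutoff applies to both input types.  A column whose
  name contains ``p-adj``/``padj``/``fdr`` is used directly instead.

Only SE events are consumed; other SUPPA2 event classes (A5/A3/MX/RI/AF/AL)
are counted and skipped.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import InputFormatError, SplitpeaError
from .reference_data import IdMap

logger = logging.getLogger("splitpea")

DEFAULT_DPSI_THRESHOLD = 0.05
DEFAULT_FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class SpliceEvent:
    """One skipped-exon event with coordinates, ΔPSI and significance."""

    event_id: str
    gene_raw: str
    gene_id: str | None
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    delta_psi: float
    p_value: float | None = None
    fdr: float | None = None
    source: str = "rmats_jcec"
    upstream: tuple[int, int] | None = None
    downstream: tuple[int, int] | None = None

    def validate(self) -> None:
        if self.exon_start >= self.exon_end:
            raise ValueError(f"{self.event_id}: exon_start >= exon_end")
        if not -1.0 <= self.delta_psi <= 1.0:
            raise ValueError(f"{self.event_id}: delta_psi {self.delta_psi} outside [-1,1]")
        if self.fdr is not None and not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.event_id}: fdr {self.fdr} outside [0,1]")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.event_id}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# rMATS
# ---------------------------------------------------------------------------

_RMATS_REQUIRED = ["GeneID", "chr", "strand", "exonStart_0base", "exonEnd",
                   "IncLevelDifference", "PValue", "FDR"]


def _clean_cell(v: object) -> str:
    return str(v).strip().strip('"')


def _is_missing(v: object) -> bool:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return True
    return _clean_cell(v).upper() in {"", "NA", "NAN", "NONE"}


def parse_rmats(path: str | Path, id_map: IdMap | None = None,
                flip_sign: bool = False, source: str = "rmats_jcec") -> list[SpliceEvent]:
    """Parse an rMATS ``SE.MATS.JC.txt`` / ``SE.MATS.JCEC.txt`` table.

    Rows with missing ΔPSI (``NA``) are skipped with a warning counter;
    a missing mandatory column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise SplitpeaError(f"rMATS file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _RMATS_REQUIRED:
        if col not in df.columns:
            raise InputFormatError(f"rMATS file {path} lacks mandatory column {col!r}")
    events: list[SpliceEvent] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        if _is_missing(rec["IncLevelDifference"]):
            n_skipped += 1
            continue
        try:
            dpsi = float(_clean_cell(rec["IncLevelDifference"]))
            start = int(_clean_cell(rec["exonStart_0base"]))
            end = int(_clean_cell(rec["exonEnd"]))
        except ValueError:
            logger.warning("%s row %d: non-numeric field; skipped", path, i)
            n_skipped += 1
            continue
        if flip_sign:
            dpsi = -dpsi
        gene_raw = _clean_cell(rec["GeneID"])
        ev = SpliceEvent(
            event_id=_clean_cell(rec.get("ID", str(i))) or str(i),
            gene_raw=gene_raw,
            gene_id=id_map.resolve(gene_raw) if id_map is not None else None,
            chrom=_clean_cell(rec["chr"]),
            strand=_clean_cell(rec["strand"]),
            exon_start=start,
            exon_end=end,
            delta_psi=dpsi,
            p_value=None if _is_missing(rec["PValue"]) else float(_clean_cell(rec["PValue"])),
            fdr=None if _is_missing(rec["FDR"]) else float(_clean_cell(rec["FDR"])),
            source=source,
            upstream=_opt_interval(rec, "upstreamES", "upstreamEE"),
            downstream=_opt_interval(rec, "downstreamES", "downstreamEE"),
        )
        ev.validate()
        events.append(ev)
    if n_skipped:
        logger.warning("parse_rmats: skipped %d rows with missing/bad values", n_skipped)
    return events


def _opt_interval(rec: dict, a: str, b: str) -> tuple[int, int] | None:
    if a in rec and b in rec and not (_is_missing(rec[a]) or _is_missing(rec[b])):
        try:
            return int(_clean_cell(rec[a])), int(_clean_cell(rec[b]))
        except ValueError:
            return None
    return None


# ---------------------------------------------------------------------------
# SUPPA2
# ---------------------------------------------------------------------------

_SUPPA_SE_RE = re.compile(
    r"^(?P<gene>[^;]+);SE:(?P<chrom>[^:]+)"
    r":(?P<e1end>\d+)-(?P<e2start>\d+)"
    r":(?P<e2end>\d+)-(?P<e3start>\d+)"
    r":(?P<strand>[+-])$"
)


def parse_suppa_event_id(event_id: str) -> tuple[str, str, tuple[int, int], str]:
    """Decompose a SUPPA2 SE event id ``gene;SE:chrom:e1end-e2start:e2end-e3start:strand``.

    Returns ``(gene_raw, chrom, (exon_start, exon_end), strand)`` with the
    skipped exon converted from 1-based inclusive junction coordinates to
    0-based half-open: ``[e2start − 1, e2end)``.
    """
    m = _SUPPA_SE_RE.match(event_id.strip())
    if not m:
        raise InputFormatError(f"not a SUPPA2 SE event id: {event_id!r}")
    e2start = int(m.group("e2start"))
    e2end = int(m.group("e2end"))
    exon = (e2start - 1, e2end)
    if exon[0] >= exon[1]:
        raise InputFormatError(f"degenerate skipped exon in {event_id!r}")
    return m.group("gene"), m.group("chrom"), exon, m.group("strand")


def format_suppa_event_id(gene: str, chrom: str, exon: tuple[int, int], strand: str,
                          upstream_end: int, downstream_start: int) -> str:
    """Inverse of :func:`parse_suppa_event_id` (1-based inclusive on output)."""
    return (f"{gene};SE:{chrom}:{upstream_end}-{exon[0] + 1}"
            f":{exon[1]}-{downstream_start}:{strand}")


def _find_column(columns: Sequence[str], suffixes: tuple[str, ...]) -> str | None:
    for col in columns:
        low = col.lower()
        if any(low.endswith(s) or low == s.lstrip("_") for s in suffixes):
            return col
    return None


def parse_suppa(dpsi_path: str | Path, psivec_path: str | Path | None = None,
                id_map: IdMap | None = None) -> list[SpliceEvent]:
    """Parse SUPPA2 ``diffSplice`` output (``.dpsi``; ``.psivec`` optional).

    Non-SE rows and unparseable ids are skipped with counters.  When the
    dpsi table has no adjusted-p column, the FDR field is filled by BH
    adjustment across the retained SE events.
    """
    dpsi_path = Path(dpsi_path)
    if not dpsi_path.exists():
        raise SplitpeaError(f"SUPPA2 dpsi file not found: {dpsi_path}")
    # round_trip parsing keeps ΔPSI bit-identical to the producing tool
    df = pd.read_csv(dpsi_path, sep="\t", index_col=0, float_precision="round_trip")
    dpsi_col = _find_column(df.columns, ("_dpsi", "dpsi"))
    pval_col = _find_column(df.columns, ("_p-val", "p-val", "pval", "p_value"))
    if dpsi_col is None or pval_col is None:
        raise InputFormatError(
            f"{dpsi_path}: need a dPSI column and a p-val column, found {list(df.columns)}")
    padj_col = _find_column(df.columns, ("p-adj", "padj", "fdr"))

    if psivec_path is not None:
        psivec = pd.read_csv(Path(psivec_path), sep="\t", index_col=0)
        missing = set(df.index) - set(psivec.index)
        if missing:
            logger.warning("parse_suppa: %d dpsi events absent from psivec; proceeding on dpsi",
                           len(missing))

    events: list[SpliceEvent] = []
    n_non_se = n_bad = 0
    for event_id, row in df.iterrows():
        sid = str(event_id)
        if ";SE:" not in sid:
            n_non_se += 1
            continue
        try:
            gene_raw, chrom, (start, end), strand = parse_suppa_event_id(sid)
        except InputFormatError:
            logger.warning("parse_suppa: unparseable event id %r; skipped", sid)
            n_bad += 1
            continue
        if _is_missing(row[dpsi_col]) or _is_missing(row[pval_col]):
            n_bad += 1
            continue
        ev = SpliceEvent(
            event_id=sid,
            gene_raw=gene_raw,
            gene_id=id_map.resolve(gene_raw) if id_map is not None else None,
            chrom=chrom,
            strand=strand,
            exon_start=start,
            exon_end=end,
            delta_psi=float(row[dpsi_col]),
            p_value=float(row[pval_col]),
            fdr=float(row[padj_col]) if padj_col is not None and not _is_missing(row[padj_col]) else None,
            source="suppa2",
        )
        ev.validate()
        events.append(ev)
    if n_non_se or n_bad:
        logger.warning("parse_suppa: skipped %d non-SE and %d bad rows", n_non_se, n_bad)
    if padj_col is None and events:
        events = bh_adjust_events(events)
    return events


def bh_adjust_events(events: Sequence[SpliceEvent]) -> list[SpliceEvent]:
    """Fill ``fdr`` by Benjamini–Hochberg over the events' raw p-values.

    Events without a p-value keep ``fdr=None``.
    """
    scored = [e for e in events if e.p_value is not None]
    if not scored:
        return list(events)
    _, padj, _, _ = multipletests([e.p_value for e in scored], method="fdr_bh")
    adj = {e.event_id: q for e, q in zip(scored, padj)}
    return [replace(e, fdr=adj.get(e.event_id, e.fdr)) for e in events]


# ---------------------------------------------------------------------------
# Significance filter
# ---------------------------------------------------------------------------

def filter_significant(events: Iterable[SpliceEvent],
                       dpsi_threshold: float = DEFAULT_DPSI_THRESHOLD,
                       fdr_threshold: float | None = DEFAULT_FDR_THRESHOLD) -> list[SpliceEvent]:
    """Keep events with ``|ΔPSI| >= dpsi_threshold`` and ``FDR < fdr_threshold``.

    ``fdr_threshold=None`` disables FDR filtering (then events with a null
    FDR are retained).  Order is preserved; the filter is idempotent.
    """
    if not 0 < dpsi_threshold <= 1:
        raise ValueError("dpsi_threshold must be in (0, 1]")
    if fdr_threshold is not None and not 0 < fdr_threshold <= 1:
        raise ValueError("fdr_threshold must be in (0, 1] or None")
    out = []
    for ev in events:
        if abs(ev.delta_psi) < dpsi_threshold:
            continue
        if fdr_threshold is not None and (ev.fdr is None or not ev.fdr < fdr_threshold):
            continue
        out.append(ev)
    return out
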