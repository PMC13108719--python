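"""Sample-specific mode: score one sample's exon PSI against a multi-sample background.

The background is a PSI matrix (exons × samples, values in [0, 1], missing
cells allowed).  For each exon shared between the sample and the background
with at least ``min_bg`` non-missing background values (default 30, below
which the estimate is considered unreliable and the exon is reported
unscored):

* ``delta_psi`` = observed PSI − median(background PSI); the median is used
  as a robust center because tissue PSI distributions are often multimodal.
* the two-sided empirical p-value uses add-one smoothing on both tails so
  it can never be zero::

      r_lo = (1 + #{bg <= obs}) / (n_bg + 1)
      r_hi = (1 + #{bg >= obs}) / (n_bg + 1)
      p    = min(1, 2 * min(r_lo, r_hi))

* an FDR is supplied by Benjamini–Hochberg adjustment across all scored
  exons, so the same significance filter defaults apply to both the
  sample-specific and condition-specific modes.

The scored exons are emitted as :class:`~splitpea.splice_io.SpliceEvent`
records (``source="sample_mode"``) ready for the rewiring pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import InputFormatError, SplitpeaError
from .splice_io import SpliceEvent

logger = logging.getLogger("splitpea")

DEFAULT_MIN_BACKGROUND = 30

ExonKey = tuple[str, str, int, int]  # (chrom, strand, exon_start, exon_end)

_KEY_COLUMNS = ["chrom", "strand", "exon_start", "exon_end"]


@dataclass
class PsiMatrix:
    """Exons × samples PSI values in [0, 1]; missing cells are NaN.

    ``data`` is indexed by the exon key (chrom, strand, exon_start,
    exon_end) with one column per sample.
    """

    data: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def exon_keys(self) -> list[ExonKey]:
        return list(self.data.index)

    def write(self, path: str | Path) -> None:
        keys = pd.DataFrame(list(self.data.index), columns=_KEY_COLUMNS)
        out = pd.concat([keys, self.data.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_psi_matrix(path: str | Path) -> PsiMatrix:
    """Load a background PSI TSV: columns ``chrom strand exon_start exon_end``
    then one column per sample.  Out-of-range values and duplicate exon keys
    are fatal."""
    path = Path(path)
    if not path.exists():
        raise SplitpeaError(f"PSI matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", na_values=["NA", "nan", ""],
                     dtype={"chrom": str, "strand": str},
                     float_precision="round_trip")
    missing_cols = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InputFormatError(f"{path}: missing key columns {missing_cols}")
    sample_cols = [c for c in df.columns if c not in _KEY_COLUMNS]
    if not sample_cols:
        raise InputFormatError(f"{path}: no sample columns")
    values = df[sample_cols].to_numpy(dtype=float)
    bad = np.where((values < 0) | (values > 1))
    if bad[0].size:
        r, c = bad[0][0], bad[1][0]
        raise InputFormatError(
            f"{path}: PSI value {values[r, c]} outside [0,1] at row {r + 2}, "
            f"column {sample_cols[c]!r}")
    keyed = df.set_index([pd.MultiIndex.from_frame(df[_KEY_COLUMNS])])[sample_cols]
    if keyed.index.duplicated().any():
        dup = keyed.index[keyed.index.duplicated()][0]
        raise InputFormatError(f"{path}: duplicate exon key {tuple(dup)}")
    keyed.index = [tuple(k) for k in keyed.index]
    return PsiMatrix(keyed.astype(float))


@dataclass
class SampleComparison:
    """Per-exon comparison of one sample against the background.

    ``table`` columns: observed, n_bg, bg_median, delta_psi, tail_rank
    (``#{bg <= obs}``, the basis of the empirical p-value), p_value, fdr.
    ``unscored`` lists exons whose background support fell below ``min_bg``.
    """

    table: pd.DataFrame
    unscored: list[ExonKey] = field(default_factory=list)
    min_bg: int = DEFAULT_MIN_BACKGROUND

    def to_events(self) -> list[SpliceEvent]:
        events = []
        for key, row in self.table.iterrows():
            chrom, strand, start, end = key
            ev = SpliceEvent(
                event_id=f"{chrom}:{start}-{end}:{strand}",
                gene_raw="", gene_id=None,
                chrom=chrom, strand=strand,
                exon_start=int(start), exon_end=int(end),
                delta_psi=float(row["delta_psi"]),
                p_value=float(row["p_value"]),
                fdr=float(row["fdr"]),
                source="sample_mode",
            )
            ev.validate()
            events.append(ev)
        return events


def empirical_two_sided_p(observed: float, background: np.ndarray) -> float:
    """Add-one–smoothed two-sided empirical tail probability in (0, 1]."""
    n = background.size
    r_lo = (1 + int((background <= observed).sum())) / (n + 1)
    r_hi = (1 + int((background >= observed).sum())) / (n + 1)
    return min(1.0, 2.0 * min(r_lo, r_hi))


def compare_to_background(sample_psi: Mapping[ExonKey, float] | pd.Series,
                          bg: PsiMatrix,
                          min_bg: int = DEFAULT_MIN_BACKGROUND) -> SampleComparison:
    """Score a sample's per-exon PSI against the background matrix.

    Exons with fewer than ``min_bg`` non-missing background values are
    reported in ``unscored`` and receive no statistics.  Raises if the
    sample and background share no exons.
    """
    if isinstance(sample_psi, pd.Series):
        sample_psi = sample_psi.to_dict()
    shared = [k for k in bg.exon_keys if k in sample_psi]
    if not shared:
        raise SplitpeaError("sample and background share no exon keys")
    rows = []
    unscored: list[ExonKey] = []
    for key in shared:
        obs = float(sample_psi[key])
        if not 0.0 <= obs <= 1.0:
            raise InputFormatError(f"sample PSI {obs} outside [0,1] for exon {key}")
        vals = bg.data.loc[[key]].to_numpy(dtype=float).ravel()
        vals = vals[~np.isnan(vals)]  # pairwise deletion of missing cells
        if vals.size < min_bg:
            unscored.append(key)
            continue
        med = float(np.median(vals))
        rows.append({
            "key": key,
            "observed": obs,
            "n_bg": int(vals.size),
            "bg_median": med,
            "delta_psi": obs - med,
            "tail_rank": int((vals <= obs).sum()),
            "p_value": empirical_two_sided_p(obs, vals),
        })
    if not rows:
        logger.warning("compare_to_background: no exon reached min_bg=%d", min_bg)
        table = pd.DataFrame(columns=["observed", "n_bg", "bg_median", "delta_psi",
                                      "tail_rank", "p_value", "fdr"])
        return SampleComparison(table, unscored, min_bg)
    table = pd.DataFrame(rows).set_index("key")
    _, fdr, _, _ = multipletests(table["p_value"].to_numpy(), method="fdr_bh")
    table["fdr"] = fdr
    return SampleComparison(table, unscored, min_bg)


def fetch_background_hint() -> str:
    """Instructions for obtaining and formatting a reference PSI background."""
    return (
        "Background PSI matrices are supplied by the user; no download is\n"
        "performed.  A convenient public source is GTEx normal-tissue PSI as\n"
        "redistributed by the IRIS database (v2.0.0): download the skipped-exon\n"
        "PSI tables for the tissues of interest and reshape them into the\n"
        "expected TSV layout:\n"
        "\n"
        "    chrom<TAB>strand<TAB>exon_start<TAB>exon_end<TAB><sample1><TAB><sample2>...\n"
        "\n"
        "with exon coordinates 0-based half-open, PSI values in [0,1], and 'NA'\n"
        "for missing cells.  Note that such backgrounds are\n"
        "not tissue-matched by default; supply tissue-matched or custom\n"
        "sample sets where the\n"
        "biological question requires it.  At least 30 background samples per\n"
        "exon are recommended (and required by default, --min-bg 30) for a\n"
        "robust estimate of the splicing change."
    )
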