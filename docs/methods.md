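# Methods

## Overview

`splitpea` predicts interaction-level consequences of cassette-exon
(skipped exon, SE) splicing changes. The unit of input is one SE event
with a ΔPSI value (PSI in the condition of interest minus PSI in the
reference, in [−1, 1]) and a significance statistic; the unit of output
is a weighted, categorized edge in a rewired PPI network. The model is
deliberately gene-level: it does not attempt transcript- or
isoform-resolved networks, only the domain-mediated signal that short-read
differential-splicing output can support.

Assumptions worth stating explicitly:

* a PPI can only be affected through a known domain–domain interaction
  (DDI) between Pfam domains of the two partners — interface knowledge is
  limited to the DDI catalog supplied;
* genomic overlap between a skipped exon and a domain's coding footprint
  is a sufficient proxy for "this event perturbs this domain";
* ΔPSI direction carries through monotonically: more exon inclusion means
  more domain, means more interaction capacity.

## Pipeline

1. **Parsing.** rMATS SE tables (`SE.MATS.JC.txt` / `SE.MATS.JCEC.txt`)
   are consumed directly: `exonStart_0base`/`exonEnd` are already 0-based
   half-open, `IncLevelDifference` is sample1 − sample2 (the `--flip-sign`
   flag negates it when sample1 is the reference group), and the `FDR`
   column is used as-is. SUPPA2 `diffSplice` output is consumed from the
   `.dpsi` file (`.psivec` optional, used only for consistency warnings);
   SE event ids `gene;SE:chrom:e1end-e2start:e2end-e3start:strand` carry
   1-based inclusive junction coordinates, converted to the internal
   0-based half-open exon `[e2start−1, e2end)`. SUPPA2 p-values receive a
   Benjamini–Hochberg adjustment across the retained SE events so that one
   FDR cutoff applies to both input dialects (an explicit adjusted-p
   column, if present, wins). ΔPSI columns are parsed with round-trip
   float precision so values are bit-identical to the producing tool's
   output.
2. **Significance filter.** Defaults: |ΔPSI| ≥ 0.05 (non-strict) and
   FDR < 0.05 (strict). The asymmetry is a documented convention choice;
   both thresholds are flags. Events with missing FDR are dropped unless
   FDR filtering is disabled.
3. **Exon → domain mapping.** Domain instances are indexed per
   (chromosome, strand) in an interval tree over their coding segments
   (0-based half-open); an event hits an annotation if any segment shares
   ≥ 1 base with the skipped exon. Per (gene, Pfam) group the aggregated
   ΔPSI is the **signed minimum** (`--domain-agg min`, default) — the most
   negative contributing change, on the rationale that partial domain loss
   already impairs the domain. `--domain-agg max-abs` keeps the
   largest-magnitude change instead (ties resolved toward the more
   negative value) for sensitivity analyses.
4. **Mediation and assembly.** For each reference PPI whose endpoints'
   full Pfam complements contain at least one catalogued DDI pair with at
   least one *affected* member (orientation-aware: one member in each
   gene), the edge is emitted. Contributing ΔPSI values are those of every
   affected domain participating in ≥ 1 mediating pair, each affected
   domain counted once per edge (`--per-pair-weighting` counts once per
   mediating pair instead; the default avoids double-counting one
   biological change that happens to sit on several interfaces).
   Category: gain if all contributions > 0, loss if all < 0, chaos
   otherwise. Weight: arithmetic mean. Domains whose aggregate ΔPSI is
   exactly 0 (possible only with filters disabled) are directionless and
   excluded. Homodimer self-loops are computed and stored; plotting and
   Gephi/GML export drop them by default (view-level only).

### Aggregation asymmetry

The signed minimum is not antisymmetric: negating all inputs maps
min(S) to −max(S), not −min(S). Consequently, globally flipping every
event's ΔPSI mirrors the network (gain↔loss, weights negated) **only**
when each affected domain aggregates a single exon-level value; domains
hit by several exons of unequal ΔPSI break the mirror, and mixed-sign
groups can even leave an edge's category unchanged. This is a property of
the aggregation rule, not a bug; the test suite pins both the
single-event mirror and the min(−S) = −max(S) behavior, and
`scripts/acceptance.py` reports the measured mirror rate on random toy
instances (typically ~0.2 under the default generator, which produces
multi-exon domain groups on purpose). Users who need a direction-symmetric
analysis should use `--domain-agg max-abs` (antisymmetric up to exact
magnitude ties) or orient ΔPSI once via `--flip-sign` rather than
negating post hoc.

## Sample-specific mode

One sample's per-exon PSI is scored against a background PSI matrix
(exons × samples, values in [0, 1], missing cells allowed; format printed
by `splitpea background-hint`). Per exon with ≥ `--min-bg` (default 30)
non-missing background values:

* ΔPSI = observed − median(background). The median was chosen as the
  background center because tissue PSI distributions are often multimodal
  and heavy-tailed; the choice is isolated in one function for easy
  replacement.
* Empirical two-sided p-value with add-one smoothing on both tails:
  `r_lo = (1 + #{bg ≤ obs}) / (n_bg + 1)`, `r_hi` symmetric for ≥, and
  `p = min(1, 2·min(r_lo, r_hi))`, so p ∈ (0, 1] and an observation above
  all 40 background values yields p = 2/41.
* FDR by Benjamini–Hochberg across all scored exons, so the same
  significance filter applies to both modes. Exons below `min-bg` are
  reported unscored rather than imputed; missing background cells are
  dropped pairwise.

With n_bg background samples the p-values live on ⌈(n_bg+1)/2⌉ atoms
(step 2/(n_bg+1)); they are exactly valid (P(p ≤ t) ≤ t) but discrete, so
calibration is checked on the randomized probability integral transform of
the underlying tail rank, u = (#{bg ≤ obs} + η)/(n_bg + 1) with
η ~ U(0, 1), which is exactly uniform under the null. A raw KS test of the
p-values against U(0, 1) would be dominated by the discreteness and reject
a perfect null about half the time at this background size. The minimum
background of 30 reflects the point where the empirical tail becomes a
usable estimate; backgrounds such as GTEx-derived PSI tables are not
tissue-matched by default and users are encouraged to supply matched sets.

## Reference data

Four TSVs, bundled as a small synthetic demonstration set and overridable
per file: PPI edge list (gene pairs + provenance tag), DDI catalog (Pfam
pairs, version suffixes stripped), Pfam domain genomic coordinates
(gene, Pfam, chrom, strand, comma-separated 0-based half-open segments),
and an identifier map onto a canonical Entrez-style id space. Symbol
lookup is case-insensitive, accession lookup case-sensitive with Ensembl
version suffixes stripped; mapping collisions are logged and first-wins.
Unmappable rows are skipped with warning counters and become fatal only
when nothing maps. Unordered duplicate edges/pairs collapse on load.

## Synthetic data and the oracle

The `fixtures` module generates, deterministically from a config + seed:
a toy genome (one chromosome per gene, so interval bugs cannot masquerade
as plausible cross-gene overlaps), domain placements, PPI/DDI references,
and a planted truth plan of events written in both the rMATS JCEC and
SUPPA2 dpsi/psivec dialects with their native coordinate conventions.
Default conditions: 12 genes, 20 events of which 85% pass the default
filters (significant events draw |ΔPSI| ∈ [0.06, 0.6] with p ∈ [1e−6,
1e−4]; the rest fail exactly one filter). The generator emulates the
formats and the coordinate arithmetic, not biological realism: no read
counts, no realistic Pfam architectures, no correlated PSI structure —
passing tests demonstrate correctness of the algorithm and the format
handling, not performance on real tissue data.

`oracle_network` recomputes the expected network by exhaustive nested
loops (every event × every domain segment; every PPI × every domain pair)
with its own hand-rolled BH adjustment, sharing no code with the pipeline
or with statsmodels; pipeline-vs-oracle agreement is exact (edge set and
categories identical, weights within 1e−12) and is the central acceptance
property, checked over 100 random instances of up to 50 genes.

## Numerical and convention choices

* All internal coordinates 0-based half-open; conversions happen at parse
  time only and are round-trip tested.
* Normalized degree = degree / total edges (`--norm nodes` gives
  degree / (n−1)); the quantity has no universal definition, so it is a
  one-line swap. Self-loops add 1 to degree.
* Ranking tiebreak chain: category count ↓, normalized degree ↓, raw
  degree ↓, gene id ↑ (the last added for full determinism).
* Consensus identity is the unordered gene pair; categories are reported
  per network, never merged.
* Gephi export writes |weight| (negative weights break force layouts);
  the sign lives in the category column. Edge-list weights print with 6
  decimals; plots use a fixed default layout seed (42).
* Empty references are fatal; empty *results* (no rewired edges) are
  valid outputs with warnings.

## Limitations

* DDI catalogs are incomplete and biased toward well-studied families;
  absence of a mediating pair is not evidence of no effect.
* The gene-level model cannot express isoform-specific partner switches,
  only gain/loss/chaos direction per gene pair.
* Only SE events are modeled; A5SS/A3SS/MXE/RI are out of scope.
* The sample-specific significance procedure (median center + smoothed
  empirical tail) is this package's own declared formulation, chosen for
  robustness and exact validity at small background sizes; it is isolated
  behind `compare_to_background` for replacement.
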