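# splitpea

**Splicing-driven rewiring of protein–protein interaction networks.**

Alternative splicing — in particular skipping of cassette exons — can remove
or restore the protein domains that physically mediate protein–protein
interactions (PPIs). `splitpea` takes standard differential skipped-exon
statistics (rMATS or SUPPA2 output, or a single sample scored against a
multi-sample PSI background), maps each significant event onto Pfam domains
by genomic overlap, propagates the splicing change through known
domain–domain interactions (DDIs), and reports a **rewired, weighted PPI
network** in which every affected interaction is classified as a

* **gain** — all contributing ΔPSI > 0 (domain more included, interaction
  potentially strengthened),
* **loss** — all contributing ΔPSI < 0 (domain depleted, interaction
  potentially disrupted), or
* **chaos** — mixed directions.

It is aimed at anyone who already runs rMATS or SUPPA2 and wants to move
from event-level ΔPSI tables to interaction-level hypotheses.

## The model

For skipped-exon events with ΔPSI = PSI(condition) − PSI(reference),
filtered at |ΔPSI| ≥ 0.05 and FDR < 0.05 by default:

1. **Exon → domain.** An event affects every Pfam domain instance whose
   genomic footprint (0-based half-open intervals, strand-aware) overlaps
   the skipped exon by ≥ 1 base. When several exons hit one (gene, domain)
   pair, the domain is assigned the **signed minimum** of their ΔPSI —
   the most loss-like change dominates, since even partial domain loss can
   impair interaction capacity.
2. **DDI mediation.** A reference PPI (A, B) is *domain-mediated* if some
   Pfam pair (d_A ∈ domains(A), d_B ∈ domains(B)) is a known DDI. Only
   mediating pairs transmit splicing changes onto the edge.
3. **Classification and weighting.** An edge is reported when ≥ 1
   mediating pair involves an affected domain. Its weight is the
   arithmetic mean of the contributing domain-level ΔPSI values (each
   affected domain counted once per edge); the gain/loss/chaos call
   follows the signs as above.

Downstream utilities compute per-gene degree, normalized degree and edge
composition, consensus counts across multiple networks, and gene rankings
by gain/loss edge count (ties broken by normalized degree, then raw
degree, then gene id), plus Gephi/Cytoscape-ready exports and a built-in
spring-layout plot (self-loops are dropped from plots by default).

## Worked example

The package bundles a deterministic toy data generator (also used by the
test suite) so the whole pipeline runs out of the box:

```bash
splitpea fixtures --out demo --seed 1
splitpea condition --input demo/toy.SE.MATS.JCEC.txt --format rmats \
    --ppi demo/ppi.tsv --ddi demo/ddi.tsv \
    --domains demo/domains.tsv --idmap demo/idmap.tsv --out demo/net
```

prints

```
20 events parsed, 17 pass |ΔPSI|>=0.05, FDR<0.05
events: 17 in, 13 on domains; affected domains: 9
edges: 1 gain, 5 loss, 0 chaos over 7 genes
wrote demo/net.edges.tsv and demo/net.graph.pkl
```

i.e. of 20 skipped-exon events, 17 survive the default filters, 13 overlap
a Pfam domain footprint, and the splicing changes propagate through the
DDI catalog onto 6 reference PPIs — 1 predicted interaction gain and
5 losses across 7 genes. `demo/net.edges.tsv` holds one row per rewired
edge:

```
gene_a  gene_b  category  weight     n_contributing  mediating_pairs
1001    1002    loss      -0.435584  2               PF00003:PF00005
1001    1004    gain      0.382153   1               PF00002:PF00008
...
```

Summary statistics and ranking:

```bash
splitpea stats demo/net.graph.pkl
splitpea rank demo/net.graph.pkl --by loss --top 5
```

```
edges: 1 gain, 5 loss, 0 chaos (6 total), 7 genes
      degree  normalized_degree  gain  loss  chaos
gene
1003       3           0.500000     0     3      0
1001       2           0.333333     1     1      0
...
```

Gene `1003` touches 3 of the 6 rewired edges, all losses — the kind of
gene the ranking surfaces as a candidate hub of splicing-driven
disruption. `splitpea export --format {edgelist,gml,gephi}` and
`splitpea plot` produce Cytoscape/Gephi files and figures;
`splitpea sample` scores one sample against a background PSI matrix
(`splitpea background-hint` describes the expected format);
`splitpea consensus` tallies edge conservation across several networks.

For real analyses, pass your own reference files (`--ppi`, `--ddi`,
`--domains`, `--idmap`) built from resources such as BioGRID/IntAct
(PPIs), 3did/iPfam (DDIs) and Pfam genomic coordinates — the bundled
files are a small synthetic set for demonstration and testing. All
reference coordinates are 0-based half-open; SUPPA2's 1-based inclusive
event ids are converted at parse time.

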