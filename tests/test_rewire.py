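"""Core algorithm: exon->domain aggregation, DDI mediation, classification,
weighting, and full-network assembly against the brute-force oracle."""

import itertools
import random

import pytest

from conftest import run_toy_pipeline, varied_config
from splitpea.fixtures import compare_network_to_oracle, oracle_network
from splitpea.reference_data import DDICatalog, DomainAnnotation, DomainIndex, PPINetwork
from splitpea.rewire import (build_rewired_network, classify_edge, edge_weight,
                             map_events_to_domains, mediating_pairs)
from splitpea.splice_io import SpliceEvent, filter_significant, parse_rmats


def _event(i, chrom, strand, start, end, dpsi):
    return SpliceEvent(event_id=f"e{i}", gene_raw="", gene_id=None, chrom=chrom,
                       strand=strand, exon_start=start, exon_end=end,
                       delta_psi=dpsi, fdr=0.01)


def replace_dpsi(ev, dpsi):
    from dataclasses import replace
    return replace(ev, delta_psi=dpsi)


class TestMapEventsToDomains:
    def test_signed_minimum_aggregation(self):
        idx = DomainIndex([DomainAnnotation("1", "PF00001", "chr1", "+", ((100, 300),))])
        events = [_event(0, "chr1", "+", 100, 150, +0.3),
                  _event(1, "chr1", "+", 200, 250, -0.2)]
        (dom,) = map_events_to_domains(events, idx)
        assert dom.delta_psi == -0.2
        assert len(dom.contributing_events) == 2

    def test_one_exon_fans_out_to_two_domains(self):
        idx = DomainIndex([
            DomainAnnotation("1", "PF00001", "chr1", "+", ((100, 200),)),
            DomainAnnotation("1", "PF00002", "chr1", "+", ((150, 250),)),
        ])
        doms = map_events_to_domains([_event(0, "chr1", "+", 140, 210, 0.4)], idx)
        assert {(d.pfam_id, d.delta_psi) for d in doms} == {("PF00001", 0.4),
                                                            ("PF00002", 0.4)}

    def test_max_abs_aggregation_option(self):
        idx = DomainIndex([DomainAnnotation("1", "PF00001", "chr1", "+", ((0, 1000),))])
        events = [_event(0, "chr1", "+", 10, 20, +0.5),
                  _event(1, "chr1", "+", 30, 40, -0.2)]
        (dom,) = map_events_to_domains(events, idx, agg="max-abs")
        assert dom.delta_psi == 0.5

    def test_grouped_minima_match_nested_loop_oracle(self):
        rng = random.Random(31)
        anns = []
        for i in range(200):
            start = rng.randrange(0, 50_000)
            anns.append(DomainAnnotation(str(rng.randrange(30)),
                                         f"PF{rng.randrange(15):05d}",
                                         f"chr{rng.randrange(3)}", rng.choice("+-"),
                                         ((start, start + rng.randrange(50, 800)),)))
        idx = DomainIndex(anns)
        events = []
        for i in range(500):
            s = rng.randrange(0, 50_000)
            events.append(_event(i, f"chr{rng.randrange(3)}", rng.choice("+-"),
                                 s, s + rng.randrange(30, 400),
                                 round(rng.uniform(-1, 1), 3)))
        got = {(d.gene_id, d.pfam_id): d.delta_psi
               for d in map_events_to_domains(events, idx)}
        expected = {}
        for ev in events:
            for a in anns:
                if (a.chrom, a.strand) == (ev.chrom, ev.strand) and any(
                        s < ev.exon_end and ev.exon_start < e for s, e in a.intervals):
                    k = (a.gene_id, a.pfam_id)
                    expected[k] = min(expected.get(k, 1.1), ev.delta_psi)
        assert got == expected


class TestMediatingPairs:
    def _ddi(self, pairs):
        cat = DDICatalog()
        for a, b in pairs:
            cat.add(a, b)
        return cat

    def test_single_pair(self):
        ddi = self._ddi([("PF00001", "PF00002")])
        assert mediating_pairs({"PF00001"}, {"PF00002"}, ddi) == [("PF00001", "PF00002")]

    def test_empty_catalog(self):
        assert mediating_pairs({"PF00001"}, {"PF00002"}, DDICatalog()) == []

    def test_matches_cartesian_product_oracle(self):
        rng = random.Random(37)
        accs = [f"PF{i:05d}" for i in range(10)]
        ddi = self._ddi([(rng.choice(accs), rng.choice(accs)) for _ in range(15)])
        for _ in range(50):
            comp_a = set(rng.sample(accs, rng.randrange(0, 6)))
            comp_b = set(rng.sample(accs, rng.randrange(0, 6)))
            expected = sorted({tuple(sorted((x, y)))
                               for x in comp_a for y in comp_b
                               if tuple(sorted((x, y))) in ddi.pairs})
            assert mediating_pairs(comp_a, comp_b, ddi) == expected


class TestClassifyAndWeight:
    @pytest.mark.parametrize("deltas,expected", [
        ([0.2, 0.4], "gain"), ([-0.1], "loss"), ([0.2, -0.3], "chaos"),
        ([0.05], "gain"),
    ])
    def test_definition_cases(self, deltas, expected):
        assert classify_edge(deltas) == expected

    def test_all_sign_patterns_match_truth_table(self):
        # exhaustive enumeration over sign patterns of length <= 4
        for n in range(1, 5):
            for pattern in itertools.product((-0.3, 0.4), repeat=n):
                pos = all(d > 0 for d in pattern)
                neg = all(d < 0 for d in pattern)
                expected = "gain" if pos else "loss" if neg else "chaos"
                assert classify_edge(list(pattern)) == expected

    def test_empty_list_is_programming_error(self):
        with pytest.raises(ValueError):
            classify_edge([])
        with pytest.raises(ValueError):
            edge_weight([])

    def test_weight_mean_and_identity(self):
        assert edge_weight([0.2, -0.3]) == pytest.approx(-0.05)
        assert edge_weight([0.7]) == 0.7
        rng = random.Random(41)
        for _ in range(100):
            xs = [rng.uniform(-1, 1) for _ in range(rng.randrange(1, 8))]
            total = 0.0
            for x in xs:
                total += x
            assert edge_weight(xs) == pytest.approx(total / len(xs), abs=1e-15)


def _micro_setup(ddi_pairs, b_domains=("PF00002",)):
    ppi = PPINetwork()
    ppi.add_edge("A", "B")
    ddi = DDICatalog()
    for a, b in ddi_pairs:
        ddi.add(a, b)
    anns = [DomainAnnotation("A", "PF00001", "chr1", "+", ((100, 300),))]
    anns += [DomainAnnotation("B", pf, "chr2", "+", ((100, 300),)) for pf in b_domains]
    index = DomainIndex(anns)
    events = [_event(0, "chr1", "+", 150, 250, -0.4)]
    return events, ppi, ddi, index


class TestBuildRewiredNetwork:
    def test_single_path_loss_edge(self):
        events, ppi, ddi, index = _micro_setup([("PF00001", "PF00002")])
        net = build_rewired_network(events, ppi, ddi, index)
        assert set(net.edges) == {("A", "B")}
        edge = net.edges[("A", "B")]
        assert edge.category == "loss" and edge.weight == -0.4
        assert edge.mediating_pairs == (("PF00001", "PF00002"),)

    def test_mediation_required(self):
        # the DDI partner PF00003 is absent from B: no edge may be reported
        events, ppi, ddi, index = _micro_setup([("PF00001", "PF00003")])
        net = build_rewired_network(events, ppi, ddi, index)
        assert len(net) == 0

    def test_affected_domain_counted_once_per_edge_by_default(self):
        # PF00001 of A pairs with both PF00002 and PF00004 of B
        events, ppi, ddi, index = _micro_setup(
            [("PF00001", "PF00002"), ("PF00001", "PF00004")],
            b_domains=("PF00002", "PF00004"))
        net = build_rewired_network(events, ppi, ddi, index)
        assert net.edges[("A", "B")].n_contributing == 1
        per_pair = build_rewired_network(events, ppi, ddi, index,
                                         per_pair_weighting=True)
        assert per_pair.edges[("A", "B")].n_contributing == 2

    def test_every_edge_has_affected_mediating_pair(self, toy_run):
        affected = {(g, p) for e in toy_run.net.edges.values()
                    for g, p, _ in e.contributing_deltas}
        for edge in toy_run.net.edges.values():
            assert edge.mediating_pairs
            assert edge.contributing_deltas
            assert any((gene, dom) in affected
                       for gene, dom, _ in edge.contributing_deltas)
            if edge.category == "gain":
                assert edge.weight > 0
            if edge.category == "loss":
                assert edge.weight < 0

    def test_matches_oracle_on_random_instances(self, tmp_path):
        for seed in range(15):
            cfg = varied_config(seed)
            run = run_toy_pipeline(cfg, tmp_path / str(seed))
            oracle = oracle_network(cfg, run.toy, run.plan)
            assert compare_network_to_oracle(run.net, oracle) == []

    def test_classification_and_weighting_mirror_under_sign_flip(self):
        # downstream of domain aggregation the method is exactly antisymmetric
        rng = random.Random(67)
        swap = {"gain": "loss", "loss": "gain", "chaos": "chaos"}
        for _ in range(200):
            deltas = [rng.uniform(-1, 1) for _ in range(rng.randrange(1, 6))]
            flipped = [-d for d in deltas]
            assert classify_edge(flipped) == swap[classify_edge(deltas)]
            assert edge_weight(flipped) == -edge_weight(deltas)

    def test_sign_flip_mirrors_network_when_domains_have_single_events(self):
        # with one contributing exon per domain the signed-minimum aggregation
        # is trivially antisymmetric, so the whole pipeline mirrors
        events, ppi, ddi, index = _micro_setup([("PF00001", "PF00002")])
        flipped = [replace_dpsi(ev, -ev.delta_psi) for ev in events]
        net = build_rewired_network(events, ppi, ddi, index)
        mirror = build_rewired_network(flipped, ppi, ddi, index)
        assert set(net.edges) == set(mirror.edges)
        edge, other = net.edges[("A", "B")], mirror.edges[("A", "B")]
        assert (edge.category, other.category) == ("loss", "gain")
        assert other.weight == -edge.weight

    def test_signed_minimum_flips_to_signed_maximum(self):
        # the aggregation itself is NOT antisymmetric on multi-exon groups:
        # min(-S) = -max(S); this pins the documented behavior
        idx = DomainIndex([DomainAnnotation("1", "PF00001", "chr1", "+", ((0, 1000),))])
        events = [_event(0, "chr1", "+", 10, 20, +0.3),
                  _event(1, "chr1", "+", 30, 40, -0.2)]
        flipped = [replace_dpsi(ev, -ev.delta_psi) for ev in events]
        (dom,) = map_events_to_domains(events, idx)
        (neg,) = map_events_to_domains(flipped, idx)
        assert dom.delta_psi == -0.2
        assert neg.delta_psi == -0.3  # -max(S), not -min(S)

    def test_locality_unaffected_ppi_edges_are_inert(self):
        events, ppi, ddi, index = _micro_setup([("PF00001", "PF00002")])
        net1 = build_rewired_network(events, ppi, ddi, index)
        ppi.add_edge("C", "D")  # endpoints without any affected domain
        net2 = build_rewired_network(events, ppi, ddi, index)
        assert net1.edges.keys() == net2.edges.keys()
        assert {k: (e.category, e.weight) for k, e in net1.edges.items()} == \
               {k: (e.category, e.weight) for k, e in net2.edges.items()}

    def test_invariant_to_input_order(self, toy_run):
        events = filter_significant(
            parse_rmats(toy_run.outdir / "toy.rmats.txt", toy_run.idmap))
        rng = random.Random(43)
        shuffled = events[:]
        rng.shuffle(shuffled)
        net2 = build_rewired_network(shuffled, toy_run.ppi, toy_run.ddi, toy_run.index)
        assert set(net2.edges) == set(toy_run.net.edges)
        for k in net2.edges:
            assert net2.edges[k].category == toy_run.net.edges[k].category
            assert net2.edges[k].weight == pytest.approx(
                toy_run.net.edges[k].weight, abs=1e-15)

    def test_report_counts(self, toy_run):
        rep = toy_run.net.report
        assert rep["n_input_events"] == round(
            toy_run.cfg.frac_significant * toy_run.cfg.n_events)
        assert (rep["n_events_overlapping_domains"]
                + rep["n_events_without_domain_overlap"]) == rep["n_input_events"]
        assert sum(rep["n_edges"].values()) == len(toy_run.net)
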