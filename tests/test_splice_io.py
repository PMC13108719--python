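"""rMATS/SUPPA2 parsing, coordinate conventions, and significance filtering."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitpea.exceptions import InputFormatError
from splitpea.reference_data import IdMap
from splitpea.splice_io import (SpliceEvent, filter_significant,
                                format_suppa_event_id, parse_rmats, parse_suppa,
                                parse_suppa_event_id)

RMATS_HEADER = ("ID\tGeneID\tgeneSymbol\tchr\tstrand\texonStart_0base\texonEnd\t"
                "upstreamES\tupstreamEE\tdownstreamES\tdownstreamEE\t"
                "PValue\tFDR\tIncLevelDifference\n")


def _rmats_file(tmp_path, rows):
    p = tmp_path / "SE.MATS.JCEC.txt"
    p.write_text(RMATS_HEADER + "".join(rows))
    return p


def _row(ev_id="1", gene='"ENSG00000000001"', dpsi="-0.3", p="0.001", fdr="0.01",
         start="100", end="200"):
    return (f"{ev_id}\t{gene}\t\"SYM\"\tchr1\t+\t{start}\t{end}\t"
            f"10\t50\t300\t400\t{p}\t{fdr}\t{dpsi}\n")


class TestParseRmats:
    def test_direct_field_mapping(self, tmp_path):
        events = parse_rmats(_rmats_file(tmp_path, [_row()]))
        assert len(events) == 1
        ev = events[0]
        assert (ev.exon_start, ev.exon_end) == (100, 200)
        assert ev.delta_psi == -0.3
        assert ev.fdr == 0.01
        assert ev.chrom == "chr1" and ev.strand == "+"
        assert ev.gene_raw == "ENSG00000000001"

    def test_flip_sign(self, tmp_path):
        ev = parse_rmats(_rmats_file(tmp_path, [_row()]), flip_sign=True)[0]
        assert ev.delta_psi == 0.3

    def test_na_rows_skipped(self, tmp_path):
        rows = [_row(ev_id=str(i)) for i in range(17)]
        rows += [_row(ev_id=str(17 + i), dpsi="NA") for i in range(3)]
        events = parse_rmats(_rmats_file(tmp_path, rows))
        assert len(events) == 17

    def test_missing_mandatory_column_fatal(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("GeneID\tchr\n\"G\"\tchr1\n")
        with pytest.raises(InputFormatError, match="exonStart_0base|strand"):
            parse_rmats(p)

    def test_gene_id_resolution(self, tmp_path):
        m = IdMap()
        m.add("ENSG00000000001", "1001")
        ev = parse_rmats(_rmats_file(tmp_path, [_row()]), m)[0]
        assert ev.gene_id == "1001"


class TestSuppaEventId:
    def test_coordinate_convention(self):
        gene, chrom, exon, strand = parse_suppa_event_id("G1;SE:chr1:100-300:400-600:+")
        assert (gene, chrom, strand) == ("G1", "chr1", "+")
        assert exon == (299, 400)  # 1-based inclusive -> 0-based half-open

    def test_minus_strand_example(self):
        _, chrom, exon, strand = parse_suppa_event_id("G1;SE:chr2:50-101:200-351:-")
        assert (chrom, exon, strand) == ("chr2", (100, 200), "-")

    def test_missing_strand_is_error(self):
        with pytest.raises(InputFormatError):
            parse_suppa_event_id("G1;SE:chr2:50-101:200-351")

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_format_parse_round_trip(self, data):
        gene = data.draw(st.from_regex(r"[A-Z0-9]{1,8}", fullmatch=True))
        chrom = f"chr{data.draw(st.integers(1, 22))}"
        strand = data.draw(st.sampled_from("+-"))
        e1end = data.draw(st.integers(1, 10_000))
        start = e1end + data.draw(st.integers(1, 1000))
        end = start + data.draw(st.integers(1, 1000))
        e3start = end + data.draw(st.integers(1, 1000))
        sid = format_suppa_event_id(gene, chrom, (start, end), strand, e1end, e3start)
        assert parse_suppa_event_id(sid) == (gene, chrom, (start, end), strand)


class TestParseSuppa:
    def _files(self, tmp_path, rows, psivec_rows=None):
        dpsi = tmp_path / "t.dpsi"
        dpsi.write_text("a-b_dPSI\ta-b_p-val\n" + "".join(rows))
        psivec = None
        if psivec_rows is not None:
            psivec = tmp_path / "t.psivec"
            psivec.write_text("s1\ts2\n" + "".join(psivec_rows))
        return dpsi, psivec

    def test_non_se_rows_skipped(self, tmp_path):
        rows = ["G1;SE:chr1:100-300:400-600:+\t0.2\t0.001\n",
                "G1;A5:chr1:100-300:400-600:+\t0.4\t0.001\n"]
        dpsi, _ = self._files(tmp_path, rows)
        events = parse_suppa(dpsi)
        assert len(events) == 1 and events[0].delta_psi == 0.2

    def test_bh_adjustment_matches_independent_computation(self, tmp_path):
        rng = random.Random(5)
        pvals = [rng.random() for _ in range(10)]
        rows = [f"G{i};SE:chr1:{100 + i}-{300 + i}:{400 + i}-{600 + i}:+\t0.2\t{p!r}\n"
                for i, p in enumerate(pvals)]
        dpsi, _ = self._files(tmp_path, rows)
        events = parse_suppa(dpsi)
        # textbook BH oracle: step-up with cumulative minimum from the largest p
        order = sorted(range(10), key=lambda i: pvals[i])
        expected = [0.0] * 10
        running = 1.0
        for rank in range(10, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * 10 / rank)
            expected[i] = running
        got = {ev.event_id: ev.fdr for ev in events}
        for i in range(10):
            sid = f"G{i};SE:chr1:{100 + i}-{300 + i}:{400 + i}-{600 + i}:+"
            assert got[sid] == pytest.approx(expected[i], abs=1e-12)

    def test_psivec_mismatch_warns_but_proceeds(self, tmp_path, caplog):
        rows = ["G1;SE:chr1:100-300:400-600:+\t0.2\t0.001\n"]
        dpsi, psivec = self._files(tmp_path, rows,
                                   psivec_rows=["OTHER;SE:chr1:1-2:3-4:+\t0.5\t0.6\n"])
        with caplog.at_level("WARNING", logger="splitpea"):
            events = parse_suppa(dpsi, psivec)
        assert len(events) == 1
        assert any("psivec" in r.message for r in caplog.records)


def _event(dpsi, fdr, i=0):
    return SpliceEvent(event_id=f"e{i}", gene_raw="G", gene_id=None, chrom="chr1",
                       strand="+", exon_start=0, exon_end=10, delta_psi=dpsi, fdr=fdr)


class TestFilterSignificant:
    def test_threshold_logic(self):
        kept = filter_significant([_event(0.04, 0.001, 0), _event(-0.5, 0.049, 1),
                                   _event(0.5, 0.05, 2)])
        assert [e.event_id for e in kept] == ["e1"]  # |dpsi|>=0.05 strict FDR<0.05

    def test_boundary_dpsi_passes(self):
        assert filter_significant([_event(0.05, 0.01)])

    def test_null_fdr_dropped_unless_fdr_filter_disabled(self):
        ev = _event(0.3, None)
        assert filter_significant([ev]) == []
        assert filter_significant([ev], fdr_threshold=None) == [ev]

    def test_idempotent_and_order_preserving(self):
        rng = random.Random(7)
        events = [_event(rng.uniform(-1, 1), rng.random(), i) for i in range(1000)]
        once = filter_significant(events)
        assert filter_significant(once) == once
        # brute-force recount oracle
        expected = [e for e in events if abs(e.delta_psi) >= 0.05 and e.fdr < 0.05]
        assert once == expected

    def test_emitted_events_satisfy_invariants(self, tmp_path):
        rows = [_row(ev_id=str(i), dpsi=str(round(np.sin(i), 3))) for i in range(5)]
        p = tmp_path / "SE.MATS.JCEC.txt"
        p.write_text(RMATS_HEADER + "".join(rows))
        for ev in parse_rmats(p):
            ev.validate()
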