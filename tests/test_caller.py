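"""Pileup construction and threshold calling, with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocall.align import Alignment
from mitocall.caller import (
    CallerConfig,
    PileupColumn,
    build_pileup,
    call_sample,
    call_site,
)


def _aln(read_id="r", start=100, strand="+", cigar=None, seq=None, qual=None):
    cigar = cigar or [("M", len(seq))]
    qlen = sum(ln for op, ln in cigar if op in "MIS")
    return Alignment(
        read_id=read_id,
        ref_name="chrM",
        start=start,
        strand=strand,
        cigar=cigar,
        seq=seq,
        quals=qual or "?" * qlen,
    )


def _col(position, ref_fr, alt_fr, alt="T", spanning=0):
    counts = {"A": ref_fr, alt: alt_fr}
    depth = sum(ref_fr) + sum(alt_fr) + spanning
    return PileupColumn(
        position=position,
        depth=depth,
        raw_depth=depth,
        allele_counts=counts,
        spanning_deletions=spanning,
    )


class TestBuildPileup:
    def test_single_read_depth(self, ref):
        seq = ref.seq[99:249]
        pile = build_pileup([_aln(seq=seq)], ref)
        assert pile.raw_depth[100:250].sum() == 150
        assert pile.raw_depth[99] == 0 and pile.raw_depth[250] == 0

    def test_opposite_strand_counts(self, ref):
        seq = ref.seq[99:249]
        pile = build_pileup(
            [_aln("a", strand="+", seq=seq), _aln("b", strand="-", seq=seq)], ref
        )
        col = pile.column(150)
        assert col.allele_counts[ref.seq[149]] == (1, 1)

    def test_deletion_spanning_and_allele(self, ref):
        # 50M 1D 99M starting at 100: deletion removes reference base 150
        seq = ref.seq[99:149] + ref.seq[150:249]
        pile = build_pileup(
            [_aln(seq=seq, cigar=[("M", 50), ("D", 1), ("M", 99)])], ref
        )
        assert pile.spanning_del[150] == 1
        from mitocall.alleles import normalize_variant

        expected = normalize_variant(149, ref.seq[148:150], ref.seq[148], ref.seq)
        assert pile.indels == {expected: [1, 0]}

    def test_insertion_keyed_to_anchor(self, ref):
        seq = ref.seq[99:149] + "X".replace("X", "T" if ref.seq[149] != "T" else "G") + ref.seq[149:249]
        pile = build_pileup(
            [_aln(seq=seq, cigar=[("M", 50), ("I", 1), ("M", 100)])], ref
        )
        assert len(pile.indels) == 1
        (pos, refa, alta), counts = next(iter(pile.indels.items()))
        assert len(alta) == len(refa) + 1
        assert counts == [1, 0]

    def test_split_gap_representations_collapse(self, ref):
        """D1 M1 D1 and D2 tracebacks of one 2-bp deletion share one key."""
        a = _aln("a", seq=ref.seq[99:149] + ref.seq[151:249],
                 cigar=[("M", 50), ("D", 2), ("M", 98)])
        b = _aln("b", seq=ref.seq[99:149] + ref.seq[151:249],
                 cigar=[("M", 50), ("D", 1), ("M", 0), ("D", 1), ("M", 98)])
        # degenerate M0 is not emitted by the mapper; build the equivalent
        b.cigar = [("M", 50), ("D", 1), ("D", 1), ("M", 98)]
        pile = build_pileup([a, b], ref)
        assert len(pile.indels) == 1
        assert sum(next(iter(pile.indels.values()))) == 2

    def test_low_quality_bases_counted_in_depth_only(self, ref):
        seq = ref.seq[99:249]
        qual = "?" * 75 + "#" * 75  # second half below Q20
        pile = build_pileup([_aln(seq=seq, qual=qual)], ref)
        assert pile.raw_depth[200] == 1
        assert pile.passing_depth[200] == 0

    def test_out_of_bounds_rejected(self, ref):
        with pytest.raises(ValueError):
            build_pileup([_aln(start=16500, seq="A" * 150)], ref)

    def test_duplicates_and_multimappers_skipped(self, ref):
        seq = ref.seq[99:249]
        a = _aln("dup", seq=seq)
        a.is_duplicate = True
        b = _aln("mm", seq=seq)
        b.mapq = 0
        pile = build_pileup([a, b], ref)
        assert pile.raw_depth.sum() == 0


class TestCallSite:
    CFG = CallerConfig()

    def test_threshold_boundary_inclusive(self):
        calls = call_site(_col(5000, (970, 970), (30, 30)), "A", self.CFG)
        assert len(calls) == 1
        assert calls[0].klass == "HETEROPLASMY"
        assert calls[0].vaf == pytest.approx(0.03)

    def test_just_below_threshold(self):
        assert call_site(_col(5000, (971, 970), (30, 29)), "A", self.CFG) == []

    def test_strand_filter(self):
        calls = call_site(_col(5000, (960, 960), (80, 0)), "A", self.CFG)
        assert all(not c.passing for c in calls)
        assert any("STRAND_BIAS" in c.filters for c in calls)

    def test_multiallelic_site_reported_fully(self):
        col = PileupColumn(
            position=3666,
            depth=2000,
            raw_depth=2000,
            allele_counts={"G": (6, 6), "A": (759, 759), "C": (235, 235)},
            spanning_deletions=0,
        )
        calls = call_site(col, "G", self.CFG)
        assert len(calls) == 2
        by_alt = {c.alt: c for c in calls}
        assert by_alt["A"].vaf == pytest.approx(0.759)
        assert by_alt["C"].vaf == pytest.approx(0.235)
        assert by_alt["A"].vaf + by_alt["C"].vaf == pytest.approx(0.994)
        assert all(c.klass == "HETEROPLASMY" for c in calls)

    def test_homoplasmy_classification(self):
        calls = call_site(_col(5000, (10, 10), (990, 990)), "A", self.CFG)
        assert calls[0].klass == "HOMOPLASMY"

    def test_min_depth_filtered(self):
        calls = call_site(_col(5000, (2, 2), (2, 2)), "A", self.CFG)
        assert all("NO_CALL" in c.filters for c in calls)

    def test_oracle_equivalence_exhaustive(self):
        """call_site == brute-force threshold predicate for all depths <= 200.

        Enumerates every (depth, fwd, rev) composition of a biallelic column
        and compares the emitted passing call against an independent literal
        transcription of the three thresholds.
        """
        cfg = self.CFG
        for depth in range(1, 201):
            for alt_total in range(0, depth + 1):
                for fwd in range(0, alt_total + 1):
                    rev = alt_total - fwd
                    ref_n = depth - alt_total
                    col = PileupColumn(
                        position=1000,
                        depth=depth,
                        raw_depth=depth,
                        allele_counts={"A": (ref_n, 0), "T": (fwd, rev)},
                        spanning_deletions=0,
                    )
                    got = [c for c in call_site(col, "A", cfg) if c.passing]
                    expect = (
                        alt_total / depth >= cfg.vaf_min
                        and fwd >= cfg.min_reads_per_strand
                        and rev >= cfg.min_reads_per_strand
                        and depth >= cfg.min_depth
                    )
                    assert len(got) == (1 if expect else 0), (depth, fwd, rev)
                    if expect:
                        expect_class = (
                            "HOMOPLASMY"
                            if alt_total / depth >= cfg.homoplasmy_vaf
                            else "HETEROPLASMY"
                        )
                        assert got[0].klass == expect_class

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_vaf_sum_bounded_and_monotone(self, data):
        n_alleles = data.draw(st.integers(1, 4))
        counts = {}
        bases = ["A", "C", "G", "T"]
        for i in range(n_alleles):
            counts[bases[i]] = (
                data.draw(st.integers(0, 300)),
                data.draw(st.integers(0, 300)),
            )
        spanning = data.draw(st.integers(0, 50))
        depth = sum(f + r for f, r in counts.values()) + spanning
        if depth == 0:
            return
        col = PileupColumn(1000, depth, depth, counts, spanning)
        calls = call_site(col, "A", self.CFG)
        assert sum(c.vaf for c in calls) <= 1.0 + 1e-9
        strict = call_site(col, "A", CallerConfig(vaf_min=0.10))
        # raising the VAF floor never adds calls
        assert {c.alt for c in strict} <= {c.alt for c in calls}


class TestCallSample:
    def test_clean_reads_yield_no_calls(self, ref):
        alns = [
            _aln(f"r{i}", start=1 + (i * 37) % 16400, strand="+-"[i % 2],
                 seq=ref.seq[(i * 37) % 16400 : (i * 37) % 16400 + 150])
            for i in range(400)
        ]
        assert call_sample(alns, ref) == []

    def test_empty_alignments_warn(self, ref):
        with pytest.warns(UserWarning):
            assert call_sample([], ref) == []

    def test_snv_called_with_correct_vaf(self, ref):
        pos, alt = 5000, "T" if ref.seq[4999] != "T" else "A"
        alns = []
        for i in range(200):
            start = pos - 149 + (i * 13) % 140
            seq = list(ref.seq[start - 1 : start + 149])
            if i % 5 == 0:  # 20% carriers
                seq[pos - start] = alt
            alns.append(_aln(f"r{i}", start=start, strand="+-"[i % 2], seq="".join(seq)))
        calls = call_sample(alns, ref)
        assert [c.key() for c in calls] == [(pos, ref.seq[4999], alt)]
        assert calls[0].vaf == pytest.approx(0.2, abs=0.02)
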