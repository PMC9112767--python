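"""Mapper: indexing, placement, origin splitting, duplicates, down-sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocall.align import (
    Alignment,
    build_index,
    downsample,
    map_read,
    map_reads,
    mark_duplicates,
    split_origin_spanning,
)
from mitocall.reference import ReferenceBundle, revcomp
from mitocall.simulate import ReadPair, SimConfig, simulate_reads


@pytest.fixture(scope="module")
def index(ref):
    return build_index(ref)


def _aln(read_id="r", start=1, strand="+", cigar=((("M"), 150),), seq=None, quals=None, **kw):
    cigar = [tuple(c) for c in cigar]
    qlen = sum(ln for op, ln in cigar if op in "MIS")
    return Alignment(
        read_id=read_id,
        ref_name="chrM",
        start=start,
        strand=strand,
        cigar=cigar,
        seq=seq or "A" * qlen,
        quals=quals or "?" * qlen,
        **kw,
    )


class TestIndex:
    def test_small_k_rejected(self, ref):
        with pytest.raises(ValueError):
            build_index(ref, k=5)

    def test_toy_repeat_index(self):
        toy = ReferenceBundle("t", "ACGTACGTTTTT", ext_len=4)
        idx = build_index(toy, k=11)
        assert idx.k == 11

    def test_full_coverage_of_offsets(self, ref, index):
        n_offsets = sum(len(v) for v in index.positions.values())
        assert n_offsets == ref.L + ref.ext_len - 21 + 1


class TestMapRead:
    def test_exact_forward_read(self, ref, index):
        seq = ref.ext_seq[99:249]  # positions 100..249
        aln = map_read("r1", seq, "?" * 150, index, ref)
        assert aln.start == 100
        assert aln.strand == "+"
        assert aln.cigar == [("M", 150)]
        assert aln.score == 0

    def test_reverse_read(self, ref, index):
        aln = map_read("r2", revcomp(ref.ext_seq[499:649]), "?" * 150, index, ref)
        assert aln.start == 500
        assert aln.strand == "-"

    def test_junction_read_splits_across_origin(self, ref, index):
        seq = ref.ext_seq[16499:16649]  # circle positions 16500..16569,1..80
        aln = map_read("r3", seq, "?" * 150, index, ref)
        pieces = split_origin_spanning(aln, ref.L)
        assert [(p.start, p.ref_span) for p in pieces] == [(16500, 70), (1, 80)]

    def test_unrelated_sequence_unmapped(self, ref, index):
        rng = np.random.default_rng(4)
        while True:
            seq = "".join(rng.choice(list("ACGT"), 150))
            kmers = {seq[i : i + 21] for i in range(130)}
            rc = revcomp(seq)
            kmers |= {rc[i : i + 21] for i in range(130)}
            if not any(k in ref.ext_seq for k in kmers):
                break
        assert map_read("junk", seq, "?" * 150, index, ref) is None

    def test_substitutions_keep_full_length_match(self, ref, index):
        seq = list(ref.ext_seq[999:1149])
        seq[0] = "A" if seq[0] != "A" else "C"  # terminal mismatch
        seq[75] = "A" if seq[75] != "A" else "C"
        aln = map_read("r4", "".join(seq), "?" * 150, index, ref)
        assert aln.start == 1000
        assert aln.cigar == [("M", 150)]
        assert aln.score == 2

    def test_deletion_read(self, ref, index):
        seq = ref.ext_seq[1999:2069] + ref.ext_seq[2071:2151]  # drop 2071..2072
        aln = map_read("r5", seq, "?" * 150, index, ref)
        # the traceback may split the 2-bp gap, but the placement and total
        # deleted length are fixed (the pileup canonicalizes representation)
        assert aln.start == 2000
        assert sum(ln for op, ln in aln.cigar if op == "D") == 2
        assert aln.ref_span == 152


class TestSplitOriginSpanning:
    def test_non_spanning_identity(self):
        aln = _aln(start=100)
        assert split_origin_spanning(aln, 16569) == [aln]

    def test_arithmetic_partition(self):
        pieces = split_origin_spanning(_aln(start=16500), 16569)
        assert [(p.start, p.cigar) for p in pieces] == [
            (16500, [("M", 70)]),
            (1, [("M", 80)]),
        ]

    def test_insertion_stays_with_anchor_piece(self):
        aln = _aln(start=16569, cigar=[("M", 1), ("I", 1), ("M", 149)])
        pieces = split_origin_spanning(aln, 16569)
        assert pieces[0].cigar == [("M", 1), ("I", 1)]
        assert pieces[1].cigar == [("M", 149)]
        assert pieces[1].start == 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_conserves_reference_and_read_bases(self, data):
        ops = data.draw(
            st.lists(
                st.tuples(st.sampled_from("MID"), st.integers(1, 80)),
                min_size=1,
                max_size=6,
            )
        )
        # legalize: start/end with M, no adjacent identical ops
        cigar = [("M", 30)]
        for op, ln in ops:
            if cigar[-1][0] != op:
                cigar.append((op, ln))
        if cigar[-1][0] != "M":
            cigar.append(("M", 10))
        aln = _aln(start=data.draw(st.integers(16300, 16569)), cigar=cigar)
        L = 16569
        if aln.end <= L:
            return
        pieces = split_origin_spanning(aln, L)
        assert sum(p.ref_span for p in pieces) == aln.ref_span
        assert sum(p.query_len for p in pieces) == aln.query_len
        assert pieces[0].end == L and pieces[-1].start == 1


class TestDuplicates:
    def _pair(self, rid, s1, s2, q="?"):
        return [
            _aln(read_id=rid, start=s1, strand="+", quals=q * 150),
            _aln(read_id=rid, start=s2, strand="-"),
        ]

    def test_identical_pairs_one_marked(self):
        alns = self._pair("a", 100, 300) + self._pair("b", 100, 300)
        mark_duplicates(alns)
        dup_ids = {a.read_id for a in alns if a.is_duplicate}
        assert len(dup_ids) == 1

    def test_distinct_pairs_unmarked(self):
        alns = self._pair("a", 100, 300) + self._pair("b", 101, 300)
        mark_duplicates(alns)
        assert not any(a.is_duplicate for a in alns)

    def test_counting(self):
        alns = []
        for rid in "abc":
            alns += self._pair(rid, 500, 700)
        alns += self._pair("d", 100, 300) + self._pair("e", 200, 400)
        mark_duplicates(alns)
        assert sum(a.is_duplicate for a in alns) == 4  # 2 pairs of the trio

    def test_highest_quality_pair_retained(self):
        alns = self._pair("low", 100, 300, q="#") + self._pair("high", 100, 300, q="I")
        mark_duplicates(alns)
        assert {a.read_id for a in alns if a.is_duplicate} == {"low"}


class TestDownsample:
    def _pairs(self, n):
        out = []
        for i in range(n):
            out += [
                _aln(read_id=f"p{i}", start=100),
                _aln(read_id=f"p{i}", start=400, strand="-"),
            ]
        return out

    def test_reduces_to_target(self):
        L = 16569
        n = int(4000 * L / 300)
        alns = self._pairs(n)
        kept = downsample(alns, target_cov=2000, L=L, seed=3)
        cov = sum(a.query_len for a in kept) / L
        assert abs(cov - 2000) / 2000 < 0.05
        assert {a.read_id for a in kept} <= {a.read_id for a in alns}

    def test_identity_below_target(self):
        alns = self._pairs(100)
        assert downsample(alns, target_cov=2000, L=16569, seed=1) == alns

    def test_seeded_determinism(self):
        alns = self._pairs(5000)
        k1 = downsample(alns, target_cov=10, L=16569, seed=9)
        k2 = downsample(alns, target_cov=10, L=16569, seed=9)
        assert [a.read_id for a in k1] == [a.read_id for a in k2]


class TestMappingAccuracy:
    def test_error_free_reads_recover_true_origin(self, ref, index):
        """>= 99.9% of clean simulated reads map to their true position."""
        cfg = SimConfig(coverage=20, seed=31, error_rate=0.0, n_snv=0, n_indel=0)
        pairs = simulate_reads(ref.seq, ref.seq, [], cfg)
        total = correct = 0
        for p in pairs:
            for seq, qual, pos, strand in (
                (p.seq1, p.qual1, p.pos1, p.strand1),
                (p.seq2, p.qual2, p.pos2, p.strand2),
            ):
                aln = map_read(p.read_id, seq, qual, index, ref)
                total += 1
                correct += (
                    aln is not None and aln.start == pos and aln.strand == strand
                )
        assert correct / total >= 0.999

    def test_dloop_coverage_recovered(self, ref, index):
        """Mean depth at the circle ends stays >= 90% of the genome-wide mean."""
        cfg = SimConfig(coverage=40, seed=37, error_rate=0.01, n_snv=0, n_indel=0)
        pairs = simulate_reads(ref.seq, ref.seq, [], cfg)
        alns = map_reads(pairs, index, ref)
        depth = np.zeros(ref.L + 2, dtype=np.int64)
        for a in alns:
            if not a.is_duplicate and a.mapq > 0:
                depth[a.start : a.start + a.ref_span] += 1
        dloop = np.r_[depth[1:301], depth[16270 : ref.L + 1]]
        assert dloop.mean() >= 0.9 * depth[1 : ref.L + 1].mean()
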