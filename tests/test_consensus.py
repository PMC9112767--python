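"""Consensus building, coordinate liftover, validation, second iteration."""

import numpy as np
import pytest

from mitocall.align import Alignment
from mitocall.caller import VariantCall
from mitocall.consensus import (
    ConsensusEdit,
    ConsensusMap,
    build_consensus,
    lift_to_reference,
    second_iteration,
    validate_consensus,
)
from mitocall.pipeline import run_simulated_sample
from mitocall.simulate import SimConfig


def _call(pos, ref, alt, vaf, klass=None, **kw):
    if klass is None:
        klass = "HOMOPLASMY" if vaf >= 0.97 else "HETEROPLASMY"
    return VariantCall(
        position=pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        depth=2000,
        strand_counts=(int(1000 * vaf), int(1000 * vaf)),
        type="SNV" if len(ref) == len(alt) == 1 else ("INS" if len(alt) > len(ref) else "DEL"),
        klass=klass,
        **kw,
    )


class TestBuildConsensus:
    def test_no_calls_identity(self, ref):
        cmap = build_consensus(ref, [])
        assert cmap.consensus_seq == ref.seq
        for p in (1, 302, 8000, 16569):
            assert cmap.to_consensus(p) == p
            assert cmap.to_reference(p) == (p, False)

    def test_single_homoplasmy(self, ref):
        cmap = build_consensus(ref, [_call(73, "A", "G", 0.995)])
        assert cmap.consensus_seq[72] == "G"
        diffs = [i for i, (a, b) in enumerate(zip(cmap.consensus_seq, ref.seq)) if a != b]
        assert diffs == [72]

    def test_minor_heteroplasmy_not_applied(self, ref):
        cmap = build_consensus(ref, [_call(73, "A", "G", 0.40)])
        assert cmap.consensus_seq == ref.seq

    def test_major_heteroplasmy_applied(self, ref):
        cmap = build_consensus(ref, [_call(73, "A", "G", 0.74)])
        assert cmap.consensus_seq[72] == "G"

    def test_insertion_shifts_downstream_map(self, ref):
        cmap = build_consensus(ref, [_call(302, "A", "ACC", 0.74)])
        assert len(cmap.consensus_seq) == ref.L + 2
        assert cmap.to_consensus(5000) == 5002
        assert cmap.to_reference(5002) == (5000, False)

    def test_highest_vaf_wins_multiallelic(self, ref):
        base = ref.seq[4999]
        alts = [b for b in "ACGT" if b != base]
        cmap = build_consensus(
            ref, [_call(5000, base, alts[0], 0.55), _call(5000, base, alts[1], 0.44)]
        )
        assert cmap.consensus_seq[4999] == alts[0]

    def test_overlapping_indel_edits_rejected(self, ref):
        a = _call(100, ref.seq[99:103], ref.seq[99], 0.99)
        b = _call(102, ref.seq[101], ref.seq[101] + "TT", 0.99)
        with pytest.raises(ValueError, match="position"):
            ConsensusMap(ref, [
                ConsensusEdit(a.position, a.ref, a.alt, a.vaf),
                ConsensusEdit(b.position, b.ref, b.alt, b.vaf),
            ])


class TestLiftover:
    def test_identity_map(self, ref):
        cmap = build_consensus(ref, [])
        call = _call(5000, ref.seq[4999], "T" if ref.seq[4999] != "T" else "A", 0.10)
        lifted = lift_to_reference(call, cmap)
        assert lifted.position == 5000
        assert lifted.iteration == 2

    def test_offset_bookkeeping_through_insertion(self, ref):
        cmap = build_consensus(ref, [_call(302, "A", "ACC", 0.74)])
        base = cmap.consensus_seq[5001]
        call = _call(5002, base, "T" if base != "T" else "A", 0.10)
        assert lift_to_reference(call, cmap).position == 5000

    def test_allele_switch(self, ref):
        cmap = build_consensus(ref, [_call(73, "A", "G", 0.995)])
        minor = _call(73, "G", "A", 0.04)
        lifted = lift_to_reference(minor, cmap)
        assert (lifted.position, lifted.ref, lifted.alt) == (73, "A", "G")
        assert lifted.annotations.get("ALLELE_SWITCH") is True
        assert lifted.annotations.get("MINOR_VAF") == pytest.approx(0.04)
        assert lifted.vaf == pytest.approx(0.96)
        assert lifted.klass == "HETEROPLASMY"

    def test_call_inside_consensus_insertion(self, ref):
        cmap = build_consensus(ref, [_call(302, "A", "ACC", 0.74)])
        call = _call(303, "C", "T", 0.10)  # consensus 303 is the first inserted C
        lifted = lift_to_reference(call, cmap)
        assert lifted.position == 302
        assert lifted.annotations.get("IN_CONSENSUS_INS") is True

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_identity_everywhere(self, ref, seed):
        """forward-then-inverse is identity at every unedited position."""
        rng = np.random.default_rng(seed)
        edits = []
        edited = set()
        for pos in sorted(rng.choice(np.arange(100, ref.L - 100), 25, replace=False)):
            pos = int(pos)
            if any(abs(pos - q) < 8 for q in edited):
                continue
            kind = rng.integers(0, 3)
            base = ref.seq[pos - 1]
            if kind == 0:
                alt = "ACGT"[("ACGT".index(base) + 1) % 4]
                edits.append(ConsensusEdit(pos, base, alt, 0.99))
            elif kind == 1:
                edits.append(ConsensusEdit(pos, base, base + "AT", 0.99))
            else:
                edits.append(ConsensusEdit(pos, ref.seq[pos - 1 : pos + 2], base, 0.99))
            edited.update(range(pos, pos + 4))
        cmap = ConsensusMap(ref, edits)
        for p in range(1, ref.L + 1):
            if p in edited:
                continue
            cp = cmap.to_consensus(p)
            assert cmap.to_reference(cp) == (p, False), p


class TestValidateConsensus:
    def _exact(self, rid, start, length=150):
        return Alignment(
            read_id=rid, ref_name="c", start=start, strand="+",
            cigar=[("M", length)], seq="A" * length, quals="?" * length,
            score=0,
        )

    def test_tiling_reads_fully_cover(self, ref):
        cmap = build_consensus(ref, [])
        alns = [self._exact(f"r{i}", s) for i, s in enumerate(range(1, ref.L - 148, 100))]
        alns.append(self._exact("tail", ref.L - 149))
        ok, uncovered = validate_consensus(cmap, alns)
        assert ok and uncovered == []

    def test_gap_reported(self, ref):
        cmap = build_consensus(ref, [])
        alns = [self._exact(f"r{i}", s) for i, s in enumerate(range(1, ref.L - 148, 100))
                if not 900 <= s <= 1100]
        alns.append(self._exact("tail", ref.L - 149))
        ok, uncovered = validate_consensus(cmap, alns)
        assert not ok
        assert any(iv.start <= 1050 <= iv.end for iv in uncovered)

    def test_small_overlap_not_merged(self, ref):
        cmap = build_consensus(ref, [])
        # 3-base overlap: below the 5-base merge floor, so a seam remains
        alns = [self._exact("a", 1, 150), self._exact("b", 148, 150)]
        ok, uncovered = validate_consensus(cmap, alns)
        assert not ok


class TestSecondIteration:
    def test_homoplasmies_absorbed(self, ref, panel):
        """A pure-backbone sample yields no calls at all in iteration 2."""
        from mitocall.caller import call_sample
        from mitocall import align as _align
        from mitocall.simulate import build_sample_genome, simulate_reads

        profile = panel[3]
        genome = build_sample_genome(ref, profile)
        cfg = SimConfig(coverage=120, seed=51, n_snv=0, n_indel=0, error_rate=0.0)
        pairs = simulate_reads(genome, genome, [], cfg)
        index = _align.build_index(ref)
        alns = [a for a in _align.map_reads(pairs, index, ref) if not a.is_duplicate]
        calls1 = call_sample(alns, ref)
        assert {c.key() for c in calls1 if c.klass == "HOMOPLASMY"} == set(profile.snvs)
        calls2, _ = second_iteration(pairs, calls1, ref, seed=51)
        assert calls2 == []

    def test_no_homoplasmies_survive_with_errors(self, ref, panel):
        """With sequencing errors the absorption still removes every homoplasmy."""
        from mitocall.caller import call_sample
        from mitocall import align as _align
        from mitocall.simulate import build_sample_genome, simulate_reads

        profile = panel[7]
        genome = build_sample_genome(ref, profile)
        cfg = SimConfig(coverage=120, seed=57, n_snv=0, n_indel=0)
        pairs = simulate_reads(genome, genome, [], cfg)
        index = _align.build_index(ref)
        alns = [a for a in _align.map_reads(pairs, index, ref) if not a.is_duplicate]
        calls1 = call_sample(alns, ref)
        calls2, _ = second_iteration(pairs, calls1, ref, seed=57)
        assert [c for c in calls2 if c.klass == "HOMOPLASMY"] == []

    def test_heteroplasmy_count_not_inflated(self, ref, panel):
        res = run_simulated_sample(
            ref, panel[2], SimConfig(coverage=150, seed=53), target_cov=2000
        )
        assert len(res.het_calls(2)) <= len(res.het_calls(1))
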