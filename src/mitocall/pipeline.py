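"""End-to-end orchestration for simulated benchmark samples.

One sample = one haplogroup backbone + injected heteroplasmies, sequenced to
a target coverage, mapped to the circularized reference, called (iteration
1), consensus-rebuilt and re-called (iteration 2), then scored against the
simulator's truth set.  ``benchmark_suite`` runs a panel of such samples and
reports per-sample and mean false-negative/false-positive counts, which is
the toolkit's primary validation surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import align as _align
from .annotate import annotate_calls, assign_haplogroup, contamination_screen
from .caller import CallerConfig, VariantCall, call_sample
from .consensus import ConsensusMap, second_iteration
from .reference import (
    ReferenceBundle,
    RegionTrack,
    default_reference,
    find_homopolymer_regions,
)
from .report import TruthComparison, compare_to_truth
from .simulate import (
    HaplogroupProfile,
    ReadPair,
    SimConfig,
    TruthVariant,
    build_sample_genome,
    default_haplogroup_panel,
    inject_heteroplasmies,
    simulate_reads,
)


@dataclass
class SampleResult:
    sample_id: str
    profile: HaplogroupProfile
    truth: list[TruthVariant]
    calls_iter1: list[VariantCall]
    calls_iter2: list[VariantCall]
    consensus: ConsensusMap
    score_iter1: TruthComparison
    score_iter2: TruthComparison
    haplogroup: str = ""

    def het_calls(self, iteration: int) -> list[VariantCall]:
        calls = self.calls_iter1 if iteration == 1 else self.calls_iter2
        return [c for c in calls if c.klass == "HETEROPLASMY" and c.passing]


def run_simulated_sample(
    ref: ReferenceBundle,
    profile: HaplogroupProfile,
    sim_cfg: SimConfig,
    caller_cfg: CallerConfig | None = None,
    index: _align.AlignerIndex | None = None,
    hp_track: RegionTrack | None = None,
    target_cov: float = 2000.0,
    sample_id: str | None = None,
) -> SampleResult:
    """Simulate one sample and run both calling iterations against truth."""
    caller_cfg = caller_cfg or CallerConfig()
    if hp_track is None:
        hp_track = RegionTrack("HP", intervals=find_homopolymer_regions(ref.seq))
    if index is None:
        index = _align.build_index(ref)

    backbone = build_sample_genome(ref, profile)
    alt_genome, truth = inject_heteroplasmies(
        backbone,
        sim_cfg,
        hp_track=hp_track,
        forbidden_positions={p for p, _, _ in profile.snvs},
    )
    pairs = simulate_reads(backbone, alt_genome, truth, sim_cfg)

    alns = _align.map_reads(pairs, index, ref)
    alns = [a for a in alns if not a.is_duplicate]
    alns = _align.downsample(alns, target_cov=target_cov, L=ref.L, seed=sim_cfg.seed)
    calls1 = call_sample(alns, ref, caller_cfg, hp_track=hp_track, iteration=1)
    calls2, cmap = second_iteration(
        pairs, calls1, ref, caller_cfg, target_cov=target_cov, seed=sim_cfg.seed
    )
    het1 = [c for c in calls1 if c.klass == "HETEROPLASMY" and c.passing]
    het2 = [c for c in calls2 if c.klass == "HETEROPLASMY" and c.passing]
    return SampleResult(
        sample_id=sample_id or profile.name,
        profile=profile,
        truth=truth,
        calls_iter1=calls1,
        calls_iter2=calls2,
        consensus=cmap,
        score_iter1=compare_to_truth(het1, truth),
        score_iter2=compare_to_truth(het2, truth),
    )


def benchmark_suite(
    n_samples: int = 10,
    coverage: float = 2000.0,
    seed: int = 1,
    ref: ReferenceBundle | None = None,
    caller_cfg: CallerConfig | None = None,
    sim_overrides: dict | None = None,
) -> tuple[pd.DataFrame, list[SampleResult]]:
    """Run the benchmark: n haplogroup samples, both iterations, scored.

    Samples use distinct haplogroup backbones from the default panel (chosen
    by seeded draw when fewer than the panel size) and per-sample seeds
    derived from ``seed``.  Returns a per-sample score table and the full
    results.
    """
    ref = ref or default_reference()
    rng = np.random.default_rng(seed)
    panel = default_haplogroup_panel(ref)
    if n_samples > len(panel):
        raise ValueError(f"at most {len(panel)} samples available")
    chosen = sorted(rng.choice(len(panel), size=n_samples, replace=False))
    index = _align.build_index(ref)
    hp_track = RegionTrack("HP", intervals=find_homopolymer_regions(ref.seq))

    rows = []
    results = []
    for i in chosen:
        profile = panel[int(i)]
        sample_seed = int(rng.integers(0, 2**31 - 1))
        sim_cfg = SimConfig(
            coverage=coverage, seed=sample_seed, **(sim_overrides or {})
        )
        res = run_simulated_sample(
            ref,
            profile,
            sim_cfg,
            caller_cfg=caller_cfg,
            index=index,
            hp_track=hp_track,
            target_cov=coverage,
        )
        results.append(res)
        rows.append(
            {
                "sample": res.sample_id,
                "n_truth": len(res.truth),
                "sites_iter1": len(res.het_calls(1)),
                "fn_iter1": res.score_iter1.false_negatives,
                "fp_iter1": res.score_iter1.false_positives,
                "sites_iter2": len(res.het_calls(2)),
                "fn_iter2": res.score_iter2.false_negatives,
                "fp_iter2": res.score_iter2.false_positives,
            }
        )
    return pd.DataFrame(rows), results


def annotate_and_classify(
    result: SampleResult,
    tracks,
    panel: list[HaplogroupProfile],
):
    """Annotate both call sets and attach haplogroup/contamination info."""
    annotate_calls(result.calls_iter1, tracks)
    annotate_calls(result.calls_iter2, tracks)
    label, _, _ = assign_haplogroup(result.calls_iter1, panel)
    result.haplogroup = label
    mix = contamination_screen(result.calls_iter2, panel, primary_hg=label)
    return label, mix
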