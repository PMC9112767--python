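"""Variant annotation, simplified haplogroup assignment, contamination screen.

Annotations give each call its genomic context: hypervariable region (HV),
homopolymer tract (HP), mutational hotspot (HS), D-loop/gene membership, and
whether the exact allele is a known NUMT artifact, a haplogroup-defining SNV
or a catalogued population variant.  All flags are pure functions of the
loaded tracks, so annotating twice changes nothing.

Haplogrouping here is a deliberately small surrogate for tree-based
classifiers: the sample is assigned to the panel profile whose defining SNVs
best match its homoplasmies.  The contamination screen exploits maternal
inheritance — a clean sample carries ONE haplogroup, so heteroplasmies that
collectively trace a second profile at a consistent allele fraction indicate
a mixed sample.  Samples at or above 3% estimated mixture are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from .caller import VariantCall
from .reference import RegionTrack
from .simulate import HaplogroupProfile

CONTAMINATION_LEVEL = 0.03
CONTAMINATION_MIN_SITES = 3


@dataclass
class MixtureReport:
    primary_hg: str
    secondary_hg: str | None
    mixture_level: float
    n_support: int
    flagged: bool


def annotate_call(
    call: VariantCall, tracks: dict[str, RegionTrack]
) -> VariantCall:
    """Set membership flags from region tracks and site lists (idempotent)."""
    pos = call.position
    ann = call.annotations
    for kind in ("HP", "HV", "HS"):
        track = tracks.get(kind)
        if track is not None and pos in track:
            ann[kind] = True
        else:
            ann.pop(kind, None)
    genic = tracks.get("GENIC")
    ann.pop("DLOOP", None)
    ann.pop("GENE", None)
    if genic is not None:
        labels = genic.labels_at(pos)
        if any(lab == "Dloop" for lab in labels):
            ann["DLOOP"] = True
        genes = [lab[4:] for lab in labels if lab.startswith("CDS:")]
        if genes:
            ann["GENE"] = ",".join(genes)
    for kind in ("NUMT", "HG", "DBSNP"):
        track = tracks.get(kind)
        if track is not None and track.contains_site(pos, call.ref, call.alt):
            ann[kind] = True
        else:
            ann.pop(kind, None)
    hp = tracks.get("HP")
    if call.type != "SNV" and hp is not None and hp.intervals:
        dist = hp.nearest_distance(pos)
        if dist is not None and dist <= 150:
            ann["HP_ADJACENT"] = True
    return call


def annotate_calls(
    calls: list[VariantCall], tracks: dict[str, RegionTrack]
) -> list[VariantCall]:
    for c in calls:
        annotate_call(c, tracks)
    return calls


def _profile_score(
    profile: HaplogroupProfile, homoplasmies: set[tuple[int, str, str]]
) -> float:
    matched = sum(1 for snv in profile.snvs if snv in homoplasmies)
    missed = len(profile.snvs) - matched
    return (matched - missed) / len(profile.snvs) if profile.snvs else -1.0


def assign_haplogroup(
    calls: list[VariantCall], profiles: list[HaplogroupProfile]
) -> tuple[str, float, bool]:
    """Best-matching profile for a sample's homoplasmic calls.

    Score per profile: (matched defining SNVs - unmatched) / profile size.
    Ties prefer the smaller profile (closer to the reference backbone), then
    the lexicographically smallest label with an ambiguity flag.

    Returns (label, match_fraction, ambiguous).
    """
    if not profiles:
        raise ValueError("need at least one haplogroup profile")
    homs = {c.key() for c in calls if c.klass == "HOMOPLASMY" and c.passing}
    scored = sorted(
        profiles,
        key=lambda p: (-_profile_score(p, homs), len(p.snvs), p.name),
    )
    best = scored[0]
    best_score = _profile_score(best, homs)
    ambiguous = (
        len(scored) > 1
        and _profile_score(scored[1], homs) == best_score
        and len(scored[1].snvs) == len(best.snvs)
    )
    matched = sum(1 for snv in best.snvs if snv in homs)
    fraction = matched / len(best.snvs) if best.snvs else 0.0
    return best.name, fraction, ambiguous


def contamination_screen(
    calls: list[VariantCall],
    profiles: list[HaplogroupProfile],
    primary_hg: str | None = None,
    level_threshold: float = CONTAMINATION_LEVEL,
    min_sites: int = CONTAMINATION_MIN_SITES,
) -> MixtureReport:
    """Screen for a second haplogroup hiding among the heteroplasmies.

    For every non-primary profile, count heteroplasmic calls matching its
    defining alleles; the best-supported profile's median matching VAF is
    the mixture estimate.  Flagged when the estimate reaches
    ``level_threshold`` with at least ``min_sites`` supporting sites.
    """
    if primary_hg is None:
        primary_hg, _, _ = assign_haplogroup(calls, profiles)
    hets = {
        c.key(): c.vaf for c in calls if c.klass == "HETEROPLASMY" and c.passing
    }
    best_label = None
    best_support: list[float] = []
    for profile in profiles:
        if profile.name == primary_hg:
            continue
        support = [hets[snv] for snv in profile.snvs if snv in hets]
        if len(support) > len(best_support) or (
            len(support) == len(best_support)
            and best_label is not None
            and profile.name < best_label
            and support
        ):
            best_label, best_support = profile.name, support
    if not best_support:
        return MixtureReport(primary_hg, None, 0.0, 0, False)
    level = min(float(median(best_support)), 0.5)
    flagged = level >= level_threshold and len(best_support) >= min_sites
    return MixtureReport(primary_hg, best_label, level, len(best_support), flagged)
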