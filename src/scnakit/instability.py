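"""Genomic-instability readouts from a status-called segmented profile.

Three score families are computed:

* the genomic index GI = A^2 / C, where A is the number of maximal altered
  (gain or loss) runs after merging adjacent same-status segments and C the
  number of distinct autosomes carrying at least one alteration;
* somatic copy-number alteration (SCNA) counts at the focal, arm and
  chromosome levels (focal: event spanning < 50% of its arm; chromosome:
  both arms carry a same-status non-focal event with sufficient coverage;
  arm: every other non-focal event);
* a shallow-coverage style large-genomic-alteration (LGA) count: per-profile
  one-copy cutoff estimation, step-wise smoothing, small-segment integration
  with interstitial filtering, then counting breaks between adjacent large
  (>= 10 Mb) same-arm segments, and the HRD call at a threshold of 18.

Sex chromosomes are excluded from every score by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import MB, GenomeModel, Segment, SegmentedProfile

__all__ = [
    "LgaConfig",
    "AlterationEvent",
    "InstabilityScores",
    "genomic_index",
    "build_events",
    "classify_events",
    "scna_scores",
    "estimate_one_copy_cutoff",
    "smooth_profile",
    "integrate_small_segments",
    "count_lga",
    "call_hrd",
    "score_profile",
    "score_cohort",
    "split_at_centromeres",
]


@dataclass(frozen=True)
class LgaConfig:
    """Tuning constants of the LGA/HRD caller."""

    large_segment_mb: float = 10.0
    small_segment_mb: float = 3.0
    smoothing_segment_mb: float = 3.0  # minimum size taking part in step-wise smoothing
    max_gap_mb: float = 3.0
    hrd_threshold: int = 18
    cutoff_floor: float = 0.15
    cutoff_ceiling: float = 0.9
    cutoff_fallback: float = 0.3
    cutoff_bin_width: float = 0.05
    cutoff_min_pairs: int = 5
    cutoff_margin: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.small_segment_mb < self.large_segment_mb):
            raise ValueError("need 0 < small_segment_mb < large_segment_mb")
        if self.hrd_threshold < 0 or self.cutoff_fallback <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.cutoff_floor < self.cutoff_ceiling):
            raise ValueError("need 0 < cutoff_floor < cutoff_ceiling")


@dataclass(frozen=True)
class AlterationEvent:
    chrom: str
    status: str  # gain | loss
    start: int
    end: int
    arm: str  # p | q
    arm_fraction: float
    level: str | None = None  # focal | arm | chromosome

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InstabilityScores:
    sample_id: str
    genomic_index: float
    n_alterations: int  # A in GI = A^2/C
    n_chromosomes_altered: int  # C
    focal_amp: int
    focal_del: int
    arm_amp: int
    arm_del: int
    chrom_amp: int
    chrom_del: int
    lga_count: int
    one_copy_cutoff: float
    hrd_call: str  # HRD | HRP | undetermined

    def to_dict(self) -> dict:
        return {
            "sample": self.sample_id,
            "gi": self.genomic_index,
            "A": self.n_alterations,
            "C": self.n_chromosomes_altered,
            "focal_amp": self.focal_amp,
            "focal_del": self.focal_del,
            "arm_amp": self.arm_amp,
            "arm_del": self.arm_del,
            "chrom_amp": self.chrom_amp,
            "chrom_del": self.chrom_del,
            "one_copy_cutoff": self.one_copy_cutoff,
            "lga": self.lga_count,
            "hrd_call": self.hrd_call,
        }


def _scoring_chromosomes(profile: SegmentedProfile, genome: GenomeModel | None, include_sex: bool):
    chroms = profile.chromosomes()
    if include_sex or genome is None:
        if include_sex:
            return chroms
        sex = {"x", "y", "chrx", "chry"}
        return [c for c in chroms if c.lower() not in sex]
    keep = {c.name for c in genome.autosomes()}
    return [c for c in chroms if c in keep]


# ---------------------------------------------------------------------------
# genomic index


def genomic_index(
    profile: SegmentedProfile,
    genome: GenomeModel | None = None,
    include_sex: bool = False,
) -> tuple[float, int, int]:
    """GI = A^2/C over maximal merged altered runs on autosomes.

    Returns (GI, A, C); GI is 0 when there is no alteration.
    """
    a = 0
    chroms_hit: set[str] = set()
    by_chrom = profile.by_chromosome()
    for chrom in _scoring_chromosomes(profile, genome, include_sex):
        prev_status = None
        for seg in by_chrom[chrom]:
            if seg.status in ("gain", "loss"):
                if seg.status != prev_status:
                    a += 1
                    chroms_hit.add(chrom)
            prev_status = seg.status
    c = len(chroms_hit)
    gi = (a * a) / c if c else 0.0
    return gi, a, c


# ---------------------------------------------------------------------------
# SCNA events


def build_events(
    profile: SegmentedProfile, genome: GenomeModel, include_sex: bool = False
) -> list[AlterationEvent]:
    """Maximal same-status altered runs, split at centromeres into arm parts."""
    events: list[AlterationEvent] = []
    by_chrom = profile.by_chromosome()
    for chrom in _scoring_chromosomes(profile, genome, include_sex):
        cinfo = genome.get(chrom)
        runs: list[tuple[str, int, int]] = []
        for seg in by_chrom[chrom]:
            if seg.status not in ("gain", "loss"):
                continue
            if runs and runs[-1][0] == seg.status and runs[-1][2] == seg.start:
                runs[-1] = (seg.status, runs[-1][1], seg.end)
            else:
                runs.append((seg.status, seg.start, seg.end))
        for status, start, end in runs:
            parts = []
            if start < cinfo.centromere:
                parts.append(("p", start, min(end, cinfo.centromere)))
            if end > cinfo.centromere:
                parts.append(("q", max(start, cinfo.centromere), end))
            for arm, s, e in parts:
                frac = (e - s) / cinfo.arm_length(arm)
                events.append(AlterationEvent(chrom, status, s, e, arm, frac))
    return events


def classify_events(
    events: list[AlterationEvent],
    genome: GenomeModel,
    arm_coverage_min: float = 0.8,
) -> list[AlterationEvent]:
    """Set the focal/arm/chromosome level on each event.

    Focal: arm_fraction < 0.5. Among non-focal events, a chromosome's events
    are chromosome-level when both arms carry a non-focal event of the same
    status covering at least ``arm_coverage_min`` of the arm; all remaining
    non-focal events are arm-level.
    """
    # (chrom, status) -> set of arms with a high-coverage non-focal event
    covered: dict[tuple[str, str], set[str]] = {}
    for ev in events:
        if ev.arm_fraction >= 0.5 and ev.arm_fraction >= arm_coverage_min:
            covered.setdefault((ev.chrom, ev.status), set()).add(ev.arm)
    out = []
    for ev in events:
        if ev.arm_fraction < 0.5:
            level = "focal"
        elif covered.get((ev.chrom, ev.status), set()) >= {"p", "q"} and (
            ev.arm_fraction >= arm_coverage_min
        ):
            level = "chromosome"
        else:
            level = "arm"
        out.append(replace(ev, level=level))
    return out


def scna_scores(events: list[AlterationEvent]) -> dict[str, int]:
    """Count classified events per level and direction.

    Chromosome-level events count once per (chromosome, status) pair even
    though both arm parts carry the label.
    """
    counts = {k: 0 for k in ("focal_amp", "focal_del", "arm_amp", "arm_del", "chrom_amp", "chrom_del")}
    chrom_pairs: set[tuple[str, str]] = set()
    for ev in events:
        if ev.level is None:
            raise ValueError("events must be classified first")
        suffix = "amp" if ev.status == "gain" else "del"
        if ev.level == "focal":
            counts[f"focal_{suffix}"] += 1
        elif ev.level == "arm":
            counts[f"arm_{suffix}"] += 1
        else:
            chrom_pairs.add((ev.chrom, ev.status))
    for _, status in chrom_pairs:
        counts["chrom_amp" if status == "gain" else "chrom_del"] += 1
    return counts


# ---------------------------------------------------------------------------
# LGA pipeline


@dataclass(frozen=True)
class _ArmSeg:
    start: int
    end: int
    mean: float
    n_probes: int

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / MB


def split_at_centromeres(
    profile: SegmentedProfile, genome: GenomeModel, include_sex: bool = False
) -> dict[tuple[str, str], list[_ArmSeg]]:
    """Per-arm segment lists, with centromere-spanning segments split."""
    arms: dict[tuple[str, str], list[_ArmSeg]] = {}
    by_chrom = profile.by_chromosome()
    for chrom in _scoring_chromosomes(profile, genome, include_sex):
        cen = genome.get(chrom).centromere
        for seg in by_chrom[chrom]:
            pieces = []
            if seg.start < cen:
                pieces.append(("p", seg.start, min(seg.end, cen)))
            if seg.end > cen:
                pieces.append(("q", max(seg.start, cen), seg.end))
            for arm, s, e in pieces:
                frac = (e - s) / seg.length
                arms.setdefault((chrom, arm), []).append(
                    _ArmSeg(s, e, seg.mean_log2, int(round(seg.n_probes * frac)))
                )
    return arms


def _arm_pairs_deltas(arms: dict, large_mb: float) -> list[float]:
    deltas = []
    for segs in arms.values():
        for a, b in zip(segs, segs[1:]):
            if a.length_mb >= large_mb and b.length_mb >= large_mb:
                deltas.append(abs(b.mean - a.mean))
    return deltas


def estimate_one_copy_cutoff(
    profile: SegmentedProfile, genome: GenomeModel, cfg: LgaConfig | None = None
) -> float:
    """Per-profile log-ratio cutoff representing a one-copy difference.

    The candidate steps are |Δ mean_log2| over adjacent pairs of large
    (>= ``large_segment_mb``) same-arm segments, restricted to
    [cutoff_floor, cutoff_ceiling]. The modal histogram bin (width
    ``cutoff_bin_width``) locates the one-copy step; the returned cutoff is
    ``cutoff_margin`` times the median of steps within one bin width of the
    modal-bin center, so steps at the mode itself always qualify downstream.
    Falls back to ``cutoff_fallback`` when fewer than ``cutoff_min_pairs``
    in-range pairs exist.
    """
    cfg = cfg or LgaConfig()
    arms = split_at_centromeres(profile, genome)
    deltas = np.array(_arm_pairs_deltas(arms, cfg.large_segment_mb))
    deltas = deltas[(deltas >= cfg.cutoff_floor) & (deltas <= cfg.cutoff_ceiling)]
    if deltas.size < cfg.cutoff_min_pairs:
        return cfg.cutoff_fallback
    nbins = int(np.ceil((cfg.cutoff_ceiling - cfg.cutoff_floor) / cfg.cutoff_bin_width))
    counts, edges = np.histogram(
        deltas, bins=nbins, range=(cfg.cutoff_floor, cfg.cutoff_ceiling)
    )
    k = int(np.argmax(counts))
    center = 0.5 * (edges[k] + edges[k + 1])
    window = deltas[np.abs(deltas - center) <= cfg.cutoff_bin_width]
    mode = float(np.median(window)) if window.size else center
    return cfg.cutoff_margin * mode


def _merge(a: _ArmSeg, b: _ArmSeg) -> _ArmSeg:
    la, lb = a.end - a.start, b.end - b.start
    mean = (a.mean * la + b.mean * lb) / (la + lb)
    return _ArmSeg(a.start, b.end, mean, a.n_probes + b.n_probes)


def _smooth_arm(segs: list[_ArmSeg], cutoff: float, min_mb: float) -> list[_ArmSeg]:
    segs = list(segs)
    while True:
        best_i, best_d = None, None
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if a.length_mb >= min_mb and b.length_mb >= min_mb:
                d = abs(b.mean - a.mean)
                if d < cutoff and (best_d is None or d < best_d):
                    best_i, best_d = i, d
        if best_i is None:
            return segs
        segs[best_i : best_i + 2] = [_merge(segs[best_i], segs[best_i + 1])]


def _integrate_arm(segs: list[_ArmSeg], cutoff: float, cfg: LgaConfig) -> list[_ArmSeg]:
    """Joint fixpoint of three merge rules, applied in priority order:
    step-wise smoothing, interstitial filtering (a sub-large segment between
    two large segments whose means differ by < cutoff is absorbed into both),
    and small-segment integration (a sub-small segment joins the neighbour
    with the closer mean; ties and boundaries resolve leftward/inward).
    One merge per iteration keeps the procedure order-deterministic."""
    segs = list(segs)
    while True:
        smoothed = _smooth_arm(segs, cutoff, cfg.smoothing_segment_mb)
        if len(smoothed) != len(segs):
            segs = smoothed
            continue
        merged = False
        for i in range(1, len(segs) - 1):
            mid, left, right = segs[i], segs[i - 1], segs[i + 1]
            if (
                mid.length_mb < cfg.large_segment_mb
                and left.length_mb >= cfg.large_segment_mb
                and right.length_mb >= cfg.large_segment_mb
                and abs(right.mean - left.mean) < cutoff
            ):
                segs[i - 1 : i + 2] = [_merge(_merge(left, mid), right)]
                merged = True
                break
        if merged:
            continue
        for i in range(len(segs)):
            if segs[i].length_mb < cfg.small_segment_mb and len(segs) > 1:
                if i == 0:
                    segs[0:2] = [_merge(segs[0], segs[1])]
                elif i == len(segs) - 1:
                    segs[i - 1 : i + 1] = [_merge(segs[i - 1], segs[i])]
                else:
                    dl = abs(segs[i].mean - segs[i - 1].mean)
                    dr = abs(segs[i].mean - segs[i + 1].mean)
                    if dl <= dr:
                        segs[i - 1 : i + 1] = [_merge(segs[i - 1], segs[i])]
                    else:
                        segs[i : i + 2] = [_merge(segs[i], segs[i + 1])]
                merged = True
                break
        if not merged:
            return segs


def _arms_to_profile(
    sample_id: str, genome: GenomeModel, arms: dict[tuple[str, str], list[_ArmSeg]]
) -> SegmentedProfile:
    segs: list[Segment] = []
    for chrom in genome.names:
        for arm in ("p", "q"):
            for s in arms.get((chrom, arm), []):
                segs.append(Segment(chrom, s.start, s.end, s.mean, "normal", s.n_probes))
    return SegmentedProfile(sample_id, tuple(segs))


def smooth_profile(
    profile: SegmentedProfile,
    cutoff: float,
    genome: GenomeModel,
    cfg: LgaConfig | None = None,
) -> SegmentedProfile:
    """Step-wise smoothing: repeatedly merge the adjacent same-arm pair of
    segments (each >= ``smoothing_segment_mb``) with the smallest |Δ| among
    pairs with |Δ| < cutoff, replacing them by their length-weighted mean."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    cfg = cfg or LgaConfig()
    arms = split_at_centromeres(profile, genome)
    arms = {k: _smooth_arm(v, cutoff, cfg.smoothing_segment_mb) for k, v in arms.items()}
    return _arms_to_profile(profile.sample_id, genome, arms)


def integrate_small_segments(
    profile: SegmentedProfile,
    cutoff: float,
    genome: GenomeModel,
    cfg: LgaConfig | None = None,
) -> SegmentedProfile:
    """Absorb small segments and filter small interstitial CNAs (see module doc)."""
    cfg = cfg or LgaConfig()
    arms = split_at_centromeres(profile, genome)
    arms = {k: _integrate_arm(v, cutoff, cfg) for k, v in arms.items()}
    return _arms_to_profile(profile.sample_id, genome, arms)


def count_lga(
    profile: SegmentedProfile,
    cutoff: float,
    genome: GenomeModel,
    cfg: LgaConfig | None = None,
) -> int:
    """Count breaks between adjacent large same-arm segments on the final
    (smoothed + integrated) segmentation. A break qualifies when both flanks
    are >= ``large_segment_mb``, the gap between them is <= ``max_gap_mb``
    (always 0 on tiling profiles) and |Δ mean| >= cutoff. Breaks across
    centromeres are never counted."""
    cfg = cfg or LgaConfig()
    arms = split_at_centromeres(profile, genome)
    n = 0
    for segs in arms.values():
        for a, b in zip(segs, segs[1:]):
            if (
                a.length_mb >= cfg.large_segment_mb
                and b.length_mb >= cfg.large_segment_mb
                and (b.start - a.end) / MB <= cfg.max_gap_mb
                and abs(b.mean - a.mean) >= cutoff
            ):
                n += 1
    return n


def call_hrd(lga_count: int, cfg: LgaConfig | None = None) -> str:
    """HRD when the LGA count reaches the threshold (inclusive), else HRP."""
    cfg = cfg or LgaConfig()
    if lga_count < 0:
        raise ValueError("lga_count must be >= 0")
    return "HRD" if lga_count >= cfg.hrd_threshold else "HRP"


# ---------------------------------------------------------------------------
# orchestration


def score_profile(
    profile: SegmentedProfile,
    genome: GenomeModel,
    cfg: LgaConfig | None = None,
    arm_coverage_min: float = 0.8,
    include_sex: bool = False,
) -> InstabilityScores:
    """Run all instability scores on one status-called profile."""
    cfg = cfg or LgaConfig()
    gi, a, c = genomic_index(profile, genome, include_sex=include_sex)
    events = classify_events(
        build_events(profile, genome, include_sex=include_sex), genome, arm_coverage_min
    )
    counts = scna_scores(events)
    cutoff = estimate_one_copy_cutoff(profile, genome, cfg)
    smoothed = smooth_profile(profile, cutoff, genome, cfg)
    integrated = integrate_small_segments(smoothed, cutoff, genome, cfg)
    lga = count_lga(integrated, cutoff, genome, cfg)
    return InstabilityScores(
        sample_id=profile.sample_id,
        genomic_index=gi,
        n_alterations=a,
        n_chromosomes_altered=c,
        lga_count=lga,
        one_copy_cutoff=cutoff,
        hrd_call=call_hrd(lga, cfg),
        **counts,
    )


def score_cohort(
    profiles: list[SegmentedProfile],
    genome: GenomeModel,
    cfg: LgaConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Score every profile; one row per sample."""
    rows = [score_profile(p, genome, cfg, **kwargs).to_dict() for p in profiles]
    return pd.DataFrame(rows)
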