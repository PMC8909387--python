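"""Synthetic cohort generation.

Builds cohorts with the statistical structure the analysis pipeline assumes:
piecewise-constant copy-number profiles with controlled LGA counts and
focal/arm/chromosome events, Gaussian probe noise on top, HRD-conditioned
immunohistochemistry markers, and proportional-hazards survival times with
administrative plus random censoring.

Construction conventions
------------------------
Requested focal/arm/chromosome events are placed as *gains* (one full-arm
segment for arm events, one whole-chromosome segment for chromosome events,
sub-large interstitial segments for focal events), so the scored
``focal_amp``/``arm_amp``/``chrom_amp`` equal the requested counts exactly.
LGA breaks are realized as alternating one-copy *losses* (levels 0 / -step)
between large (>= 10 Mb) flanking segments within dedicated arms; each loss
segment spans < 50% of its arm, so LGA carriers additionally contribute a
deterministic number of focal deletions. :class:`ProfileTruth` carries the
complete expected scores, bookkept at construction time independently of the
scoring code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import MB, GenomeModel, ProbeSeries, Segment, SegmentedProfile, default_genome

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "ProfileTruth",
    "CohortResult",
    "simulate_profile",
    "render_probes",
    "simulate_markers",
    "simulate_survival",
    "simulate_cohort",
    "lga_capacity",
    "patients_frame",
    "DEFAULT_MARKER_SPEC",
    "DEFAULT_SURVIVAL_SPEC",
]


class CapacityError(ValueError):
    """The genome cannot host the requested number of events."""


# Marker conditional distributions given HRD status. HLA-E high-rate defaults
# follow the printed 89%/44% split; other markers default to no HRD effect.
DEFAULT_MARKER_SPEC: dict[str, dict] = {
    "hla_e": {"scale": "semiquant_0_3", "p_high_hrd": 0.89, "p_high_hrp": 0.44},
    "cd3_tumor": {"scale": "semiquant_0_3", "p_high_hrd": 0.5, "p_high_hrp": 0.5},
    "icos": {"scale": "binary", "p_high_hrd": 0.5, "p_high_hrp": 0.5},
    "foxp3": {"scale": "count", "mean_hrd": 12.0, "mean_hrp": 12.0},
    "mxa": {"scale": "hscore", "mean_hrd": 160.0, "mean_hrp": 110.0, "sd": 50.0},
}

DEFAULT_SURVIVAL_SPEC: dict[str, dict] = {
    "pfs": {
        "dist": "exponential",
        "rate": 1.0 / 24.0,
        "coefs": {"cd3_tumor_high": math.log(0.52)},
        "admin_censor_time": 60.0,
        "random_censor_rate": 0.005,
    },
    "os": {
        "dist": "exponential",
        "rate": 1.0 / 60.0,
        "coefs": {"true_hrd": math.log(0.5)},
        "admin_censor_time": 84.0,
        "random_censor_rate": 0.005,
    },
}


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 103
    hrd_prevalence: float = 0.5
    lga_mean_hrd: float = 25.0
    lga_mean_hrp: float = 8.0
    focal_rate: float = 3.0
    arm_rate: float = 1.5
    chrom_rate: float = 1.0
    step_log2: float = 0.6
    probe_spacing: int = 1_000_000
    noise_sd: float = 0.0
    render: bool = False
    marker_spec: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_SPEC))
    survival_spec: dict = field(default_factory=lambda: dict(DEFAULT_SURVIVAL_SPEC))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0 <= self.hrd_prevalence <= 1):
            raise ValueError("hrd_prevalence must be a probability")
        for name in ("lga_mean_hrd", "lga_mean_hrp", "focal_rate", "arm_rate", "chrom_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    true_hrd: bool
    true_lga: int
    markers: dict[str, float]
    pfs_time: float
    pfs_event: bool
    os_time: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.pfs_time <= 0 or self.os_time <= 0:
            raise ValueError(f"{self.patient_id}: survival times must be > 0")


@dataclass(frozen=True)
class ProfileTruth:
    """Ground-truth expected scores of a constructed profile."""

    lga: int
    focal_amp: int
    focal_del: int
    arm_amp: int
    arm_del: int
    chrom_amp: int
    chrom_del: int
    n_alterations: int  # expected A of the genomic index
    n_chromosomes_altered: int  # expected C

    @property
    def genomic_index(self) -> float:
        if self.n_chromosomes_altered == 0:
            return 0.0
        return self.n_alterations**2 / self.n_chromosomes_altered


@dataclass(frozen=True)
class CohortResult:
    records: list[PatientRecord]
    profiles: list[SegmentedProfile]
    truths: list[ProfileTruth]
    probes: dict[str, ProbeSeries] | None


def _status_for(mean: float, gain_thr: float, loss_thr: float) -> str:
    if mean >= gain_thr:
        return "gain"
    if mean <= loss_thr:
        return "loss"
    return "normal"


def _arm_capacity(length_mb: float, large_mb: float) -> int:
    """Maximum LGA breaks an arm can host with all flanks >= large_mb and
    every altered segment spanning < 50% of the arm."""
    k = int(length_mb // large_mb) - 1
    if k == 1 and length_mb <= 2 * large_mb:
        return 0
    return max(k, 0)


def lga_capacity(genome: GenomeModel, large_mb: float = 10.0) -> int:
    """Total LGA breaks placeable on the autosomes of a genome."""
    return sum(
        _arm_capacity((e - s) / MB, large_mb) for _, _, s, e in genome.arms(autosomes_only=True)
    )


def _lga_arm_layout(length: int, k: int, large_mb: float) -> list[tuple[float, bool]]:
    """Segment (length_bp, is_loss) layout realizing k breaks within one arm."""
    if k == 0:
        return [(length, False)]
    if k == 1:
        s1 = max(large_mb * MB, 0.45 * length)
        if not (large_mb * MB <= s1 < 0.5 * length):
            s1 = large_mb * MB
        sizes = [length - s1, s1]
    else:
        base = length / (k + 1)
        sizes = [base] * (k + 1)
    return [(sz, i % 2 == 1) for i, sz in enumerate(sizes)]


def simulate_profile(
    target_lga: int,
    n_focal: int,
    n_arm: int,
    n_chrom: int,
    genome: GenomeModel,
    step_log2: float = 0.6,
    rng: np.random.Generator | None = None,
    large_mb: float = 10.0,
    focal_size_mb: float = 8.0,
    gain_threshold: float = 0.2,
    loss_threshold: float = -0.2,
    sample_id: str = "sim",
) -> tuple[SegmentedProfile, ProfileTruth]:
    """Construct a noise-free profile with an exact LGA count and exact
    amplification-event counts (see module docstring for the conventions).

    Raises :class:`CapacityError` when the genome cannot host the request —
    never silently places fewer events.
    """
    if min(target_lga, n_focal, n_arm, n_chrom) < 0:
        raise ValueError("event counts must be >= 0")
    if step_log2 <= 0:
        raise ValueError("step_log2 must be > 0")
    rng = rng or np.random.default_rng(0)
    autosomes = genome.autosomes()
    order = list(rng.permutation(len(autosomes)))
    chroms = [autosomes[i] for i in order]

    if n_chrom + n_arm > len(chroms):
        raise CapacityError(
            f"need {n_chrom + n_arm} chromosomes for arm/chromosome events, "
            f"have {len(chroms)} autosomes"
        )
    chrom_event_chroms = chroms[:n_chrom]
    arm_event_chroms = chroms[n_chrom : n_chrom + n_arm]
    free_chroms = chroms[n_chrom + n_arm :]

    # LGA carriers: arms of the remaining chromosomes, largest capacity first
    lga_arms: list[tuple[str, int, int, int]] = []  # (chrom, start, end, k)
    remaining = target_lga
    arm_pool = []
    for c in free_chroms:
        arm_pool.append((c.name, 0, c.centromere))
        arm_pool.append((c.name, c.centromere, c.length))
    arm_pool.sort(key=lambda a: -(a[2] - a[1]))
    for chrom, s, e in arm_pool:
        if remaining == 0:
            break
        cap = _arm_capacity((e - s) / MB, large_mb)
        k = min(cap, remaining)
        if k > 0:
            lga_arms.append((chrom, s, e, k))
            remaining -= k
    if remaining > 0:
        raise CapacityError(
            f"genome capacity exceeded: {remaining} of {target_lga} LGA breaks "
            "cannot be placed with the required flank sizes"
        )

    # focal hosts: free arms without LGA plus the unused arm of arm-event chromosomes
    used = {(c, s) for c, s, _, _ in lga_arms}
    focal_pool: list[tuple[str, int, int]] = []
    for c in free_chroms:
        for s, e in ((0, c.centromere), (c.centromere, c.length)):
            if (c.name, s) not in used:
                focal_pool.append((c.name, s, e))
    for c in arm_event_chroms:
        # arm events occupy the longer arm; the other arm can host focal events
        if c.centromere >= c.length - c.centromere:
            focal_pool.append((c.name, c.centromere, c.length))
        else:
            focal_pool.append((c.name, 0, c.centromere))
    focal_sites: list[tuple[str, int, int]] = []
    need = n_focal
    for chrom, s, e in focal_pool:
        if need == 0:
            break
        arm_len = e - s
        size = min(focal_size_mb * MB, 0.45 * arm_len, (large_mb - 1.0) * MB)
        if size <= 0:
            continue
        slot = 3.0 * size
        m = min(int(arm_len // slot), need)
        for i in range(m):
            mid = s + (i + 0.5) * (arm_len / max(int(arm_len // slot), 1))
            focal_sites.append((chrom, int(mid - size / 2), int(mid + size / 2)))
        need -= m
    if need > 0:
        raise CapacityError(f"cannot place {need} of {n_focal} focal events")

    step = step_log2
    # assemble intervals per chromosome: (start, end, level)
    intervals: dict[str, list[tuple[int, int, float]]] = {c.name: [] for c in autosomes}
    for c in chrom_event_chroms:
        intervals[c.name].append((0, c.length, step))
    for c in arm_event_chroms:
        if c.centromere >= c.length - c.centromere:
            intervals[c.name].append((0, c.centromere, step))
        else:
            intervals[c.name].append((c.centromere, c.length, step))
    induced_focal_del = 0
    lga_chroms = set()
    for chrom, s, e, k in lga_arms:
        pos = float(s)
        for size, is_loss in _lga_arm_layout(e - s, k, large_mb):
            nxt = min(pos + size, e)
            intervals[chrom].append((int(round(pos)), int(round(nxt)), -step if is_loss else 0.0))
            if is_loss:
                induced_focal_del += 1
            pos = nxt
        # make the last interval end exactly at the arm end
        last = intervals[chrom][-1]
        intervals[chrom][-1] = (last[0], e, last[2])
        lga_chroms.add(chrom)
    for chrom, s, e in focal_sites:
        intervals[chrom].append((s, e, step))

    segments: list[Segment] = []
    for c in autosomes:
        ivs = sorted(intervals[c.name])
        cursor = 0
        for s, e, level in ivs:
            if s < cursor:
                raise RuntimeError("internal: overlapping simulated intervals")
            if s > cursor:
                segments.append(_mk_segment(c.name, cursor, s, 0.0, gain_threshold, loss_threshold))
            segments.append(_mk_segment(c.name, s, e, level, gain_threshold, loss_threshold))
            cursor = e
        if cursor < c.length:
            segments.append(
                _mk_segment(c.name, cursor, c.length, 0.0, gain_threshold, loss_threshold)
            )

    altered_chroms = (
        {c.name for c in chrom_event_chroms}
        | {c.name for c in arm_event_chroms}
        | {c for c, _, _ in focal_sites}
        | lga_chroms
    )
    truth = ProfileTruth(
        lga=target_lga,
        focal_amp=n_focal,
        focal_del=induced_focal_del,
        arm_amp=n_arm,
        arm_del=0,
        chrom_amp=n_chrom,
        chrom_del=0,
        n_alterations=n_focal + n_arm + n_chrom + induced_focal_del,
        n_chromosomes_altered=len(altered_chroms),
    )
    return SegmentedProfile(sample_id, tuple(segments)), truth


def _mk_segment(chrom, start, end, level, gain_thr, loss_thr) -> Segment:
    return Segment(chrom, int(start), int(end), level, _status_for(level, gain_thr, loss_thr), 0)


def render_probes(
    profile: SegmentedProfile,
    probe_spacing: int,
    noise_sd: float,
    rng: np.random.Generator | None = None,
) -> ProbeSeries:
    """Regularly spaced probes whose log2 ratio is the segment mean plus
    Gaussian noise."""
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = rng or np.random.default_rng(0)
    chroms, poss, vals = [], [], []
    for chrom, segs in profile.by_chromosome().items():
        ends = np.array([s.end for s in segs])
        means = np.array([s.mean_log2 for s in segs])
        pos = np.arange(probe_spacing // 2, segs[-1].end, probe_spacing)
        idx = np.searchsorted(ends, pos, side="right")
        v = means[idx]
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.size)
        chroms.extend([chrom] * pos.size)
        poss.append(pos)
        vals.append(v)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.concatenate(poss) if poss else np.array([], int),
            "log2ratio": np.concatenate(vals) if vals else np.array([], float),
        }
    )
    return ProbeSeries(profile.sample_id, df)


def simulate_markers(
    true_hrd: bool, marker_spec: Mapping[str, Mapping] | None = None, rng=None
) -> dict[str, float]:
    """Draw marker values independently given HRD status."""
    spec = marker_spec if marker_spec is not None else DEFAULT_MARKER_SPEC
    rng = rng or np.random.default_rng(0)
    out: dict[str, float] = {}
    for marker, ms in spec.items():
        scale = ms.get("scale")
        if scale in ("binary", "semiquant_0_3"):
            p = ms["p_high_hrd"] if true_hrd else ms["p_high_hrp"]
            if not (0 <= p <= 1):
                raise ValueError(f"{marker}: probability {p} outside [0, 1]")
            high = rng.random() < p
            if scale == "binary":
                out[marker] = float(high)
            else:
                out[marker] = float(rng.integers(2, 4) if high else rng.integers(0, 2))
        elif scale == "count":
            mean = ms["mean_hrd"] if true_hrd else ms["mean_hrp"]
            out[marker] = float(rng.poisson(mean))
        elif scale in ("hscore", "percent"):
            mean = ms["mean_hrd"] if true_hrd else ms["mean_hrp"]
            hi = 300.0 if scale == "hscore" else 100.0
            out[marker] = float(np.clip(rng.normal(mean, ms.get("sd", 20.0)), 0.0, hi))
        else:
            raise ValueError(f"{marker}: unknown marker scale {scale!r}")
    return out


def simulate_survival(
    covariates: Mapping[str, float], spec: Mapping, rng: np.random.Generator | None = None
) -> tuple[float, bool]:
    """Proportional-hazards survival time by inversion, with administrative
    and exponential random censoring. Returns (observed time, event flag)."""
    rng = rng or np.random.default_rng(0)
    coefs = spec.get("coefs", {})
    missing = [k for k in coefs if k not in covariates]
    if missing:
        raise KeyError(f"survival spec references unknown covariates {missing}")
    lp = sum(beta * float(covariates[name]) for name, beta in coefs.items())
    dist = spec.get("dist", "exponential")
    if dist == "exponential":
        rate = float(spec["rate"])
        if rate <= 0:
            raise ValueError("exponential rate must be > 0")
        t_event = rng.exponential(1.0 / (rate * math.exp(lp)))
    elif dist == "weibull":
        shape, scale = float(spec["shape"]), float(spec["scale"])
        if shape <= 0 or scale <= 0:
            raise ValueError("weibull shape/scale must be > 0")
        t_event = scale * (rng.exponential(1.0) * math.exp(-lp)) ** (1.0 / shape)
    else:
        raise ValueError(f"unknown baseline hazard {dist!r}")
    admin = float(spec.get("admin_censor_time", np.inf))
    if admin <= 0:
        raise ValueError("admin_censor_time must be > 0")
    censor = admin
    cr = float(spec.get("random_censor_rate", 0.0))
    if cr > 0:
        censor = min(censor, rng.exponential(1.0 / cr))
    return (min(t_event, censor), bool(t_event <= censor))


def _covariates_for(true_hrd: bool, markers: Mapping[str, float], spec: Mapping[str, Mapping]) -> dict:
    cov = {"true_hrd": float(true_hrd)}
    for marker, ms in spec.items():
        v = markers[marker]
        scale = ms.get("scale")
        if scale == "binary":
            cov[f"{marker}_high"] = v
        elif scale == "semiquant_0_3":
            cov[f"{marker}_high"] = float(v >= 2)
        elif scale == "count":
            cov[marker] = v
        else:
            cov[marker] = v / 100.0
    return cov


def simulate_cohort(config: CohortConfig, genome: GenomeModel | None = None) -> CohortResult:
    """Simulate a full cohort: profiles, markers and survival endpoints.

    Reproducible under ``config.seed``. Per-patient LGA counts are Poisson
    with the group mean (HRD vs HRP), truncated at the genome's capacity.
    """
    genome = genome or default_genome()
    rng = np.random.default_rng(config.seed)
    cap = lga_capacity(genome)
    records: list[PatientRecord] = []
    profiles: list[SegmentedProfile] = []
    truths: list[ProfileTruth] = []
    probes: dict[str, ProbeSeries] = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        hrd = bool(rng.random() < config.hrd_prevalence)
        mean = config.lga_mean_hrd if hrd else config.lga_mean_hrp
        lga = int(min(rng.poisson(mean), cap))
        profile, truth = simulate_profile(
            target_lga=lga,
            n_focal=int(rng.poisson(config.focal_rate)),
            n_arm=int(rng.poisson(config.arm_rate)),
            n_chrom=int(rng.poisson(config.chrom_rate)),
            genome=genome,
            step_log2=config.step_log2,
            rng=rng,
            sample_id=pid,
        )
        markers = simulate_markers(hrd, config.marker_spec, rng)
        cov = _covariates_for(hrd, markers, config.marker_spec)
        pfs_time, pfs_event = simulate_survival(cov, config.survival_spec["pfs"], rng)
        os_time, os_event = simulate_survival(cov, config.survival_spec["os"], rng)
        records.append(
            PatientRecord(pid, hrd, lga, markers, pfs_time, pfs_event, os_time, os_event)
        )
        profiles.append(profile)
        truths.append(truth)
        if config.render:
            probes[pid] = render_probes(profile, config.probe_spacing, config.noise_sd, rng)
    return CohortResult(records, profiles, truths, probes if config.render else None)


def patients_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """One row per patient: id, truth, marker columns, endpoints."""
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "true_hrd": int(r.true_hrd), "true_lga": r.true_lga}
        row.update(r.markers)
        row.update(
            {
                "pfs_time": r.pfs_time,
                "pfs_event": int(r.pfs_event),
                "os_time": r.os_time,
                "os_event": int(r.os_event),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
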