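"""Probe-level log-ratio processing: centering, change-point segmentation,
status calling, and baseline recalibration.

Segmentation is recursive binary splitting on the two-sample t-statistic with
permutation acceptance at level ``alpha`` — a documented stand-in for CBS that
honours the same output contract (a tiling profile whose segment means are the
means of their probes). Users with pre-segmented data can skip this stage
entirely and feed SEG tables straight into the scoring layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .genome import GenomeModel, ProbeSeries, Segment, SegmentedProfile

__all__ = [
    "SegmentationConfig",
    "center_probes",
    "segment_probes",
    "call_status",
    "recalibrate_baseline",
    "status_for",
]


@dataclass(frozen=True)
class SegmentationConfig:
    alpha: float = 0.01
    min_probes_per_segment: int = 5
    gain_threshold: float = 0.2
    loss_threshold: float = -0.2
    baseline_offset: float = 0.0
    n_permutations: int = 199
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.loss_threshold < 0 < self.gain_threshold):
            raise ValueError("need loss_threshold < 0 < gain_threshold")
        if self.min_probes_per_segment < 2:
            raise ValueError("min_probes_per_segment must be >= 2")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


def center_probes(series: ProbeSeries) -> ProbeSeries:
    """Median-center the log2 ratios of a probe series."""
    if len(series) == 0:
        raise ValueError("cannot center an empty probe series")
    df = series.probes.copy()
    df["log2ratio"] = df["log2ratio"] - df["log2ratio"].median()
    return ProbeSeries(series.sample_id, df)


def status_for(mean_log2: float, cfg: SegmentationConfig) -> str:
    if mean_log2 >= cfg.gain_threshold:
        return "gain"
    if mean_log2 <= cfg.loss_threshold:
        return "loss"
    return "normal"


def _t_statistics(x: np.ndarray, min_probes: int) -> tuple[np.ndarray, np.ndarray]:
    """|t| of every candidate split of x, with candidate left-sizes.

    Returns (left_sizes, abs_t). Splits with zero pooled variance get |t| = inf
    when the means differ and 0 when they do not.
    """
    n = x.size
    ks = np.arange(min_probes, n - min_probes + 1)
    if ks.size == 0:
        return ks, np.empty(0)
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    tot, tot2 = cs[-1], css[-1]
    nl = ks.astype(float)
    nr = n - nl
    sl = cs[ks - 1]
    ml = sl / nl
    mr = (tot - sl) / nr
    ssl = css[ks - 1] - nl * ml**2
    ssr = (tot2 - css[ks - 1]) - nr * mr**2
    sp2 = (ssl + ssr) / max(n - 2, 1)
    sp2 = np.maximum(sp2, 0.0)
    denom = np.sqrt(sp2 * (1.0 / nl + 1.0 / nr))
    diff = np.abs(ml - mr)
    # cumsum rounding can leave diff ~1e-16 with an exactly-zero pooled
    # variance in constant regions; such splits must not look infinitely good
    tol = 1e-8 * max(1.0, float(np.max(np.abs(x))))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t = np.where(denom == 0, np.where(diff > tol, np.inf, 0.0), t)
    return ks, t


def _max_abs_t_rows(X: np.ndarray, min_probes: int) -> np.ndarray:
    """Row-wise max |t| over all candidate splits, vectorized over rows."""
    B, n = X.shape
    ks = np.arange(min_probes, n - min_probes + 1)
    if ks.size == 0:
        return np.zeros(B)
    cs = np.cumsum(X, axis=1)
    css = np.cumsum(X * X, axis=1)
    tot = cs[:, -1:]
    tot2 = css[:, -1:]
    nl = ks.astype(float)[None, :]
    nr = n - nl
    sl = cs[:, ks - 1]
    ml = sl / nl
    mr = (tot - sl) / nr
    ssl = css[:, ks - 1] - nl * ml**2
    ssr = (tot2 - css[:, ks - 1]) - nr * mr**2
    sp2 = np.maximum((ssl + ssr) / max(n - 2, 1), 0.0)
    denom = np.sqrt(sp2 * (1.0 / nl + 1.0 / nr))
    diff = np.abs(ml - mr)
    tol = 1e-8 * max(1.0, float(np.max(np.abs(X))))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t = np.where(denom == 0, np.where(diff > tol, np.inf, 0.0), t)
    return np.max(t, axis=1)


def _segment_chromosome(
    values: np.ndarray, cfg: SegmentationConfig, chrom_key: int
) -> list[tuple[int, int]]:
    """Recursive binary segmentation; returns half-open probe-index intervals."""
    out: list[tuple[int, int]] = []

    def rec(i: int, j: int) -> None:
        x = values[i:j]
        ks, t = _t_statistics(x, cfg.min_probes_per_segment)
        if t.size == 0:
            out.append((i, j))
            return
        best = int(np.argmax(t))
        obs = t[best]
        if not np.isfinite(obs) and obs > 0:
            p = 1.0 / (cfg.n_permutations + 1)
        elif obs == 0:
            p = 1.0
        else:
            # per-node seed keyed by the interval so p-values do not depend on
            # alpha or on decisions taken elsewhere in the recursion
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, chrom_key, i, j])
            )
            perm = np.tile(x, (cfg.n_permutations, 1))
            perm = rng.permuted(perm, axis=1)
            perm_max = _max_abs_t_rows(perm, cfg.min_probes_per_segment)
            p = (1.0 + int(np.sum(perm_max >= obs))) / (cfg.n_permutations + 1.0)
        if p <= cfg.alpha:
            k = i + int(ks[best])
            rec(i, k)
            rec(k, j)
        else:
            out.append((i, j))

    rec(0, values.size)
    out.sort()
    return out


def segment_probes(
    series: ProbeSeries, genome: GenomeModel, cfg: SegmentationConfig | None = None
) -> SegmentedProfile:
    """Segment a probe series into a tiling profile, one chromosome at a time.

    Segment boundaries fall at midpoints between flanking probes and are
    extended to the chromosome ends. Chromosomes with fewer than
    ``min_probes_per_segment`` probes become a single segment (with a warning).
    Statuses are left 'normal'; apply :func:`call_status` afterwards.
    """
    cfg = cfg or SegmentationConfig()
    segments: list[Segment] = []
    for chrom in series.chromosomes():
        c = genome.get(chrom)
        pos, vals = series.values_for(chrom)
        if pos.size and pos[-1] >= c.length:
            raise ValueError(f"probe beyond end of {chrom}")
        if vals.size < cfg.min_probes_per_segment:
            warnings.warn(
                f"{series.sample_id}: {chrom} has {vals.size} probes "
                f"(< {cfg.min_probes_per_segment}); emitting a single segment",
                stacklevel=2,
            )
            intervals = [(0, vals.size)]
        else:
            intervals = _segment_chromosome(vals, cfg, genome.chrom_index(chrom))
        for idx, (i, j) in enumerate(intervals):
            start = 0 if i == 0 else int((pos[i - 1] + pos[i]) // 2)
            end = c.length if j == vals.size else int((pos[j - 1] + pos[j]) // 2)
            segments.append(
                Segment(chrom, start, end, float(np.mean(vals[i:j])), "normal", j - i)
            )
    return SegmentedProfile(series.sample_id, tuple(segments))


def call_status(profile: SegmentedProfile, cfg: SegmentationConfig | None = None) -> SegmentedProfile:
    """Assign gain/normal/loss to each segment from its mean log2 ratio."""
    cfg = cfg or SegmentationConfig()
    return SegmentedProfile(
        profile.sample_id,
        tuple(replace(s, status=status_for(s.mean_log2, cfg)) for s in profile.segments),
    )


def recalibrate_baseline(
    profile: SegmentedProfile, offset: float, cfg: SegmentationConfig | None = None
) -> SegmentedProfile:
    """Shift all segment means by ``-offset`` and recompute statuses.

    This replaces an interactive baseline-correction step: a reviewer who
    judges the diploid level to sit at ``offset`` (instead of 0) applies it
    here and statuses are re-derived from the corrected means.
    """
    cfg = cfg or SegmentationConfig()
    shifted = SegmentedProfile(
        profile.sample_id,
        tuple(replace(s, mean_log2=s.mean_log2 - offset) for s in profile.segments),
    )
    return call_status(shifted, cfg)
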