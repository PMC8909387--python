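"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (plain loops over tables, exhaustive
enumeration) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

MB = 1_000_000


# ---------------------------------------------------------------------------
# genomic index: naive recount of maximal altered runs from a segment table


def naive_genomic_index(rows, sex_names=("chrX", "chrY", "X", "Y")):
    """rows: iterable of (chrom, start, end, status) sorted by position."""
    a = 0
    chroms = set()
    prev_chrom, prev_status = None, None
    for chrom, start, end, status in rows:
        if chrom in sex_names:
            prev_chrom, prev_status = chrom, None
            continue
        if status in ("gain", "loss") and not (
            chrom == prev_chrom and status == prev_status
        ):
            a += 1
            chroms.add(chrom)
        prev_chrom, prev_status = chrom, status
    c = len(chroms)
    return (a * a / c if c else 0.0), a, c


# ---------------------------------------------------------------------------
# SCNA classification: naive run-merging + level assignment


def naive_scna(rows, genome_table, arm_coverage_min=0.8):
    """rows: (chrom, start, end, status); genome_table: chrom -> (length, centromere).

    Returns the six counts (focal_amp, focal_del, arm_amp, arm_del,
    chrom_amp, chrom_del) recomputed from scratch.
    """
    runs = []
    cur = None
    for chrom, start, end, status in rows:
        if status not in ("gain", "loss"):
            cur = None
            continue
        if cur and cur[0] == chrom and cur[3] == status and cur[2] == start:
            cur = (chrom, cur[1], end, status)
            runs[-1] = cur
        else:
            cur = (chrom, start, end, status)
            runs.append(cur)
    # split at centromere into per-arm pieces
    pieces = []
    for chrom, start, end, status in runs:
        length, cen = genome_table[chrom]
        if start < cen:
            pieces.append((chrom, "p", start, min(end, cen), status))
        if end > cen:
            pieces.append((chrom, "q", max(start, cen), end, status))
    fractions = {}
    for chrom, arm, s, e, status in pieces:
        length, cen = genome_table[chrom]
        arm_len = cen if arm == "p" else length - cen
        fractions[(chrom, arm, s, e, status)] = (e - s) / arm_len
    counts = dict.fromkeys(
        ["focal_amp", "focal_del", "arm_amp", "arm_del", "chrom_amp", "chrom_del"], 0
    )
    chrom_level = set()
    for key, frac in fractions.items():
        chrom, arm, s, e, status = key
        if frac < 0.5:
            counts["focal_amp" if status == "gain" else "focal_del"] += 1
            continue
        other = "q" if arm == "p" else "p"
        other_covered = any(
            k[0] == chrom and k[1] == other and k[4] == status and f >= arm_coverage_min
            for k, f in fractions.items()
        )
        if frac >= arm_coverage_min and other_covered:
            chrom_level.add((chrom, status))
        else:
            counts["arm_amp" if status == "gain" else "arm_del"] += 1
    for chrom, status in chrom_level:
        counts["chrom_amp" if status == "gain" else "chrom_del"] += 1
    return counts


# ---------------------------------------------------------------------------
# LGA: naive pair scan on a final (already filtered) segmentation


def naive_count_lga(rows, genome_table, cutoff, large_mb=10.0, max_gap_mb=3.0):
    """rows: (chrom, start, end, mean) of the final segmentation."""
    per_arm = {}
    for chrom, start, end, mean in rows:
        length, cen = genome_table[chrom]
        parts = []
        if start < cen:
            parts.append((chrom, "p", start, min(end, cen), mean))
        if end > cen:
            parts.append((chrom, "q", max(start, cen), end, mean))
        for p in parts:
            per_arm.setdefault((p[0], p[1]), []).append(p[2:])
    n = 0
    for segs in per_arm.values():
        segs = sorted(segs)
        for (s1, e1, m1), (s2, e2, m2) in zip(segs, segs[1:]):
            large = (e1 - s1) >= large_mb * MB and (e2 - s2) >= large_mb * MB
            if large and (s2 - e1) <= max_gap_mb * MB and abs(m2 - m1) >= cutoff:
                n += 1
    return n


def naive_interstitial_filter(segs, cutoff, large_mb=10.0, small_mb=3.0, smooth_mb=3.0):
    """One-arm version of the small-segment integration, recomputed naively.

    segs: list of (length_mb, mean). Returns the filtered list. Rule priority
    per iteration: step-wise smoothing merge (smallest sub-cutoff shift among
    pairs of >= smooth_mb segments), interstitial absorption, small-segment
    integration.
    """
    segs = [list(s) for s in segs]
    changed = True
    while changed:
        changed = False
        # smoothing: merge the smallest sub-cutoff shift first
        while True:
            best, best_d = None, None
            for i in range(len(segs) - 1):
                if segs[i][0] >= smooth_mb and segs[i + 1][0] >= smooth_mb:
                    d = abs(segs[i + 1][1] - segs[i][1])
                    if d < cutoff and (best_d is None or d < best_d):
                        best, best_d = i, d
            if best is None:
                break
            total = segs[best][0] + segs[best + 1][0]
            mean = (segs[best][0] * segs[best][1] + segs[best + 1][0] * segs[best + 1][1]) / total
            segs[best : best + 2] = [[total, mean]]
            changed = True
        for i in range(1, len(segs) - 1):
            ln, mean = segs[i]
            if (
                ln < large_mb
                and segs[i - 1][0] >= large_mb
                and segs[i + 1][0] >= large_mb
                and abs(segs[i + 1][1] - segs[i - 1][1]) < cutoff
            ):
                total = segs[i - 1][0] + ln + segs[i + 1][0]
                mean = (
                    segs[i - 1][0] * segs[i - 1][1] + ln * mean + segs[i + 1][0] * segs[i + 1][1]
                ) / total
                segs[i - 1 : i + 2] = [[total, mean]]
                changed = True
                break
        if changed:
            continue
        for i, (ln, mean) in enumerate(segs):
            if ln < small_mb and len(segs) > 1:
                if i == 0:
                    j = 1
                elif i == len(segs) - 1:
                    j = i - 1
                else:
                    j = i - 1 if abs(mean - segs[i - 1][1]) <= abs(mean - segs[i + 1][1]) else i + 1
                lo, hi = min(i, j), max(i, j)
                total = segs[lo][0] + segs[hi][0]
                merged = [total, (segs[lo][0] * segs[lo][1] + segs[hi][0] * segs[hi][1]) / total]
                segs[lo : hi + 1] = [merged]
                changed = True
                break
    return [tuple(s) for s in segs]


# ---------------------------------------------------------------------------
# Fisher exact test by hypergeometric enumeration


def fisher_exact_enum(table):
    """Two-sided Fisher p for a 2x2 table by enumerating all tables with the
    same margins and summing probabilities <= that of the observed table."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# log-rank / maxstat oracles


def naive_logrank_chi2(time, event, group):
    """Textbook O-E/V log-rank chi-square computed with explicit loops."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    o = e = v = 0.0
    for tj in sorted(set(time[event])):
        at_risk = time >= tj
        nj = at_risk.sum()
        dj = (event & (time == tj)).sum()
        n1 = (at_risk & group).sum()
        d1 = (event & (time == tj) & group).sum()
        o += d1
        e += dj * n1 / nj
        if nj > 1:
            v += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
    if v == 0:
        return 0.0
    return (o - e) ** 2 / v


def exhaustive_maxstat(values, time, event, q_range=(0.1, 0.9)):
    """Best dichotomizing cutoff by scanning every candidate split."""
    values = np.asarray(values, float)
    distinct = np.unique(values)
    lo, hi = np.quantile(values, q_range[0]), np.quantile(values, q_range[1])
    mids = [(a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])]
    mids = [m for m in mids if lo <= m <= hi] or mids
    best_cut, best_z = None, -1.0
    for m in mids:
        chi2 = naive_logrank_chi2(time, event, values > m)
        z = math.sqrt(chi2)
        if z > best_z + 1e-12:
            best_cut, best_z = m, z
    return best_cut, best_z
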