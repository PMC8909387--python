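"""Genome coordinate model and tabular I/O for copy-number data.

Coordinates are 0-based half-open throughout. Chromosome arms are defined by a
single centromere breakpoint: p = [0, centromere), q = [centromere, length).
Sex chromosomes (named X/Y, chrX/chrY) are recognised so that scoring code can
exclude them by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Chromosome",
    "GenomeModel",
    "Segment",
    "SegmentedProfile",
    "ProbeSeries",
    "STATUSES",
    "arm_of",
    "read_genome_model",
    "write_genome_model",
    "read_segments",
    "write_segments",
    "read_probes",
    "write_probes",
    "toy_genome",
    "default_genome",
]

STATUSES = ("loss", "normal", "gain")

MB = 1_000_000

_SEX_NAMES = {"x", "y", "chrx", "chry"}

SEG_COLUMNS = ["sample", "chrom", "start", "end", "mean_log2", "status", "n_probes"]
PROBE_COLUMNS = ["sample", "chrom", "pos", "log2ratio"]


class GenomeValidationError(ValueError):
    """A genome model or profile violates a structural invariant."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GenomeValidationError(
                f"chromosome {self.name!r}: length must be > 0, got {self.length}"
            )
        if not (0 < self.centromere < self.length):
            raise GenomeValidationError(
                f"chromosome {self.name!r}: centromere must lie strictly inside "
                f"(0, {self.length}), got {self.centromere}"
            )

    @property
    def is_sex_chromosome(self) -> bool:
        return self.name.lower() in _SEX_NAMES

    def arm_bounds(self, arm: str) -> tuple[int, int]:
        if arm == "p":
            return 0, self.centromere
        if arm == "q":
            return self.centromere, self.length
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")

    def arm_length(self, arm: str) -> int:
        lo, hi = self.arm_bounds(arm)
        return hi - lo


@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GenomeValidationError(f"duplicate chromosome names: {sorted(dupes)}")
        object.__setattr__(self, "_by_name", {c.name: c for c in self.chromosomes})

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name  # type: ignore[attr-defined]

    def get(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]  # type: ignore[attr-defined]
        except KeyError:
            raise GenomeValidationError(f"unknown chromosome {name!r}") from None

    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if not c.is_sex_chromosome]

    def chrom_index(self, name: str) -> int:
        return self.names.index(name)

    def arms(self, autosomes_only: bool = False) -> list[tuple[str, str, int, int]]:
        """All (chrom, arm, start, end) tuples, in genome order."""
        chroms = self.autosomes() if autosomes_only else list(self.chromosomes)
        out = []
        for c in chroms:
            out.append((c.name, "p", 0, c.centromere))
            out.append((c.name, "q", c.centromere, c.length))
        return out


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    status: str = "normal"
    n_probes: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.status not in STATUSES:
            raise GenomeValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: bad status {self.status!r}"
            )
        if self.n_probes < 0:
            raise GenomeValidationError("n_probes must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return self.length / MB


@dataclass(frozen=True)
class SegmentedProfile:
    """Per-sample ordered copy-number segments.

    Within each chromosome segments must be sorted, non-overlapping and
    contiguous (each start equals the previous end). Use ``validate(genome)``
    to additionally check that each chromosome is tiled from 0 to its length.
    """

    sample_id: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        prev: dict[str, Segment] = {}
        seen_order: list[str] = []
        for seg in self.segments:
            if seg.chrom in prev:
                p = prev[seg.chrom]
                if seg.start < p.end:
                    raise GenomeValidationError(
                        f"{self.sample_id}: overlapping segments on {seg.chrom} "
                        f"({p.start}-{p.end} then {seg.start}-{seg.end})"
                    )
                if seg.start != p.end:
                    raise GenomeValidationError(
                        f"{self.sample_id}: gap on {seg.chrom} between {p.end} and {seg.start}"
                    )
            else:
                seen_order.append(seg.chrom)
            prev[seg.chrom] = seg
        # chromosome blocks must not interleave
        blocks = []
        for seg in self.segments:
            if not blocks or blocks[-1] != seg.chrom:
                blocks.append(seg.chrom)
        if len(blocks) != len(set(blocks)):
            raise GenomeValidationError(
                f"{self.sample_id}: segments of one chromosome must be stored in one block"
            )

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for seg in self.segments:
            if not out or out[-1] != seg.chrom:
                out.append(seg.chrom)
        return out

    def by_chromosome(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def validate(self, genome: GenomeModel) -> None:
        for chrom, segs in self.by_chromosome().items():
            c = genome.get(chrom)
            if segs[0].start != 0 or segs[-1].end != c.length:
                raise GenomeValidationError(
                    f"{self.sample_id}: {chrom} is not tiled "
                    f"([{segs[0].start}, {segs[-1].end}) vs [0, {c.length}))"
                )
            if segs[-1].end > c.length:
                raise GenomeValidationError(
                    f"{self.sample_id}: segment beyond end of {chrom}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "mean_log2": [s.mean_log2 for s in self.segments],
                "status": [s.status for s in self.segments],
                "n_probes": [s.n_probes for s in self.segments],
            }
        )


@dataclass(frozen=True)
class ProbeSeries:
    """Ordered probe-level log2 ratios for one sample."""

    sample_id: str
    probes: pd.DataFrame  # columns chrom, pos, log2ratio

    def __post_init__(self) -> None:
        df = self.probes
        missing = {"chrom", "pos", "log2ratio"} - set(df.columns)
        if missing:
            raise GenomeValidationError(f"probe table missing columns {sorted(missing)}")
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenomeValidationError(
                    f"{self.sample_id}: probes on {chrom} not strictly increasing"
                )

    def __len__(self) -> int:
        return len(self.probes)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.probes["chrom"]))

    def values_for(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        grp = self.probes[self.probes["chrom"] == chrom]
        return grp["pos"].to_numpy(), grp["log2ratio"].to_numpy(float)


def arm_of(segment: Segment, genome: GenomeModel) -> str:
    """Assign a segment to the p arm, q arm, or 'spanning' the centromere."""
    c = genome.get(segment.chrom)
    if segment.end > c.length:
        raise GenomeValidationError(
            f"segment {segment.chrom}:{segment.start}-{segment.end} beyond chromosome end"
        )
    if segment.end <= c.centromere:
        return "p"
    if segment.start >= c.centromere:
        return "q"
    return "spanning"


# ---------------------------------------------------------------------------
# genome model I/O


def read_genome_model(path: str | Path) -> GenomeModel:
    """Read a genome model from a YAML or JSON config.

    Expected shape::

        chromosomes:
          - {name: chr1, length_bp: 100000000, centromere_bp: 40000000}
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict) or "chromosomes" not in data:
        raise GenomeValidationError(f"{path}: expected a mapping with a 'chromosomes' list")
    chroms = []
    for entry in data["chromosomes"]:
        try:
            chroms.append(
                Chromosome(
                    name=str(entry["name"]),
                    length=int(entry["length_bp"]),
                    centromere=int(entry["centromere_bp"]),
                )
            )
        except KeyError as exc:
            raise GenomeValidationError(f"{path}: chromosome entry missing key {exc}") from None
    return GenomeModel(tuple(chroms))


def write_genome_model(genome: GenomeModel, path: str | Path) -> None:
    data = {
        "chromosomes": [
            {"name": c.name, "length_bp": c.length, "centromere_bp": c.centromere}
            for c in genome.chromosomes
        ]
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def toy_genome() -> GenomeModel:
    """Three-chromosome toy genome used in examples and small tests."""
    return GenomeModel(
        (
            Chromosome("chr1", 100 * MB, 40 * MB),
            Chromosome("chr2", 80 * MB, 30 * MB),
            Chromosome("chr3", 60 * MB, 25 * MB),
        )
    )


# Approximate human autosome lengths and centromere midpoints (Mb), reduced to
# a single breakpoint per chromosome. Convenience frame for simulations.
_DEFAULT_AUTOSOMES_MB = [
    ("chr1", 249.0, 123.4), ("chr2", 242.2, 93.9), ("chr3", 198.3, 90.9),
    ("chr4", 190.2, 50.0), ("chr5", 181.5, 48.8), ("chr6", 170.8, 59.8),
    ("chr7", 159.3, 60.1), ("chr8", 145.1, 45.2), ("chr9", 138.4, 43.0),
    ("chr10", 133.8, 39.8), ("chr11", 135.1, 53.4), ("chr12", 133.3, 35.5),
    ("chr13", 114.4, 17.7), ("chr14", 107.0, 17.2), ("chr15", 102.0, 19.0),
    ("chr16", 90.3, 36.8), ("chr17", 83.3, 25.1), ("chr18", 80.4, 18.5),
    ("chr19", 58.6, 26.2), ("chr20", 64.4, 28.1), ("chr21", 46.7, 12.0),
    ("chr22", 50.8, 15.0),
]


def default_genome() -> GenomeModel:
    """22-autosome genome with approximate lengths/centromeres."""
    return GenomeModel(
        tuple(
            Chromosome(name, int(length * MB), int(cen * MB))
            for name, length, cen in _DEFAULT_AUTOSOMES_MB
        )
    )


# ---------------------------------------------------------------------------
# segment and probe table I/O


def read_segments(
    path: str | Path,
    genome: GenomeModel,
    dialect: str = "zero_based",
    fill_gaps: bool = False,
) -> list[SegmentedProfile]:
    """Read a SEG-like TSV into per-sample profiles.

    Required columns: sample, chrom, start, end, mean_log2. Optional: status,
    n_probes. ``dialect='one_based'`` converts 1-based inclusive coordinates to
    the internal 0-based half-open convention. With ``fill_gaps=True``, gaps
    (including chromosome ends) are filled with zero-mean 'normal' segments so
    the tiling invariant holds; otherwise gaps are an error.
    """
    if dialect not in ("zero_based", "one_based"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "mean_log2"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeValidationError(f"{path}: missing columns {sorted(missing)}")
    if "status" not in df.columns:
        df["status"] = "normal"
    if "n_probes" not in df.columns:
        df["n_probes"] = 0

    starts = df["start"].to_numpy(np.int64)
    ends = df["end"].to_numpy(np.int64)
    if dialect == "one_based":
        starts = starts - 1
    bad = np.nonzero(ends <= starts)[0]
    if bad.size:
        raise GenomeValidationError(
            f"{path}: end <= start in rows {list(bad + 2)} (1-based incl. header)"
        )
    df = df.assign(start=starts, end=ends)

    unknown = sorted(set(df["chrom"]) - set(genome.names))
    if unknown:
        raise GenomeValidationError(f"{path}: unknown chromosomes {unknown}")

    profiles = []
    for sample, sdf in df.groupby("sample", sort=False):
        segments: list[Segment] = []
        for chrom in [c for c in genome.names if c in set(sdf["chrom"])]:
            cdf = sdf[sdf["chrom"] == chrom].sort_values("start")
            clen = genome.get(chrom).length
            rows = list(cdf.itertuples(index=False))
            overlaps = [
                (a, b)
                for a, b in zip(rows, rows[1:])
                if b.start < a.end
            ]
            if overlaps:
                desc = "; ".join(
                    f"{chrom}:{a.start}-{a.end} overlaps {chrom}:{b.start}-{b.end}"
                    for a, b in overlaps
                )
                raise GenomeValidationError(f"{path}: sample {sample!r}: {desc}")
            cursor = 0
            for r in rows:
                if r.end > clen:
                    raise GenomeValidationError(
                        f"{path}: sample {sample!r}: segment beyond end of {chrom}"
                    )
                if r.start > cursor:
                    if not fill_gaps:
                        raise GenomeValidationError(
                            f"{path}: sample {sample!r}: gap on {chrom} "
                            f"[{cursor}, {r.start}); pass fill_gaps=True to repair"
                        )
                    segments.append(Segment(chrom, cursor, int(r.start), 0.0, "normal", 0))
                segments.append(
                    Segment(
                        chrom,
                        int(r.start),
                        int(r.end),
                        float(r.mean_log2),
                        str(r.status),
                        int(r.n_probes),
                    )
                )
                cursor = int(r.end)
            if cursor < clen:
                if not fill_gaps:
                    raise GenomeValidationError(
                        f"{path}: sample {sample!r}: {chrom} not tiled to its end "
                        f"({cursor} < {clen}); pass fill_gaps=True to repair"
                    )
                segments.append(Segment(chrom, cursor, clen, 0.0, "normal", 0))
        profile = SegmentedProfile(str(sample), tuple(segments))
        profile.validate(genome)
        profiles.append(profile)
    return profiles


def write_segments(profiles: Iterable[SegmentedProfile], path: str | Path) -> None:
    frames = [p.to_frame() for p in profiles]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SEG_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probes(path: str | Path) -> list[ProbeSeries]:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise GenomeValidationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for sample, sdf in df.groupby("sample", sort=False):
        out.append(
            ProbeSeries(str(sample), sdf[["chrom", "pos", "log2ratio"]].reset_index(drop=True))
        )
    return out


def write_probes(series: Iterable[ProbeSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        df = s.probes.copy()
        df.insert(0, "sample", s.sample_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PROBE_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
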