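"""Candidate-region construction and signal binning.

Reads BED peak files and bedGraph signal tracks, builds labeled 4000 bp
regions from peak-overlap rules (STARR ∩ DNase, then ChIP support), and
aggregates per-base signal into fixed-width bins (10 bp by default, giving a
length-400 vector per 4000 bp region per signal).

Coordinates are 0-based half-open throughout (BED native).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

REGION_LENGTH = 4000
DEFAULT_BIN_SIZE = 10

SIGNAL_KINDS = ("STARR", "DNase", "H3K27ac", "H3K4me3", "H3K4me1", "H3K9ac")


class BedParseError(ValueError):
    """Raised when a BED/bedGraph line cannot be parsed or validated."""


@dataclass(frozen=True)
class GenomicRegion:
    """A labeled interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    label: str = "unknown"  # positive | negative | unknown

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.label not in ("positive", "negative", "unknown"):
            raise ValueError(f"invalid label {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    """Sorted collection of peaks from one assay."""

    peaks: list[tuple[str, int, int]]
    source_kind: str = "STARR"

    def __post_init__(self) -> None:
        for chrom, start, end in self.peaks:
            if end <= start:
                raise ValueError(f"peak end <= start: {chrom}:{start}-{end}")
        self.peaks = sorted(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Peaks grouped per chromosome as (n, 2) start/end arrays."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.peaks:
            out.setdefault(chrom, []).append((start, end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


@dataclass
class SignalTrack:
    """Interval-valued signal (bedGraph semantics): absent bases read as 0."""

    intervals: list[tuple[str, int, int, float]]
    signal_kind: str = "DNase"

    def __post_init__(self) -> None:
        for chrom, start, end, value in self.intervals:
            if end <= start:
                raise ValueError(f"interval end <= start: {chrom}:{start}-{end}")
            if not np.isfinite(value):
                raise ValueError(f"non-finite value at {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        out: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in self.intervals:
            out.setdefault(chrom, []).append((start, end, value))
        result = {}
        for chrom, rows in out.items():
            arr = np.asarray(rows, dtype=np.float64)
            result[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return result


@dataclass
class SignalMatrix:
    """Samples × (bins_per_region · n_signals) feature matrix with labels."""

    X: np.ndarray
    y: np.ndarray
    signal_kinds: list[str]
    region_index: list[GenomicRegion]
    bins_per_region: int = 400

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] % self.bins_per_region != 0:
            raise ValueError(
                f"column count {self.X.shape[1]} not divisible by "
                f"{self.bins_per_region}"
            )
        if self.X.shape[1] != self.bins_per_region * len(self.signal_kinds):
            raise ValueError("column count inconsistent with signal_kinds")
        if len(self.region_index) != self.X.shape[0]:
            raise ValueError("region_index does not align with rows")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y does not align with rows")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def block(self, signal_kind: str) -> np.ndarray:
        """Columns for one signal kind (view)."""
        try:
            i = self.signal_kinds.index(signal_kind)
        except ValueError:
            raise KeyError(f"signal kind {signal_kind!r} not in matrix") from None
        b = self.bins_per_region
        return self.X[:, i * b : (i + 1) * b]

    def save(self, prefix: str | Path) -> None:
        """Persist as <prefix>.tsv plus <prefix>.json sidecar."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".tsv"), self.X, delimiter="\t", fmt="%.6g")
        sidecar = {
            "signal_kinds": self.signal_kinds,
            "bins_per_region": self.bins_per_region,
            "y": self.y.tolist(),
            "regions": [
                [r.chrom, r.start, r.end, r.label] for r in self.region_index
            ],
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, prefix: str | Path) -> "SignalMatrix":
        prefix = Path(prefix)
        X = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        regions = [
            GenomicRegion(c, int(s), int(e), lab) for c, s, e, lab in meta["regions"]
        ]
        return cls(
            X=X,
            y=np.asarray(meta["y"]),
            signal_kinds=meta["signal_kinds"],
            region_index=regions,
            bins_per_region=meta["bins_per_region"],
        )


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, source_kind: str = "STARR") -> PeakSet:
    """Read a BED3+ file into a sorted, validated PeakSet."""
    peaks: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise BedParseError(
                    f"{path}: line {lineno}: end ({end}) <= start ({start})"
                )
            peaks.append((fields[0], start, end))
    return PeakSet(peaks=peaks, source_kind=source_kind)


def read_bedgraph(path: str | Path, signal_kind: str = "DNase") -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack."""
    intervals: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise BedParseError(f"{path}: line {lineno}: fewer than 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: bad fields") from exc
            if end <= start:
                raise BedParseError(
                    f"{path}: line {lineno}: end ({end}) <= start ({start})"
                )
            intervals.append((fields[0], start, end, value))
    return SignalTrack(intervals=intervals, signal_kind=signal_kind)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column <chrom> <size> text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}: line {lineno}: need 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# Interval operations
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge touching or overlapping sorted intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intersect_peaks(a: PeakSet, b: PeakSet) -> PeakSet:
    """Bases covered by at least one peak of `a` AND one of `b`.

    Pairwise intersection spans, with touching/overlapping outputs merged.
    """
    out: list[tuple[str, int, int]] = []
    a_by, b_by = a.by_chrom(), b.by_chrom()
    for chrom in sorted(set(a_by) & set(b_by)):
        pa, pb = a_by[chrom], b_by[chrom]
        hits: list[tuple[int, int]] = []
        i = j = 0
        while i < len(pa) and j < len(pb):
            lo = max(pa[i, 0], pb[j, 0])
            hi = min(pa[i, 1], pb[j, 1])
            if hi > lo:
                hits.append((int(lo), int(hi)))
            if pa[i, 1] <= pb[j, 1]:
                i += 1
            else:
                j += 1
        out.extend((chrom, s, e) for s, e in _merge_intervals(hits))
    return PeakSet(peaks=out, source_kind=f"{a.source_kind}&{b.source_kind}")


def _standardize_region(
    chrom: str,
    start: int,
    end: int,
    length: int,
    chrom_sizes: Mapping[str, int] | None,
) -> tuple[int, int]:
    """Anchor at midpoint, expand symmetrically, clip then shift."""
    mid = (start + end) // 2
    lo = mid - length // 2
    hi = lo + length
    if lo < 0:
        lo, hi = 0, length
    if chrom_sizes is not None and chrom in chrom_sizes:
        size = chrom_sizes[chrom]
        if hi > size:
            hi = size
            lo = max(0, size - length)
    return lo, hi


def label_regions(
    starr: PeakSet,
    dnase: PeakSet,
    chip: Sequence[PeakSet],
    chrom_sizes: Mapping[str, int] | None = None,
    region_length: int = REGION_LENGTH,
) -> list[GenomicRegion]:
    """Positive 4000 bp regions: STARR∩DNase candidates supported by ≥1 ChIP peak.

    Each positive is anchored at the candidate midpoint and standardized to
    ``region_length``.
    """
    if not chip:
        raise ValueError("need at least one ChIP PeakSet")
    candidates = intersect_peaks(starr, dnase)
    if len(candidates) == 0:
        warnings.warn("no STARR∩DNase candidate regions found", stacklevel=2)
        return []
    chip_by = [ps.by_chrom() for ps in chip]
    positives: list[GenomicRegion] = []
    for chrom, start, end in candidates.peaks:
        supported = False
        for by in chip_by:
            ivals = by.get(chrom)
            if ivals is None:
                continue
            if bool(((ivals[:, 0] < end) & (start < ivals[:, 1])).any()):
                supported = True
                break
        if supported:
            lo, hi = _standardize_region(chrom, start, end, region_length, chrom_sizes)
            positives.append(GenomicRegion(chrom, lo, hi, "positive"))
    return positives


def sample_negatives(
    chrom_sizes: Mapping[str, int],
    positives: Sequence[GenomicRegion],
    n: int,
    seed: int,
    region_length: int = REGION_LENGTH,
) -> list[GenomicRegion]:
    """Randomly placed 4000 bp regions overlapping no positive by ≥1 bp."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    chroms = [c for c, size in chrom_sizes.items() if size >= region_length]
    if not chroms:
        raise ValueError(f"no chromosome can host a {region_length} bp region")
    weights = np.asarray([chrom_sizes[c] - region_length + 1 for c in chroms], float)
    weights /= weights.sum()
    pos_by: dict[str, list[tuple[int, int]]] = {}
    for p in positives:
        pos_by.setdefault(p.chrom, []).append((p.start, p.end))

    out: list[GenomicRegion] = []
    max_attempts = 1000 * n
    attempts = 0
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, chrom_sizes[chrom] - region_length + 1))
        end = start + region_length
        if any(start < pe and ps < end for ps, pe in pos_by.get(chrom, ())):
            continue
        out.append(GenomicRegion(chrom, start, end, "negative"))
    if len(out) < n:
        raise RuntimeError(
            f"could only place {len(out)} of {n} negative regions "
            f"after {max_attempts} attempts"
        )
    return out


# ---------------------------------------------------------------------------
# Signal binning
# ---------------------------------------------------------------------------

def bin_signal(
    track: SignalTrack,
    region: GenomicRegion,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> np.ndarray:
    """Mean per-base signal in consecutive ``bin_size`` bp bins over the region.

    Bases not covered by any track interval contribute 0.
    """
    length = region.length
    if length % bin_size != 0:
        raise ValueError(
            f"region length {length} not divisible by bin size {bin_size}"
        )
    per_base = np.zeros(length, dtype=np.float64)
    chrom_data = track.by_chrom().get(region.chrom)
    if chrom_data is not None:
        starts, ends, values = chrom_data
        lo = np.maximum(starts, region.start) - region.start
        hi = np.minimum(ends, region.end) - region.start
        for s, e, v in zip(lo, hi, values):
            if e > s:
                per_base[s:e] += v
    return per_base.reshape(-1, bin_size).mean(axis=1)


def build_matrix(
    regions: Sequence[GenomicRegion],
    tracks: Mapping[str, SignalTrack],
    signal_kinds: Sequence[str],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> SignalMatrix:
    """Concatenate binned-signal blocks in the given signal order."""
    for kind in signal_kinds:
        if kind not in tracks:
            raise KeyError(f"no track provided for signal kind {kind!r}")
    if not regions:
        raise ValueError("no regions given")
    bins = regions[0].length // bin_size
    blocks = []
    for kind in signal_kinds:
        block = np.stack([bin_signal(tracks[kind], r, bin_size) for r in regions])
        blocks.append(block)
    X = np.concatenate(blocks, axis=1)
    y = np.asarray([1 if r.label == "positive" else 0 for r in regions])
    return SignalMatrix(
        X=X,
        y=y,
        signal_kinds=list(signal_kinds),
        region_index=list(regions),
        bins_per_region=bins,
    )


def add_gaussian_noise(m: SignalMatrix, sigma: float, seed: int) -> SignalMatrix:
    """Elementwise N(0, sigma²) perturbation of the feature matrix."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    X = m.X + rng.normal(0.0, sigma, size=m.X.shape) if sigma > 0 else m.X.copy()
    return SignalMatrix(
        X=X,
        y=m.y.copy(),
        signal_kinds=list(m.signal_kinds),
        region_index=list(m.region_index),
        bins_per_region=m.bins_per_region,
    )
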