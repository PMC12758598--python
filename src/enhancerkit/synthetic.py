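"""Synthetic data generators.

Emulates the structure of the real inputs at desk scale: labeled 4000 bp
regions with locally enriched signal bumps against background noise at a
1:10 positive:negative ratio, 4000 bp sequences with a motif-dense planted
enhancer at a 50 bp-aligned offset, and balanced 200 bp window training sets.
All generators are bit-reproducible given a seed and can also emit the same
on-disk formats the real pipeline reads (BED, bedGraph, FASTA, chrom.sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .locator import Embedder, kmer_embed
from .regions import (
    DEFAULT_BIN_SIZE,
    REGION_LENGTH,
    GenomicRegion,
    SignalMatrix,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_signal_dataset",
    "gen_localization_dataset",
    "gen_window_training_set",
    "gen_genome_fixture",
]


@dataclass
class SimConfig:
    seed: int = 0
    n_pos: int = 20
    n_neg: int | None = None  # default 10 * n_pos
    region_length: int = REGION_LENGTH
    bin_size: int = DEFAULT_BIN_SIZE
    signal_kinds: list[str] = field(default_factory=lambda: ["DNase", "H3K27ac"])
    enrichment_height: float = 2.0
    bump_width: int = 600  # bp, Gaussian sd of the enrichment profile
    background_level: float = 0.1
    noise_sigma: float = 0.3
    motif: str = "TGACTCAGC"
    motif_density: float = 0.8
    enhancer_length: int = 1000  # bp, multiple of 50
    kmer_k: int = 4
    windows_per_class: int = 500

    def validate(self) -> None:
        if self.n_pos < 1:
            raise ValueError("n_pos must be >= 1")
        if self.region_length % self.bin_size != 0:
            raise ValueError("region_length must be divisible by bin_size")
        if self.enhancer_length % 50 != 0:
            raise ValueError("enhancer_length must be a multiple of 50")
        if not 200 <= self.enhancer_length <= self.region_length:
            raise ValueError("enhancer_length must be in [200, region_length]")
        if self.noise_sigma < 0 or self.background_level < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.motif_density <= 1.0:
            raise ValueError("motif_density must be in [0, 1]")
        if not self.signal_kinds:
            raise ValueError("need at least one signal kind")

    @property
    def n_negatives(self) -> int:
        return 10 * self.n_pos if self.n_neg is None else self.n_neg


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    enhancer_intervals: list[tuple[str, int, int]]  # absolute bp, per positive
    enriched_signals: list[str] = field(default_factory=list)
    motif_positions: list[list[int]] = field(default_factory=list)  # per sequence


# ---------------------------------------------------------------------------
# Stage-1 data: binned signal matrices
# ---------------------------------------------------------------------------

def gen_signal_dataset(cfg: SimConfig) -> tuple[SignalMatrix, SimTruth]:
    """Positives carry a Gaussian enrichment bump in every configured signal."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_bins = cfg.region_length // cfg.bin_size
    n_neg = cfg.n_negatives
    n = cfg.n_pos + n_neg
    spacing = 2 * cfg.region_length

    regions = []
    for i in range(n):
        label = "positive" if i < cfg.n_pos else "negative"
        start = i * spacing
        regions.append(GenomicRegion("chrSim", start, start + cfg.region_length, label))

    half = cfg.enhancer_length // 2
    centers_bp = []
    truth_intervals = []
    for i in range(cfg.n_pos):
        lo_bp, hi_bp = half, cfg.region_length - half
        center = 50 * int(rng.integers(lo_bp // 50, hi_bp // 50 + 1))
        centers_bp.append(center)
        truth_intervals.append(
            ("chrSim", regions[i].start + center - half, regions[i].start + center + half)
        )

    bin_pos_bp = (np.arange(n_bins) + 0.5) * cfg.bin_size
    blocks = []
    for _kind in cfg.signal_kinds:
        block = cfg.background_level + rng.normal(
            0.0, cfg.noise_sigma, size=(n, n_bins)
        )
        for i, center in enumerate(centers_bp):
            bump = cfg.enrichment_height * np.exp(
                -0.5 * ((bin_pos_bp - center) / cfg.bump_width) ** 2
            )
            block[i] += bump
        blocks.append(block)
    X = np.concatenate(blocks, axis=1)
    y = np.r_[np.ones(cfg.n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    matrix = SignalMatrix(
        X=X,
        y=y,
        signal_kinds=list(cfg.signal_kinds),
        region_index=regions,
        bins_per_region=n_bins,
    )
    truth = SimTruth(
        enhancer_intervals=truth_intervals,
        enriched_signals=list(cfg.signal_kinds),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Stage-2 data: sequences with planted enhancers
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def gen_localization_dataset(
    cfg: SimConfig,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """4000 bp sequences, each with a motif-dense enhancer at a 50 bp offset.

    Returns FASTA-like ``(name, sequence)`` records plus the planted truth.
    """
    cfg.validate()
    if cfg.enhancer_length > cfg.region_length:
        raise ValueError("enhancer_length exceeds region_length")
    rng = np.random.default_rng(cfg.seed)
    records = []
    truth_intervals = []
    motif_positions: list[list[int]] = []
    motif = np.array(list(cfg.motif))
    mlen = len(cfg.motif)
    for i in range(cfg.n_pos):
        seq = _random_seq(rng, cfg.region_length)
        offset = 50 * int(rng.integers(0, (cfg.region_length - cfg.enhancer_length) // 50 + 1))
        n_slots = cfg.enhancer_length // mlen
        n_copies = int(round(cfg.motif_density * n_slots))
        slots = rng.choice(n_slots, size=n_copies, replace=False) if n_copies else []
        positions = sorted(offset + int(s) * mlen for s in slots)
        for p in positions:
            seq[p : p + mlen] = motif
        name = f"region_{i}"
        records.append((name, "".join(seq)))
        truth_intervals.append((name, offset, offset + cfg.enhancer_length))
        motif_positions.append(positions)
    truth = SimTruth(
        enhancer_intervals=truth_intervals, motif_positions=motif_positions
    )
    return records, truth


def gen_window_training_set(
    cfg: SimConfig,
    window: int = 200,
    step: int = 50,
    labeling: str = "overlap50",
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced embedded 200 bp windows from planted-enhancer sequences.

    ``labeling="overlap50"``: positives overlap the true enhancer by ≥50% of
    the window, negatives have zero overlap, partially overlapping windows are
    dropped.  ``labeling="sharp"``: positives lie fully inside the enhancer
    and everything else (including partial overlaps) is negative — a scorer
    trained this way has its decision boundary at the enhancer edge, which is
    what boundary-recovery benchmarks need (an overlap50-trained scorer
    retains half-overlapping windows and systematically widens calls by
    window/2 per side).
    """
    cfg.validate()
    if labeling not in ("overlap50", "sharp"):
        raise ValueError(f"unknown labeling {labeling!r}")
    records, truth = gen_localization_dataset(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    pos_seqs: list[str] = []
    neg_seqs: list[str] = []
    for (name, seq), (_, enh_start, enh_end) in zip(records, truth.enhancer_intervals):
        for off in range(0, len(seq) - window + 1, step):
            overlap = max(0, min(off + window, enh_end) - max(off, enh_start))
            if labeling == "overlap50":
                if overlap * 2 >= window:
                    pos_seqs.append(seq[off : off + window])
                elif overlap == 0:
                    neg_seqs.append(seq[off : off + window])
            else:
                if overlap == window:
                    pos_seqs.append(seq[off : off + window])
                else:
                    neg_seqs.append(seq[off : off + window])
    n_per_class = min(cfg.windows_per_class, len(pos_seqs), len(neg_seqs))
    pos_pick = rng.choice(len(pos_seqs), size=n_per_class, replace=False)
    neg_pick = rng.choice(len(neg_seqs), size=n_per_class, replace=False)
    chosen = [pos_seqs[i] for i in pos_pick] + [neg_seqs[i] for i in neg_pick]
    X = np.stack([kmer_embed(s, cfg.kmer_k) for s in chosen])
    y = np.r_[np.ones(n_per_class, dtype=int), np.zeros(n_per_class, dtype=int)]
    return X, y


# ---------------------------------------------------------------------------
# On-disk genome fixture exercising the real I/O path
# ---------------------------------------------------------------------------

def gen_genome_fixture(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a toy genome: chrom.sizes, STARR/DNase/ChIP BED peaks around
    planted enhancers, and bedGraph tracks with enrichment bumps.

    The peak files are constructed so that every planted enhancer survives the
    STARR∩DNase∩ChIP labeling rule and nothing else does.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spacing = 3 * cfg.region_length
    chrom = "chrSim"
    genome_size = (cfg.n_pos + 2) * spacing
    centers = [(i + 1) * spacing for i in range(cfg.n_pos)]

    paths: dict[str, Path] = {}
    sizes_path = outdir / "chrom.sizes"
    sizes_path.write_text(f"{chrom}\t{genome_size}\n")
    paths["chrom_sizes"] = sizes_path

    half = cfg.enhancer_length // 2

    def write_peaks(fname: str, jitter: int) -> Path:
        p = outdir / fname
        lines = []
        for c in centers:
            j = int(rng.integers(-jitter, jitter + 1))
            lines.append(f"{chrom}\t{c - half + j}\t{c + half + j}\n")
        p.write_text("".join(lines))
        return p

    paths["STARR"] = write_peaks("starr_peaks.bed", jitter=50)
    paths["DNase"] = write_peaks("dnase_peaks.bed", jitter=50)
    for kind in ("H3K27ac", "H3K4me3"):
        paths[kind] = write_peaks(f"{kind.lower()}_peaks.bed", jitter=100)

    bin_size = cfg.bin_size
    for kind in cfg.signal_kinds:
        p = outdir / f"{kind.lower()}_signal.bedgraph"
        with open(p, "w") as fh:
            for c in centers:
                lo = c - cfg.region_length
                hi = c + cfg.region_length
                starts = np.arange(lo, hi, bin_size)
                mids = starts + bin_size / 2
                vals = (
                    cfg.background_level
                    + cfg.enrichment_height
                    * np.exp(-0.5 * ((mids - c) / cfg.bump_width) ** 2)
                    + rng.normal(0.0, cfg.noise_sigma, size=len(starts))
                )
                for s, v in zip(starts, vals):
                    fh.write(f"{chrom}\t{s}\t{s + bin_size}\t{v:.5f}\n")
        paths[f"track_{kind}"] = p

    truth_path = outdir / "truth_enhancers.bed"
    truth_path.write_text(
        "".join(f"{chrom}\t{c - half}\t{c + half}\n" for c in centers)
    )
    paths["truth"] = truth_path
    return paths


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio.SeqIO import parse as seqio_parse

    return [(rec.id, str(rec.seq)) for rec in seqio_parse(str(path), "fasta")]
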