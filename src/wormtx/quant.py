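"""Expression quantification for tiling arrays and RNA-seq coverage.

Tiling arrays: probe signal is PM − MM (perfect-match minus mismatch
intensity), replicates are made comparable by quantile normalization and
combined, probe values are smoothed with a Hodges–Lehmann pseudomedian
over a 110 bp window, a transcript's value is the median over probes
overlapping its exons by at least 50 % of the probe length, and arrays
are made comparable by dividing by the slide median.

RNA-seq: per-transcript expression is the average depth of coverage per
million mapped reads (dcpm).  Bases whose reads map to 96 or more
genomic locations (the "representation" value) are excluded from both
the coverage sum and the base count, so multi-mapping regions do not
inflate or deflate the average; a transcript with no eligible base gets
a missing value rather than zero.

Coordinates are 0-based half-open throughout; strand is ignored for
probe–exon overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple chromosomes")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class ProbeMeasurement:
    probe_id: str
    interval: GenomicInterval
    pm: np.ndarray  # one intensity per replicate
    mm: np.ndarray

    def __post_init__(self):
        self.pm = np.asarray(self.pm, dtype=float)
        self.mm = np.asarray(self.mm, dtype=float)
        if self.pm.shape != self.mm.shape:
            raise ValueError(f"{self.probe_id}: PM/MM replicate count mismatch")


@dataclass
class TilingConfig:
    smoothing_window_bp: float = 110.0
    min_exon_overlap_fraction: float = 0.5
    replicate_combine: str = "mean"  # or "median"

    def __post_init__(self):
        if self.smoothing_window_bp <= 0:
            raise ValueError("smoothing window must be positive")
        if not 0 < self.min_exon_overlap_fraction <= 1:
            raise ValueError("overlap fraction must be in (0, 1]")


@dataclass
class DcpmConfig:
    representation_cutoff: int = 96
    scale: float = 1_000_000.0
    quality_threshold: float = 0.0  # bases must exceed this score to count coverage

    def __post_init__(self):
        if self.representation_cutoff <= 0:
            raise ValueError("representation cutoff must be positive")


@dataclass
class ReadStats:
    high_quality_mapped_reads: int

    def __post_init__(self):
        if self.high_quality_mapped_reads <= 0:
            raise ValueError("mapped-read count must be positive")


@dataclass
class CoverageTrack:
    """Per-base coverage with multi-mapping representation values.

    Backed by a DataFrame with columns (chrom, pos, score, representation);
    bases absent from the table are taken as score 0, representation 1.
    """

    data: pd.DataFrame

    def __post_init__(self):
        need = {"chrom", "pos", "score", "representation"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"coverage table lacks columns {sorted(missing)}")
        if (self.data["representation"] < 1).any():
            raise ValueError("representation values must be >= 1")
        self._by_chrom = {
            str(c): g.set_index("pos") for c, g in self.data.groupby("chrom")
        }

    @classmethod
    def from_tsv(cls, path) -> "CoverageTrack":
        df = pd.read_csv(
            path, sep="\t",
            dtype={"chrom": str, "pos": int, "score": float, "representation": int},
        )
        return cls(df)

    def base_arrays(self, interval: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
        """(score, representation) arrays for every base of ``interval``."""
        n = len(interval)
        score = np.zeros(n)
        rep = np.ones(n, dtype=int)
        g = self._by_chrom.get(interval.chrom)
        if g is not None:
            pos = g.index.values
            mask = (pos >= interval.start) & (pos < interval.end)
            idx = pos[mask] - interval.start
            score[idx] = g["score"].values[mask]
            rep[idx] = g["representation"].values[mask]
        return score, rep


# ---------------------------------------------------------------------------
# tiling-array primitives

def pm_mm_difference(probes: Sequence[ProbeMeasurement]) -> np.ndarray:
    """Per-probe, per-replicate specific-hybridization signal (PM − MM).

    Negative differences are retained: clipping would bias downstream
    medians upward.
    """
    if not probes:
        raise ValueError("no probes")
    counts = {p.pm.shape for p in probes}
    if len(counts) > 1:
        raise ValueError("probes have differing replicate counts")
    return np.vstack([p.pm - p.mm for p in probes])


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force identical value distributions across columns.

    Each column's order statistics are replaced by the across-column mean
    of order statistics; within-column ranks are preserved.  Ties are
    resolved by stable sort order, the convention of the standard
    implementation for full-resolution intensity data.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    if np.isnan(m).all(axis=0).any():
        raise ValueError("a column is entirely missing")
    order = np.argsort(m, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(m.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows + np.zeros_like(order[:1]), axis=0)
    means = np.sort(m, axis=0).mean(axis=1)
    return means[ranks]


def pseudomedian(values: Iterable[float]) -> float:
    """Hodges–Lehmann estimator: median of all pairwise averages (i <= j).

    Including self-pairs keeps the estimator defined for a single value.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("pseudomedian of empty set")
    i, j = np.triu_indices(v.size)
    return float(np.median((v[i] + v[j]) / 2.0))


def pseudomedian_smooth(
    values: Sequence[float], positions: Sequence[float], window_bp: float
) -> np.ndarray:
    """Smooth per-probe values with the pseudomedian of a centered window.

    For each probe, all probes whose center lies within ±window/2 of its
    own center contribute.  Every window contains the probe itself, so
    the result is always defined; window → 0 returns the input.
    """
    vals = np.asarray(values, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if vals.shape != pos.shape:
        raise ValueError("values and positions differ in length")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    if window_bp < 0:
        raise ValueError("window must be non-negative")
    half = window_bp / 2.0
    out = np.empty_like(vals)
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    for k in range(vals.size):
        out[k] = pseudomedian(vals[lo[k]:hi[k]])
    return out


def _exon_overlap(interval: GenomicInterval, model: TranscriptModel) -> int:
    return sum(interval.overlap(e) for e in model.exons)


def transcript_expression_from_probes(
    probes: Sequence[ProbeMeasurement],
    smoothed: Sequence[float],
    model: TranscriptModel,
    config: TilingConfig | None = None,
) -> float:
    """Median smoothed signal over probes overlapping the transcript's
    exons by at least ``min_exon_overlap_fraction`` of the probe length.

    Returns NaN when no probe qualifies.  Overlap is summed across exons,
    so a probe straddling an intron still qualifies if its exonic parts
    together reach the threshold.
    """
    config = config or TilingConfig()
    vals = [
        s
        for p, s in zip(probes, smoothed)
        if p.interval.chrom == model.chrom
        and _exon_overlap(p.interval, model) / len(p.interval)
        >= config.min_exon_overlap_fraction
    ]
    if not vals:
        return float("nan")
    return float(np.median(vals))


def slide_median_normalize(values: np.ndarray | pd.Series):
    """Divide every probe value on an array by the slide (array-wide) median."""
    v = np.asarray(values, dtype=float)
    med = float(np.median(v[~np.isnan(v)]))
    if med == 0:
        raise ValueError("slide median is zero; cannot normalize")
    out = values / med
    return out


def tiling_expression(
    probes: Sequence[ProbeMeasurement],
    models: Sequence[TranscriptModel],
    config: TilingConfig | None = None,
) -> pd.Series:
    """Full tiling pipeline for one condition: PM−MM, quantile
    normalization across replicates, replicate combination, pseudomedian
    smoothing per chromosome, per-transcript median, slide-median
    normalization.  Returns one value per transcript (NaN when no probe
    qualifies)."""
    config = config or TilingConfig()
    signal = pm_mm_difference(probes)
    if signal.shape[1] >= 2:
        signal = quantile_normalize(signal)
    combine = np.nanmedian if config.replicate_combine == "median" else np.nanmean
    combined = combine(signal, axis=1)

    # smooth within each chromosome, in coordinate order
    idx = sorted(range(len(probes)), key=lambda k: (probes[k].interval.chrom, probes[k].interval.center))
    smoothed = np.empty(len(probes))
    start = 0
    while start < len(idx):
        chrom = probes[idx[start]].interval.chrom
        stop = start
        while stop < len(idx) and probes[idx[stop]].interval.chrom == chrom:
            stop += 1
        block = idx[start:stop]
        sm = pseudomedian_smooth(
            combined[block],
            [probes[k].interval.center for k in block],
            config.smoothing_window_bp,
        )
        smoothed[block] = sm
        start = stop

    smoothed = slide_median_normalize(smoothed)
    out = {}
    for m in models:
        out[m.transcript_id] = transcript_expression_from_probes(
            probes, smoothed, m, config
        )
    return pd.Series(out, name="tiling")


# ---------------------------------------------------------------------------
# RNA-seq dcpm

def compute_dcpm(
    coverage: CoverageTrack,
    model: TranscriptModel,
    read_stats: ReadStats,
    config: DcpmConfig | None = None,
) -> float:
    """Average depth of coverage per million mapped reads for one transcript.

    numerator   = sum of scores over exonic bases with score above the
                  quality threshold and representation below the cutoff
    denominator = count of exonic bases with representation below the cutoff
    dcpm        = numerator / denominator * 1e6 / mapped_reads

    A transcript whose every exonic base is at or above the representation
    cutoff has zero bases in the denominator and yields NaN (missing), the
    convention used in the per-transcript expression tables.
    """
    config = config or DcpmConfig()
    total = 0.0
    eligible = 0
    for exon in model.exons:
        score, rep = coverage.base_arrays(exon)
        ok = rep < config.representation_cutoff
        eligible += int(ok.sum())
        counted = ok & (score > config.quality_threshold)
        total += float(score[counted].sum())
    if eligible == 0:
        return float("nan")
    return (total / eligible) * config.scale / read_stats.high_quality_mapped_reads


def dcpm_table(
    coverage: CoverageTrack,
    models: Sequence[TranscriptModel],
    read_stats: ReadStats,
    config: DcpmConfig | None = None,
) -> pd.Series:
    """dcpm for every transcript model; NaN marks missing values."""
    config = config or DcpmConfig()
    return pd.Series(
        {m.transcript_id: compute_dcpm(coverage, m, read_stats, config) for m in models},
        name="dcpm",
    )


# ---------------------------------------------------------------------------
# GFF3 transcript models

def read_transcript_models(path) -> list[TranscriptModel]:
    """Read gene/mRNA/exon features from a GFF3 file into transcript models.

    Supports the common layout gene -> mRNA -> exon with ID/Parent
    attributes; GFF3 coordinates (1-based closed) are converted to the
    0-based half-open convention used internally.
    """
    mrna_gene: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line[:80]}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("mRNA", "transcript"):
                mrna_gene[attr["ID"]] = attr.get("Parent", attr["ID"])
            elif ftype == "exon":
                parent = attr["Parent"].split(",")[0]
                exons.setdefault(parent, []).append(
                    GenomicInterval(chrom, int(start) - 1, int(end), strand)
                )
    models = []
    for tid, ex in exons.items():
        models.append(
            TranscriptModel(
                transcript_id=tid, gene_id=mrna_gene.get(tid, tid), exons=ex
            )
        )
    return models


def read_probe_table(path) -> list[ProbeMeasurement]:
    """Probe table TSV: probe_id, chrom, start, end, pm_rep1.., mm_rep1.. ."""
    df = pd.read_csv(path, sep="\t")
    pm_cols = sorted(c for c in df.columns if c.startswith("pm_"))
    mm_cols = sorted(c for c in df.columns if c.startswith("mm_"))
    if len(pm_cols) != len(mm_cols) or not pm_cols:
        raise ValueError("probe table needs matching pm_*/mm_* columns")
    probes = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        probes.append(
            ProbeMeasurement(
                probe_id=str(d["probe_id"]),
                interval=GenomicInterval(str(d["chrom"]), int(d["start"]), int(d["end"])),
                pm=np.array([d[c] for c in pm_cols], dtype=float),
                mm=np.array([d[c] for c in mm_cols], dtype=float),
            )
        )
    return probes
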