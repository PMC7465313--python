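"""Run statistics, enrichment statistics, and coverage-based off-target
detection for targeted-enrichment sequencing runs.

Inputs are reads (FASTQ or in-memory) and alignments in PAF convention
(0-based half-open target coordinates, as emitted by long-read mappers);
SAM is accepted through a thin pysam reader.  The public window
coordinates are 1-based inclusive.

Three report families:

* read statistics - counts, bases, median length, N50, median read
  quality, with a pass partition at mean read quality >= 7 (probability-
  space mean);
* enrichment statistics - aligned reads, on-target forward/reverse read
  counts, on-target "coverage" in the read-count sense (the sum of the
  strand counts), on-target percentage, plus mean per-base depth over the
  window (labelled separately since it is a different quantity);
* off-target regions - binned, mapping-quality-filtered coverage merged
  into regions where depth >= 25x at mapq >= 40, excluding the on-target
  window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_PASS_QUALITY = 7.0
DEFAULT_MIN_MAPQ = 40
DEFAULT_MIN_COVERAGE = 25.0
DEFAULT_BIN_SIZE = 1000


# ---------------------------------------------------------------------------
# alignments (PAF convention)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment in PAF convention: coordinates 0-based half-open."""
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    blocklen: int
    mapq: int

    def __post_init__(self):
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"{self.qname}: bad query interval")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"{self.qname}: bad target interval")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"{self.qname}: mapq outside [0,255]")


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join(map(str, (
                r.qname, r.qlen, r.qstart, r.qend, r.strand, r.tname,
                r.tlen, r.tstart, r.tend, r.nmatch, r.blocklen, r.mapq))) + "\n")


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}: line {lineno}: fewer than 12 PAF columns")
            out.append(AlignmentRecord(
                qname=parts[0], qlen=int(parts[1]), qstart=int(parts[2]),
                qend=int(parts[3]), strand=parts[4], tname=parts[5],
                tlen=int(parts[6]), tstart=int(parts[7]), tend=int(parts[8]),
                nmatch=int(parts[9]), blocklen=int(parts[10]), mapq=int(parts[11])))
    return out


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Thin SAM/BAM reader mapping mapped records onto the PAF convention."""
    import pysam
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_end is None:
                continue
            qlen = rec.infer_read_length() or rec.query_length or 1
            qstart = rec.query_alignment_start
            qend = rec.query_alignment_end
            out.append(AlignmentRecord(
                qname=rec.query_name, qlen=qlen, qstart=qstart, qend=qend,
                strand="-" if rec.is_reverse else "+",
                tname=rec.reference_name,
                tlen=fh.get_reference_length(rec.reference_name),
                tstart=rec.reference_start, tend=rec.reference_end,
                nmatch=qend - qstart, blocklen=rec.reference_end - rec.reference_start,
                mapq=rec.mapping_quality))
    return out


# ---------------------------------------------------------------------------
# read statistics
# ---------------------------------------------------------------------------

@dataclass
class ReadStats:
    reads: int
    bases: int
    median_length: float
    n50: int
    median_quality: float
    pass_reads: int
    pass_bases: int
    pass_median_length: float
    pass_n50: int
    pass_median_quality: float
    pass_threshold: float = DEFAULT_PASS_QUALITY


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that reads of length >= L contain at least half of
    all bases."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length set")
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


def _normalise_reads(reads) -> tuple[np.ndarray, np.ndarray]:
    """Accepts SimulatedRead-like objects (``sequence``/``qualities``) or
    ``(length, mean_quality)`` pairs; returns (lengths, mean_qualities)."""
    from .readsim import mean_read_quality
    lengths, quals = [], []
    for r in reads:
        if hasattr(r, "qualities"):
            lengths.append(len(r.sequence))
            quals.append(mean_read_quality(r.qualities))
        else:
            length, q = r
            lengths.append(int(length))
            quals.append(float(q))
    return np.asarray(lengths, dtype=np.int64), np.asarray(quals, dtype=float)


def read_stats(reads, pass_threshold: float = DEFAULT_PASS_QUALITY) -> ReadStats:
    """Summary statistics with a pass partition at mean quality >=
    ``pass_threshold`` (inclusive)."""
    lengths, quals = _normalise_reads(reads)
    if lengths.size == 0:
        raise ValueError("read_stats requires at least one read")
    keep = quals >= pass_threshold
    if keep.any():
        p_len, p_q = lengths[keep], quals[keep]
        pass_part = (int(keep.sum()), int(p_len.sum()), float(np.median(p_len)),
                     n50(p_len), float(np.median(p_q)))
    else:
        pass_part = (0, 0, 0.0, 0, 0.0)
    return ReadStats(
        reads=int(lengths.size), bases=int(lengths.sum()),
        median_length=float(np.median(lengths)), n50=n50(lengths),
        median_quality=float(np.median(quals)),
        pass_reads=pass_part[0], pass_bases=pass_part[1],
        pass_median_length=pass_part[2], pass_n50=pass_part[3],
        pass_median_quality=pass_part[4], pass_threshold=pass_threshold)


# ---------------------------------------------------------------------------
# enrichment report
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    aligned_reads: int
    on_target_forward: int
    on_target_reverse: int
    on_target_coverage: int     # read-count semantics: forward + reverse
    on_target_percentage: float
    mean_window_depth: float    # mean per-base depth over the window(s)
    empty_input: bool = False


Window = tuple[str, int, int]   # contig, 1-based inclusive start/end


def _as_windows(window) -> list[Window]:
    if isinstance(window, tuple) and len(window) == 3 and isinstance(window[0], str):
        return [window]
    return list(window)


def _overlaps(rec: AlignmentRecord, w: Window) -> bool:
    contig, start, end = w
    return rec.tname == contig and rec.tstart <= end - 1 and rec.tend >= start


def best_alignments(alignments: Iterable[AlignmentRecord]) -> dict[str, AlignmentRecord]:
    """Primary alignment per query: highest mapq, deterministic tie-break
    by first target coordinate."""
    best: dict[str, AlignmentRecord] = {}
    for rec in alignments:
        cur = best.get(rec.qname)
        if cur is None or rec.mapq > cur.mapq or (
                rec.mapq == cur.mapq and
                (rec.tname, rec.tstart) < (cur.tname, cur.tstart)):
            best[rec.qname] = rec
    return best


def enrichment_report(alignments: Sequence[AlignmentRecord],
                      window) -> EnrichmentReport:
    """Table-style enrichment statistics against one or more windows.

    A read is on-target iff its best (primary) alignment overlaps a window
    by >= 1 bp.  "Coverage" is the on-target read count (forward +
    reverse); mean per-base depth over the window is reported separately.
    """
    windows = _as_windows(window)
    if not alignments:
        warnings.warn("enrichment_report: no alignments", stacklevel=2)
        return EnrichmentReport(0, 0, 0, 0, 0.0, 0.0, empty_input=True)
    best = best_alignments(alignments)
    fwd = rev = 0
    for rec in best.values():
        if any(_overlaps(rec, w) for w in windows):
            if rec.strand == "+":
                fwd += 1
            else:
                rev += 1
    aligned = len(best)
    on = fwd + rev
    depth = per_base_depth(list(best.values()), min_mapq=0)
    total = 0.0
    span = 0
    for contig, start, end in windows:
        if contig in depth:
            vec = depth[contig][start - 1:end]
            total += float(vec.sum())
            span += end - start + 1
        else:
            span += end - start + 1
    return EnrichmentReport(
        aligned_reads=aligned, on_target_forward=fwd, on_target_reverse=rev,
        on_target_coverage=on,
        on_target_percentage=100.0 * on / aligned,
        mean_window_depth=total / span if span else 0.0)


# ---------------------------------------------------------------------------
# depth, bins, off-target regions
# ---------------------------------------------------------------------------

def per_base_depth(alignments: Sequence[AlignmentRecord],
                   min_mapq: int = 0) -> dict[str, np.ndarray]:
    """Depth vector per contig: number of alignments with mapq >=
    ``min_mapq`` covering each position (vector index 0 = position 1)."""
    lengths: dict[str, int] = {}
    for rec in alignments:
        lengths[rec.tname] = max(lengths.get(rec.tname, 0), rec.tlen)
    diff = {c: np.zeros(L + 1, dtype=np.int64) for c, L in lengths.items()}
    for rec in alignments:
        if rec.mapq < min_mapq:
            continue
        diff[rec.tname][rec.tstart] += 1
        diff[rec.tname][rec.tend] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diff.items()}


@dataclass(frozen=True)
class CoverageBin:
    contig: str
    start: int      # 1-based inclusive
    end: int
    depth: float    # mean per-base depth in the bin


def bin_coverage(alignments: Sequence[AlignmentRecord],
                 bin_size: int = DEFAULT_BIN_SIZE,
                 min_mapq: int = DEFAULT_MIN_MAPQ) -> list[CoverageBin]:
    """Fixed-width binned mean depth under a mapping-quality filter."""
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    depth = per_base_depth(alignments, min_mapq=min_mapq)
    bins: list[CoverageBin] = []
    for contig in sorted(depth):
        vec = depth[contig]
        for b0 in range(0, len(vec), bin_size):
            chunk = vec[b0:b0 + bin_size]
            bins.append(CoverageBin(contig, b0 + 1, b0 + len(chunk),
                                    float(chunk.mean())))
    return bins


@dataclass
class OffTargetRegion:
    contig: str
    start: int
    end: int
    total_size: int
    max_coverage: float
    annotations: list[str] = field(default_factory=list)


def detect_offtargets(bins: Sequence[CoverageBin], window,
                      min_coverage: float = DEFAULT_MIN_COVERAGE,
                      annotations: Sequence[tuple[str, int, int, str]] = ()
                      ) -> list[OffTargetRegion]:
    """Merge adjacent qualifying bins into off-target regions.

    Bins must already be mapping-quality filtered (see
    :func:`bin_coverage`).  Regions overlapping the on-target window(s)
    are excluded; each region reports its size, maximum bin coverage and
    any overlapping annotation labels.
    """
    if min_coverage <= 0:
        raise ValueError("min_coverage must be positive")
    windows = _as_windows(window) if window else []
    regions: list[OffTargetRegion] = []
    current: OffTargetRegion | None = None
    for b in bins:
        if b.depth >= min_coverage:
            if (current is not None and current.contig == b.contig
                    and b.start == current.end + 1):
                current.end = b.end
                current.max_coverage = max(current.max_coverage, b.depth)
            else:
                if current is not None:
                    regions.append(current)
                current = OffTargetRegion(b.contig, b.start, b.end,
                                          0, b.depth)
        else:
            if current is not None:
                regions.append(current)
                current = None
    if current is not None:
        regions.append(current)

    out = []
    for r in regions:
        r.total_size = r.end - r.start + 1
        if any(r.contig == c and r.start <= e and r.end >= s
               for c, s, e in windows):
            continue
        r.annotations = [label for c, s, e, label in annotations
                         if c == r.contig and r.start <= e and r.end >= s]
        out.append(r)
    return out


def plot_window_depth(alignments: Sequence[AlignmentRecord], window,
                      path: str | Path, min_mapq: int = 0) -> None:
    """Per-base depth profile over the on-target window(s), one panel per
    window, written to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    windows = _as_windows(window)
    depth = per_base_depth(alignments, min_mapq=min_mapq)
    fig, axes = plt.subplots(len(windows), 1, squeeze=False,
                             figsize=(8, 2.5 * len(windows)))
    for ax, (contig, start, end) in zip(axes.ravel(), windows):
        vec = depth.get(contig)
        y = vec[start - 1:end] if vec is not None else np.zeros(end - start + 1)
        ax.fill_between(np.arange(start, start + len(y)), y, step="mid",
                        alpha=0.6)
        ax.set_title(f"{contig}:{start}-{end}")
        ax.set_ylabel("depth")
    axes.ravel()[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def find_offtarget_regions(alignments: Sequence[AlignmentRecord], window,
                           bin_size: int = DEFAULT_BIN_SIZE,
                           min_mapq: int = DEFAULT_MIN_MAPQ,
                           min_coverage: float = DEFAULT_MIN_COVERAGE,
                           annotations=()) -> list[OffTargetRegion]:
    """Convenience composition: bin under the mapq filter, then detect."""
    bins = bin_coverage(alignments, bin_size=bin_size, min_mapq=min_mapq)
    return detect_offtargets(bins, window, min_coverage=min_coverage,
                             annotations=annotations)
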