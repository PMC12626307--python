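"""Per-base read-depth extraction from BAM, bedGraph, or in-memory arrays.

All sources expose ``fetch(chrom, start, end) -> np.ndarray`` returning one
integer depth per base of the half-open window.  Coverage is strand-agnostic
by default (unstranded RNA-seq); BAM mode can optionally restrict to
sense-strand alignments for stranded libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class CoverageTrack:
    chrom: str
    start: int
    depths: np.ndarray  # length == end - start, all >= 0

    @property
    def end(self) -> int:
        return self.start + len(self.depths)


class ArrayCoverageSource:
    """Depths held as one integer array per chromosome (simulation output)."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = arrays

    def fetch(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self.arrays[chrom]
        if start >= 0 and end <= len(arr):
            return arr[start:end]
        # window reaches past the contig: zero-fill the overhang
        out = np.zeros(end - start, dtype=arr.dtype)
        s, e = max(start, 0), min(end, len(arr))
        if s < e:
            out[s - start : e - start] = arr[s:e]
        return out

    def chrom_length(self, chrom: str) -> int:
        return len(self.arrays[chrom])


class BedGraphCoverageSource:
    """4-column bedGraph (0-based half-open); absent bases count as depth 0."""

    def __init__(self, path: str):
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#", "browser")):
                    continue
                chrom, s, e, v = line.split()[:4]
                per_chrom.setdefault(chrom, []).append((int(s), int(e), int(round(float(v)))))
        self._ivals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            s, e, v = (np.asarray(x, dtype=np.int64) for x in zip(*rows))
            self._ivals[chrom] = (s, e, v)

    def fetch(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=np.int64)
        if chrom not in self._ivals:
            return out
        starts, ends, vals = self._ivals[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], vals[lo:hi]):
            a, b = max(s, start), min(e, end)
            if a < b:
                out[a - start : b - start] = v
        return out


class BamCoverageSource:
    """Aligned-base depth from a coordinate-sorted, indexed BAM.

    Counts M/=/X bases of mapped, primary (non-secondary, non-supplementary)
    alignments with MAPQ >= ``mapq_min``.  N gaps of spliced alignments do
    not contribute, so intron-spanning reads never inflate intronic depth.
    Duplicates are excluded by default (flag-configurable).
    """

    def __init__(
        self,
        path: str,
        mapq_min: int = 0,
        keep_duplicates: bool = False,
        stranded: str | None = None,
    ):
        import pysam

        self.path = path
        self.mapq_min = mapq_min
        self.keep_duplicates = keep_duplicates
        self.stranded = stranded
        self._af = pysam.AlignmentFile(path, "rb")
        if not self._af.has_index():
            raise ValueError(
                f"{path} has no index; create one with 'samtools index {path}'"
            )

    def _keep(self, read) -> bool:
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_qcfail:
            return False
        if not self.keep_duplicates and read.is_duplicate:
            return False
        if read.mapping_quality < self.mapq_min:
            return False
        if self.stranded == "+" and read.is_reverse:
            return False
        if self.stranded == "-" and not read.is_reverse:
            return False
        return True

    def fetch(self, chrom: str, start: int, end: int) -> np.ndarray:
        ref_len = self._af.get_reference_length(chrom)
        qs, qe = max(0, start), min(end, ref_len)
        if (qs, qe) != (start, end):
            warnings.warn(
                f"window {chrom}:{start}-{end} clipped to contig bounds [0, {ref_len})"
            )
        out = np.zeros(end - start, dtype=np.int64)
        if qs >= qe:
            return out
        a, c, g, t = self._af.count_coverage(
            chrom, qs, qe, quality_threshold=0, read_callback=self._keep
        )
        depth = np.asarray(a) + np.asarray(c) + np.asarray(g) + np.asarray(t)
        out[qs - start : qe - start] = depth
        return out


def open_coverage(path_or_source) -> object:
    """Open a coverage source from a path (BAM by extension, else bedGraph)."""
    if hasattr(path_or_source, "fetch"):
        return path_or_source
    p = str(path_or_source)
    if p.endswith((".bam", ".cram")):
        return BamCoverageSource(p)
    return BedGraphCoverageSource(p)


def fetch_coverage(source, chrom: str, start: int, end: int) -> CoverageTrack:
    if start >= end:
        raise ValueError(f"empty window {chrom}:{start}-{end}")
    return CoverageTrack(chrom=chrom, start=start, depths=np.asarray(source.fetch(chrom, start, end)))


def mean_depth(track: CoverageTrack, sub: tuple[int, int] | None = None) -> float:
    """Arithmetic mean depth over ``sub`` (genomic coords) or the whole track."""
    if sub is None:
        d = track.depths
    else:
        s, e = sub
        if not (track.start <= s and e <= track.end):
            raise ValueError("sub-interval outside the track window")
        d = track.depths[s - track.start : e - track.start]
    if len(d) == 0:
        raise ValueError("mean depth over an empty interval is undefined")
    return float(np.mean(d))


def write_bedgraph(arrays: dict[str, np.ndarray], path: str) -> None:
    """Run-length-encode per-chromosome depth arrays as 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            arr = np.asarray(arrays[chrom])
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
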