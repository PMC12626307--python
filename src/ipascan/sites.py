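"""Candidate IPA-site catalog construction.

Candidate cleavage/polyA positions come from up to three evidence sources —
an annotated polyA-site database (BED), peaks called from 3'-end-seq reads,
and genome scans for polyadenylation-signal (PAS) hexamers — and are
restricted to independent introns.  Nearby sites from different sources are
merged with preference db > peak > pas.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from ._seq import get_sequence, revcomp
from .annotation import GeneModel, IndependentIntron

#: The two canonical PAS hexamers.
DEFAULT_MOTIFS = ("AATAAA", "ATTAAA")

#: Distance (nt, transcript orientation) from PAS motif start to the
#: reported cleavage position; midpoint of the canonical 10-30 nt spacing.
DEFAULT_PAS_OFFSET = 21

_SOURCE_PRIORITY = {"db": 0, "peak": 1, "pas": 2}


class CatalogConfigError(ValueError):
    """No evidence source supplied to build_catalog."""


@dataclass(frozen=True)
class CandidateSite:
    chrom: str
    pos: int  # 0-based cleavage/polyA position
    strand: str
    source: str  # db | peak | pas
    gene_id: str
    intron: IndependentIntron
    hexamer: str | None = None
    name: str | None = None


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    count: int
    strand: str = "."


def pas_variant_motifs() -> tuple[str, ...]:
    """AATAAA, ATTAAA plus the 1-mismatch neighborhood of AATAAA."""
    base = "AATAAA"
    variants = {base, "ATTAAA"}
    for i in range(6):
        for b in "ACGT":
            variants.add(base[:i] + b + base[i + 1 :])
    return tuple(sorted(variants))


def _find_all(seq: str, motif: str) -> list[int]:
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def scan_pas(
    genome,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
    offset: int = DEFAULT_PAS_OFFSET,
    gene_id: str = "",
    intron: IndependentIntron | None = None,
) -> list[CandidateSite]:
    """Scan the sense strand of [start, end) for PAS hexamers.

    The reported position is the motif start plus ``offset`` nt downstream in
    transcript orientation; hits whose projected cleavage position falls
    outside the scanned window are dropped.
    """
    seq = get_sequence(genome, chrom, start, end)
    if strand == "-":
        seq = revcomp(seq)
    out = []
    for motif in motifs:
        for i in _find_all(seq, motif):
            sense_pos = i + offset
            if sense_pos >= len(seq):
                continue
            pos = start + sense_pos if strand == "+" else end - 1 - sense_pos
            out.append(
                CandidateSite(
                    chrom=chrom,
                    pos=pos,
                    strand=strand,
                    source="pas",
                    gene_id=gene_id,
                    intron=intron,
                    hexamer=motif,
                )
            )
    out.sort(key=lambda s: s.pos)
    return out


def call_peaks(
    positions,
    min_reads: int = 5,
    merge_gap: int = 24,
) -> list[Peak]:
    """Single-linkage clustering of 3'-end read positions into peaks.

    ``positions`` is an iterable of ``(chrom, pos)`` or ``(chrom, pos, strand)``
    tuples, one entry per read.  Positions within ``merge_gap`` nt of the
    previous one join its cluster; clusters supported by at least
    ``min_reads`` reads become peaks with the summit at the modal position
    (ties broken leftmost).
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for item in positions:
        chrom, pos = item[0], item[1]
        strand = item[2] if len(item) > 2 else "."
        by_key.setdefault((chrom, strand), []).append(int(pos))
    peaks = []
    for (chrom, strand), pts in by_key.items():
        pts.sort()
        cluster: list[int] = []
        for p in pts + [None]:  # sentinel flushes the last cluster
            if cluster and (p is None or p - cluster[-1] > merge_gap):
                if len(cluster) >= min_reads:
                    counts: dict[int, int] = {}
                    for q in cluster:
                        counts[q] = counts.get(q, 0) + 1
                    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
                    peaks.append(
                        Peak(
                            chrom=chrom,
                            start=cluster[0],
                            end=cluster[-1] + 1,
                            summit=best[0],
                            count=len(cluster),
                            strand=strand,
                        )
                    )
                cluster = []
            if p is not None:
                cluster.append(p)
    peaks.sort(key=lambda pk: (pk.chrom, pk.start))
    return peaks


def threeprime_positions_from_bam(path: str, mapq_min: int = 0):
    """Yield (chrom, pos, strand) of the 3'-most aligned base of each read."""
    import pysam

    with pysam.AlignmentFile(path, "rb") as af:
        for read in af.fetch():
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq_min:
                continue
            if read.is_reverse:
                yield (read.reference_name, read.reference_start, "-")
            else:
                yield (read.reference_name, read.reference_end - 1, "+")


def _intron_index(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for intron in g.independent_introns:
            tree.addi(intron.start, intron.end, (g, intron))
    return trees


def _locate(trees, chrom: str, pos: int, strand: str):
    tree = trees.get(chrom)
    if tree is None:
        return None
    hits = [
        iv.data
        for iv in tree[pos]
        if strand in (".", iv.data[0].strand)
    ]
    if not hits:
        return None
    # deterministic choice if overlapping genes share the strand
    hits.sort(key=lambda gi: (gi[1].end - gi[1].start, gi[0].gene_id))
    return hits[0]


def build_catalog(
    genes: list[GeneModel],
    db_sites=None,
    peaks: list[Peak] | None = None,
    genome=None,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
    pas_offset: int = DEFAULT_PAS_OFFSET,
    dedup_window: int = 50,
    pas_variants: bool = False,
) -> list[CandidateSite]:
    """Union of database, peak, and PAS-scan candidates inside independent introns.

    ``db_sites`` is an iterable of ``(chrom, pos, strand[, name])`` tuples
    (see :func:`read_bed6`).  Sites outside every independent intron are
    dropped.  Within ``dedup_window`` nt on the same strand only the
    highest-priority source (db > peak > pas) is kept.
    """
    if db_sites is None and peaks is None and genome is None:
        raise CatalogConfigError(
            "at least one of db_sites, peaks, or genome must be provided"
        )
    trees = _intron_index(genes)
    raw: list[CandidateSite] = []
    for entry in db_sites or []:
        chrom, pos, strand = entry[0], int(entry[1]), entry[2]
        name = entry[3] if len(entry) > 3 else None
        hit = _locate(trees, chrom, pos, strand)
        if hit is None:
            continue
        g, intron = hit
        raw.append(
            CandidateSite(
                chrom=chrom, pos=pos, strand=g.strand, source="db",
                gene_id=g.gene_id, intron=intron, name=name,
            )
        )
    for pk in peaks or []:
        hit = _locate(trees, pk.chrom, pk.summit, pk.strand)
        if hit is None:
            continue
        g, intron = hit
        raw.append(
            CandidateSite(
                chrom=pk.chrom, pos=pk.summit, strand=g.strand, source="peak",
                gene_id=g.gene_id, intron=intron,
            )
        )
    if genome is not None:
        scan_motifs = pas_variant_motifs() if pas_variants else motifs
        for g in genes:
            for intron in g.independent_introns:
                for s in scan_pas(
                    genome, g.chrom, intron.start, intron.end, g.strand,
                    motifs=scan_motifs, offset=pas_offset,
                    gene_id=g.gene_id, intron=intron,
                ):
                    raw.append(s)
    # dedup per intron: keep by source priority, then position
    by_intron: dict[tuple[str, int, int, str], list[CandidateSite]] = {}
    for s in raw:
        key = (s.chrom, s.intron.start, s.intron.end, s.gene_id)
        by_intron.setdefault(key, []).append(s)
    catalog: list[CandidateSite] = []
    for group in by_intron.values():
        group.sort(key=lambda s: (_SOURCE_PRIORITY[s.source], s.pos))
        kept: list[CandidateSite] = []
        for s in group:
            if any(abs(s.pos - k.pos) <= dedup_window for k in kept):
                continue
            kept.append(s)
        catalog.extend(kept)
    catalog.sort(key=lambda s: (s.chrom, s.pos, s.gene_id))
    return catalog


def read_bed6(path: str) -> list[tuple[str, int, str, str]]:
    """Read a BED file into (chrom, pos, strand, name) tuples.

    Single-base features contribute their start; longer features their
    midpoint.  Missing strand/name columns default to '.'.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            pos = start if end - start <= 1 else (start + end) // 2
            out.append((chrom, pos, strand, name))
    return out


def write_catalog_bed(catalog: list[CandidateSite], path: str) -> None:
    with open(path, "w") as fh:
        for s in catalog:
            name = s.name or f"{s.gene_id}|{s.source}"
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{name}\t0\t{s.strand}\n")
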