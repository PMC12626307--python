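"""Gene-model handling: GTF/refFlat parsing, exon unions and independent introns.

Internally every coordinate is 0-based half-open, the BED convention.  GTF
input (1-based inclusive) is converted on the way in and restored on the way
out.  The central derived structure is the *independent intron*: a maximal
gap between consecutive intervals of a gene's merged exon union, i.e. an
intronic interval that overlaps no exon of any isoform of that gene.  IPA
candidate sites are only considered inside independent introns, which removes
ambiguity from alternative splicing and annotated transcript ends.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field


class AnnotationParseError(ValueError):
    """Raised for malformed annotation lines (message names the line number)."""


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid exon interval [{self.start}, {self.end})")


@dataclass
class Transcript:
    id: str
    exons: list[Exon]
    cds_start: int | None = None
    cds_end: int | None = None

    def sort(self) -> None:
        self.exons.sort(key=lambda e: e.start)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom


@dataclass(frozen=True)
class IndependentIntron:
    """Intronic interval overlapping no exon of any isoform of its gene.

    ``upstream_exon_end`` is the genomic coordinate of the flanking
    exon-union boundary on the transcript-5' side: the intron start for a
    plus-strand gene, the intron end for a minus-strand gene.
    """

    chrom: str
    start: int
    end: int
    strand: str
    upstream_exon_end: int
    gene_id: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]
    exon_union: list[tuple[int, int]] = field(default_factory=list)
    independent_introns: list[IndependentIntron] = field(default_factory=list)

    def finalize(self) -> "GeneModel":
        """Compute exon_union and independent introns from the transcripts."""
        intervals = [(e.start, e.end) for t in self.transcripts for e in t.exons]
        self.exon_union = merge_intervals(intervals)
        self.independent_introns = independent_introns(self)
        return self


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly overlapping half-open intervals into a disjoint sorted list."""
    if not intervals:
        return []
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def independent_introns(g: GeneModel) -> list[IndependentIntron]:
    """Gaps between consecutive exon-union intervals of a gene.

    Every such gap overlaps no exon of any isoform (the union contains all
    exons), and is flanked on both sides by union boundaries, so every gap
    qualifies.  Single-exon genes yield an empty list.
    """
    union = g.exon_union if g.exon_union else merge_intervals(
        [(e.start, e.end) for t in g.transcripts for e in t.exons]
    )
    introns = []
    for (s0, e0), (s1, e1) in zip(union, union[1:]):
        upstream = e0 if g.strand == "+" else s1
        introns.append(
            IndependentIntron(
                chrom=g.chrom,
                start=e0,
                end=s1,
                strand=g.strand,
                upstream_exon_end=upstream,
                gene_id=g.gene_id,
            )
        )
    return introns


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attrs(field8: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field8))


def read_gtf(path: str) -> list[GeneModel]:
    """Read exon and CDS records from a GTF file into GeneModels.

    Requires ``gene_id`` and ``transcript_id`` attributes (RefSeq / Ensembl
    dialects).  1-based inclusive coordinates are converted to 0-based
    half-open.  Malformed lines raise :class:`AnnotationParseError` naming
    the line number.
    """
    tx_exons: dict[tuple[str, str], Transcript] = {}
    tx_meta: dict[tuple[str, str], tuple[str, str]] = {}  # -> (chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            chrom, _src, feature, start, end, _score, strand, frame, attrs = parts[:9]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            a = _parse_gtf_attrs(attrs)
            if "gene_id" not in a or "transcript_id" not in a:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: missing gene_id/transcript_id attribute"
                )
            key = (a["gene_id"], a["transcript_id"])
            tx = tx_exons.setdefault(key, Transcript(id=a["transcript_id"], exons=[]))
            tx_meta.setdefault(key, (chrom, strand))
            if feature == "exon":
                fr = int(frame) if frame in ("0", "1", "2") else None
                tx.exons.append(Exon(chrom=chrom, start=start0, end=end0, frame=fr))
            else:  # CDS: track coding bounds
                tx.cds_start = start0 if tx.cds_start is None else min(tx.cds_start, start0)
                tx.cds_end = end0 if tx.cds_end is None else max(tx.cds_end, end0)
    return _assemble_genes(tx_exons, tx_meta)


def read_refflat(path: str) -> list[GeneModel]:
    """Read UCSC refFlat (11 columns, 0-based half-open coordinates)."""
    tx_exons: dict[tuple[str, str], Transcript] = {}
    tx_meta: dict[tuple[str, str], tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 11:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 11 refFlat columns, got {len(parts)}"
                )
            gene, tx_id, chrom, strand, _txs, _txe, cds_s, cds_e, _n, ex_starts, ex_ends = parts[:11]
            starts = [int(x) for x in ex_starts.rstrip(",").split(",") if x]
            ends = [int(x) for x in ex_ends.rstrip(",").split(",") if x]
            if len(starts) != len(ends):
                raise AnnotationParseError(
                    f"{path}: line {lineno}: exonStarts/exonEnds length mismatch"
                )
            tx = Transcript(
                id=tx_id,
                exons=[Exon(chrom=chrom, start=s, end=e) for s, e in zip(starts, ends)],
            )
            cds_s_i, cds_e_i = int(cds_s), int(cds_e)
            if cds_s_i < cds_e_i:  # refFlat uses cdsStart == cdsEnd for non-coding
                tx.cds_start, tx.cds_end = cds_s_i, cds_e_i
            tx_exons[(gene, tx_id)] = tx
            tx_meta[(gene, tx_id)] = (chrom, strand)
    return _assemble_genes(tx_exons, tx_meta)


def _assemble_genes(
    tx_exons: dict[tuple[str, str], Transcript],
    tx_meta: dict[tuple[str, str], tuple[str, str]],
) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    dropped: set[str] = set()
    for (gene_id, _tx_id), tx in tx_exons.items():
        chrom, strand = tx_meta[(gene_id, _tx_id)]
        if not tx.exons:
            warnings.warn(f"transcript {tx.id} of gene {gene_id} has no exons; skipped")
            continue
        tx.sort()
        g = genes.get(gene_id)
        if g is None:
            genes[gene_id] = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, transcripts=[tx])
        else:
            if g.chrom != chrom or g.strand != strand:
                dropped.add(gene_id)
                continue
            g.transcripts.append(tx)
    for gene_id in dropped:
        warnings.warn(
            f"gene {gene_id} has isoforms on multiple chromosomes or strands; rejected"
        )
        genes.pop(gene_id, None)
    out = [g.finalize() for g in genes.values()]
    out.sort(key=lambda g: (g.chrom, g.exon_union[0][0] if g.exon_union else 0))
    return out


def read_annotation(path: str, format: str | None = None) -> list[GeneModel]:
    """Dispatch to the GTF or refFlat reader; format inferred from extension."""
    if format is None:
        format = "gtf" if str(path).lower().endswith((".gtf", ".gff")) else "refflat"
    if format == "gtf":
        return read_gtf(path)
    if format == "refflat":
        return read_refflat(path)
    raise ValueError(f"unknown annotation format: {format!r}")


def write_gtf(genes: list[GeneModel], path: str, source: str = "ipascan") -> None:
    """Emit exon (and CDS-bound) records; restores 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.id}";'
                for e in t.exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
                if t.cds_start is not None and t.cds_end is not None:
                    for e in t.exons:
                        s = max(e.start, t.cds_start)
                        x = min(e.end, t.cds_end)
                        if s < x:
                            fh.write(
                                f"{g.chrom}\t{source}\tCDS\t{s + 1}\t{x}\t.\t{g.strand}\t.\t{attrs}\n"
                            )
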