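"""Truncated-isoform peptide reconstruction for called IPA events.

Type 1 events extend the annotated reading frame across the exon-intron
junction into the retained intron (the hybrid terminal exon inherits the
upstream CDS frame).  Type 2 events append the cryptic-exon sequence to the
spliced upstream CDS and translate it in all three frames from the cryptic
exon start, since the reading frame of an unannotated internal exon is
unknown.  Translation uses the standard nuclear code and stops before the
first stop codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data import CodonTable

from ._seq import get_sequence, revcomp
from .annotation import GeneModel, Transcript
from .detect import IpaEvent

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)


@dataclass
class PeptideRecord:
    event_id: str
    frame: int  # 0 | 1 | 2
    aa_sequence: str
    novel_tail_start: int | None = None  # aa index where annotated protein ends

    def fasta_header(self) -> str:
        return f"{self.event_id}|frame{self.frame}"


def translate(dna: str, frame: int = 0) -> str:
    """Translate from ``frame`` up to (not including) the first stop codon.

    Incomplete trailing codons are dropped; codons containing N (or any
    non-ACGT character) translate to 'X'.
    """
    if not 0 <= frame <= 2:
        raise ValueError("frame must be 0, 1 or 2")
    dna = dna.upper()
    aas = []
    for i in range(frame, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        if codon in _STOPS:
            break
        aas.append(_FORWARD.get(codon, "X"))
    return "".join(aas)


def _upstream_cds_seq(
    t: Transcript, gene: GeneModel, genome, intron
) -> str:
    """Spliced CDS sequence of exons upstream (transcript 5') of the intron."""
    parts = []
    for e in t.exons:
        s = max(e.start, t.cds_start)
        x = min(e.end, t.cds_end)
        if s >= x:
            continue
        if gene.strand == "+":
            x = min(x, intron.start)
            if s < x:
                parts.append(get_sequence(genome, gene.chrom, s, x))
        else:
            s = max(s, intron.end)
            if s < x:
                parts.append(get_sequence(genome, gene.chrom, s, x))
    if gene.strand == "+":
        return "".join(parts)
    return "".join(revcomp(p) for p in reversed(parts))


def _pick_transcript(gene: GeneModel, genome, intron) -> tuple[Transcript, str] | None:
    best = None
    for t in gene.transcripts:
        if t.cds_start is None or t.cds_end is None:
            continue
        ups = _upstream_cds_seq(t, gene, genome, intron)
        if not ups:
            continue
        if best is None or len(ups) > len(best[1]):
            best = (t, ups)
    return best


def event_peptides(event: IpaEvent, gene: GeneModel, genome) -> list[PeptideRecord]:
    """Peptide records for one called event (1 for Type 1, up to 3 for Type 2)."""
    intron = event.site.intron
    picked = _pick_transcript(gene, genome, intron)
    if picked is None:
        warnings.warn(
            f"gene {gene.gene_id}: no coding transcript upstream of the event; "
            "no peptide emitted"
        )
        return []
    _t, upstream = picked
    event_id = f"{gene.gene_id}|{event.chrom}:{event.pos}|type{event.ipa_type}"
    records: list[PeptideRecord] = []
    if event.ipa_type == 1:
        if gene.strand == "+":
            novel = get_sequence(genome, gene.chrom, intron.start, event.pos + 1)
        else:
            novel = revcomp(get_sequence(genome, gene.chrom, event.pos, intron.end))
        aa = translate(upstream + novel, 0)
        if aa:
            records.append(
                PeptideRecord(
                    event_id=event_id, frame=0, aa_sequence=aa,
                    novel_tail_start=min(len(upstream) // 3, len(aa)),
                )
            )
    else:
        ce0, ce1 = event.cryptic_exon
        ce_seq = get_sequence(genome, gene.chrom, ce0, ce1)
        if gene.strand == "-":
            ce_seq = revcomp(ce_seq)
        prefix = translate(upstream, 0)
        for frame in (0, 1, 2):
            tail = translate(ce_seq, frame)
            aa = prefix + tail
            if aa:
                records.append(
                    PeptideRecord(
                        event_id=event_id, frame=frame, aa_sequence=aa,
                        novel_tail_start=len(prefix),
                    )
                )
    return records


def sample_peptides(
    events: list[IpaEvent], genes: list[GeneModel], genome
) -> list[PeptideRecord]:
    gene_by_id = {g.gene_id: g for g in genes}
    out = []
    for e in events:
        g = gene_by_id.get(e.gene_id)
        if g is not None:
            out.extend(event_peptides(e, g, genome))
    return out


def write_fasta(records: list[PeptideRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.fasta_header()}\n")
            for i in range(0, len(r.aa_sequence), width):
                fh.write(r.aa_sequence[i : i + width] + "\n")


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Minimal FASTA reader used for round-trip checks: (header, sequence)."""
    out: list[tuple[str, str]] = []
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    out.append((header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        out.append((header, "".join(chunks)))
    return out
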