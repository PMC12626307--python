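"""Shared genome-sequence access helpers.

A "genome" is either a plain ``Mapping[str, str]`` of chromosome sequences
(simulation output) or a ``pyfaidx.Fasta`` handle; both are read through
:func:`get_sequence`, which uppercases soft-masked bases.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def get_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) of a chromosome, uppercased; clipping is the caller's job."""
    if start < 0 or start > end:
        raise ValueError(f"invalid region {chrom}:{start}-{end}")
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc
    if isinstance(seq, str):
        if end > len(seq):
            raise ValueError(f"region {chrom}:{start}-{end} beyond chromosome end {len(seq)}")
        return seq[start:end].upper()
    # pyfaidx FastaRecord supports slicing; str() yields the sequence
    if end > len(seq):
        raise ValueError(f"region {chrom}:{start}-{end} beyond chromosome end {len(seq)}")
    return str(seq[start:end]).upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])
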