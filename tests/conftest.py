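import numpy as np
import pytest

from ipascan.annotation import Exon, GeneModel, Transcript
from ipascan.coverage import ArrayCoverageSource
from ipascan.simulate import SimConfig, simulate_sample


def make_gene(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    exon_lists=(((0, 100), (2000, 2100)),),
    cds=None,
):
    """Build a GeneModel from per-transcript exon interval lists."""
    transcripts = []
    for i, exons in enumerate(exon_lists):
        tx = Transcript(
            id=f"{gene_id}.t{i + 1}",
            exons=[Exon(chrom=chrom, start=s, end=e) for s, e in exons],
        )
        if cds is not None:
            tx.cds_start, tx.cds_end = cds
        transcripts.append(tx)
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, transcripts=transcripts
    ).finalize()


def flat_coverage(length, segments, chrom="chr1", dtype=np.int64):
    """ArrayCoverageSource from (start, end, depth) segments on one chromosome."""
    arr = np.zeros(length, dtype=dtype)
    for s, e, d in segments:
        arr[s:e] = d
    return ArrayCoverageSource({chrom: arr})


@pytest.fixture(scope="session")
def small_sample():
    """A small but fully featured simulated sample (40 planted events)."""
    cfg = SimConfig(
        n_genes=120, n_type1=20, n_type2=20, genes_per_chrom=40, seed=7
    )
    return simulate_sample(cfg)
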