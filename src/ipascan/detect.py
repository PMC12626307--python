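"""Single-sample IPA event calling.

For every candidate site inside an independent intron the caller computes
the truncation ratio TR = C2/C1, where C1 is the mean read depth over the
gene's merged exons and C2 the mean depth over the event's intronic
terminal region.  Two event architectures are distinguished:

* Type 1 — splicing of the host intron is inhibited and the transcript is
  polyadenylated inside it: the retained-intron stretch from the upstream
  exon boundary to the site carries coverage that drops sharply past the
  site.
* Type 2 — a cryptic exon inside the intron becomes the new terminal exon:
  a coverage block reaching at least 80% of exonic depth ends at the site,
  separated from the upstream exon by a low-coverage gap.

Type 1 is attempted first; Type 2 only if no Type 1 event is found at the
site.  Events with TR < 0.2 or C2 <= 10 are filtered out, and at most one
event (the highest-TR one) is reported per independent intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel, IndependentIntron
from .sites import CandidateSite


@dataclass
class DetectParams:
    """Tunable thresholds of the caller (defaults are the recommended values)."""

    tr_min: float = 0.2        # minimum truncation ratio
    c2_min: float = 10.0       # minimum mean intronic depth (strict: C2 > c2_min)
    drop_window: int = 100     # nt inspected downstream of a Type 1 site
    drop_frac: float = 0.5     # downstream mean must fall below drop_frac * C2
    contig_frac: float = 0.5   # Type 1 window must start (at the exon junction)
                               # at >= contig_frac * C2 — rejects gapped profiles
    ce_frac: float = 0.8       # cryptic-exon mean depth >= ce_frac * C1
    ce_edge_frac: float = 0.5  # bases below ce_edge_frac * C1 are trimmed off
                               # the block's upstream edge (boundary refinement)
    min_ce_len: int = 50       # cryptic exon length bounds (nt)
    max_ce_len: int = 2000
    min_gap: int = 50          # low-coverage gap separating cryptic exon from
    low_frac: float = 0.2      # the upstream exon: gap mean < low_frac * C1


@dataclass
class IpaEvent:
    site: CandidateSite
    ipa_type: int  # 1 | 2
    c1: float
    c2: float
    tr: float
    gene_id: str
    cryptic_exon: tuple[int, int] | None = None
    c2_region: tuple[int, int] = field(default=None)  # interval C2 was averaged over

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos

    @property
    def strand(self) -> str:
        return self.site.strand


def compute_c1(g: GeneModel, cov) -> float:
    """Mean per-base depth over the gene's exon union (all isoforms merged)."""
    total = 0.0
    nbases = 0
    for s, e in g.exon_union:
        d = cov.fetch(g.chrom, s, e)
        total += float(np.sum(d))
        nbases += e - s
    return total / nbases if nbases else 0.0


def _type1_window(intron: IndependentIntron, pos: int) -> tuple[int, int]:
    """Retained-intron stretch from the upstream exon boundary to the site."""
    if intron.strand == "+":
        return (intron.start, pos)
    return (pos + 1, intron.end)


def detect_type1(
    site: CandidateSite,
    intron: IndependentIntron,
    c1: float,
    cov,
    params: DetectParams = DetectParams(),
) -> IpaEvent | None:
    """Type 1 check at a candidate site; None if any filter fails."""
    w0, w1 = _type1_window(intron, site.pos)
    if w0 >= w1 or c1 <= 0:
        return None
    window = cov.fetch(site.chrom, w0, w1)
    c2 = float(np.mean(window))
    tr = c2 / c1
    if tr < params.tr_min or c2 <= params.c2_min:
        return None
    # the retained intron must be contiguous with the upstream exon: depth at
    # the exon junction comparable to C2 (a gapped profile is a Type 2 shape)
    w = min(params.drop_window, len(window))
    junction = window[:w] if intron.strand == "+" else window[-w:]
    if float(np.mean(junction)) < params.contig_frac * c2:
        return None
    # significant drop downstream of the site
    if intron.strand == "+":
        d0, d1 = site.pos, min(site.pos + params.drop_window, intron.end)
    else:
        d0, d1 = max(site.pos + 1 - params.drop_window, intron.start), site.pos + 1
    if d0 < d1:
        down = float(np.mean(cov.fetch(site.chrom, d0, d1)))
        if down >= params.drop_frac * c2:
            return None
    return IpaEvent(
        site=site, ipa_type=1, c1=c1, c2=c2, tr=tr,
        gene_id=site.gene_id, c2_region=(w0, w1),
    )


def find_cryptic_exon(
    site: CandidateSite,
    intron: IndependentIntron,
    c1: float,
    cov,
    params: DetectParams = DetectParams(),
) -> tuple[int, int] | None:
    """Longest coverage block ending at the site with mean depth >= 0.8 * C1.

    Because a mean over a long block dilutes slowly, the longest qualifying
    suffix can overshoot into the low-coverage gap; low bases
    (< ce_edge_frac * C1) are therefore trimmed off the upstream edge to
    refine the boundary.  The block length must lie within
    [min_ce_len, max_ce_len] and the block must be preceded (transcript
    orientation) by at least ``min_gap`` nt of low coverage
    (< low_frac * C1), so that a high block contiguous with the upstream
    exon — a Type 1 signature — is not mistaken for a cryptic exon.
    """
    if c1 <= 0:
        return None
    if intron.strand == "+":
        arr = cov.fetch(site.chrom, intron.start, site.pos + 1)
        rev = arr[::-1]  # rev[0] is the site base; rev ascends upstream
    else:
        rev = cov.fetch(site.chrom, site.pos, intron.end)
    n = len(rev)
    if n < params.min_ce_len + params.min_gap:
        return None
    csum = np.cumsum(rev, dtype=np.float64)
    lengths = np.arange(1, n + 1)
    means = csum / lengths
    max_l = min(params.max_ce_len, n - params.min_gap)
    ok = (means >= params.ce_frac * c1) & (lengths <= max_l)
    if not np.any(ok):
        return None
    L = int(lengths[np.flatnonzero(ok)[-1]])  # longest qualifying block
    edge = params.ce_edge_frac * c1
    while L > 0 and rev[L - 1] < edge:  # refine the upstream boundary
        L -= 1
    if L < params.min_ce_len:
        return None
    gap = rev[L : L + params.min_gap]
    if len(gap) < params.min_gap or float(np.mean(gap)) >= params.low_frac * c1:
        return None
    if intron.strand == "+":
        return (site.pos + 1 - L, site.pos + 1)
    return (site.pos, site.pos + L)


def detect_type2(
    site: CandidateSite,
    intron: IndependentIntron,
    c1: float,
    cov,
    params: DetectParams = DetectParams(),
) -> IpaEvent | None:
    """Type 2 check: C2 is averaged over the cryptic exon itself."""
    ce = find_cryptic_exon(site, intron, c1, cov, params)
    if ce is None or c1 <= 0:
        return None
    c2 = float(np.mean(cov.fetch(site.chrom, ce[0], ce[1])))
    tr = c2 / c1
    if tr < params.tr_min or c2 <= params.c2_min:
        return None
    return IpaEvent(
        site=site, ipa_type=2, c1=c1, c2=c2, tr=tr,
        gene_id=site.gene_id, cryptic_exon=ce, c2_region=ce,
    )


def detect_sample(
    genes: list[GeneModel],
    catalog: list[CandidateSite],
    cov,
    params: DetectParams = DetectParams(),
) -> list[IpaEvent]:
    """Call IPA events for one sample.

    Per candidate site Type 1 is attempted before Type 2; per independent
    intron only the highest-TR event survives (ties go to the most upstream
    site in transcript orientation).  Unexpressed genes (C1 == 0) are
    skipped.  Events are returned sorted by genomic position.
    """
    by_gene: dict[str, list[CandidateSite]] = {}
    for s in catalog:
        by_gene.setdefault(s.gene_id, []).append(s)
    gene_by_id = {g.gene_id: g for g in genes}
    events: list[IpaEvent] = []
    for gene_id, sites in by_gene.items():
        g = gene_by_id.get(gene_id)
        if g is None:
            continue
        c1 = compute_c1(g, cov)
        if c1 <= 0:
            continue
        by_intron: dict[tuple[int, int], list[CandidateSite]] = {}
        for s in sites:
            by_intron.setdefault((s.intron.start, s.intron.end), []).append(s)
        for site_group in by_intron.values():
            candidates: list[IpaEvent] = []
            for s in site_group:
                ev = detect_type1(s, s.intron, c1, cov, params)
                if ev is None:
                    ev = detect_type2(s, s.intron, c1, cov, params)
                if ev is not None:
                    candidates.append(ev)
            if not candidates:
                continue
            upstream_key = (
                (lambda e: e.pos) if g.strand == "+" else (lambda e: -e.pos)
            )
            candidates.sort(key=lambda e: (-e.tr, upstream_key(e)))
            events.append(candidates[0])
    events.sort(key=lambda e: (e.chrom, e.pos, e.gene_id))
    return events


def events_to_table(events: list[IpaEvent]):
    """Events as a DataFrame with the standard output columns."""
    import pandas as pd

    rows = []
    for e in events:
        ce = e.cryptic_exon
        rows.append(
            {
                "gene_id": e.gene_id,
                "chrom": e.chrom,
                "strand": e.strand,
                "ipa_pos": e.pos,
                "type": e.ipa_type,
                "C1": round(e.c1, 4),
                "C2": round(e.c2, 4),
                "TR": round(e.tr, 6),
                "cryptic_start": ce[0] if ce else "",
                "cryptic_end": ce[1] if ce else "",
                "source": e.site.source,
            }
        )
    cols = [
        "gene_id", "chrom", "strand", "ipa_pos", "type", "C1", "C2", "TR",
        "cryptic_start", "cryptic_end", "source",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_events_tsv(events: list[IpaEvent], path: str) -> None:
    events_to_table(events).to_csv(path, sep="\t", index=False)


def write_events_bed(events: list[IpaEvent], path: str) -> None:
    with open(path, "w") as fh:
        for e in events:
            score = int(round(1000 * min(e.tr, 1.0)))
            fh.write(
                f"{e.chrom}\t{e.pos}\t{e.pos + 1}\t{e.gene_id}|type{e.ipa_type}\t{score}\t{e.strand}\n"
            )
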