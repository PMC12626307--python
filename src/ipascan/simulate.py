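"""Synthetic benchmark generator: genomes, annotations, coverage and truth.

The generator emulates the statistical structure of a short-read RNA-seq
experiment with planted IPA events, working directly at the level of
per-base coverage (read-level BAM synthesis is available for end-to-end
checks).  Per gene, an expression level lambda is drawn from a Gamma
mixture and exonic per-base depth is Poisson(lambda); IPA events are
planted only in highly expressed genes (top expression quantile).  A Type 1
event elevates the intron from the upstream exon boundary to the site to
Poisson(TR * lambda); a Type 2 event plants a cryptic block of depth
Poisson(TR * lambda) ending at the site, flanked by background.  A canonical
AATAAA hexamer is written into the genome 21 nt upstream of every planted
site so that sequence-based candidate scanning can recover it.  Unused decoy
candidate sites in non-event genes are emitted as negatives.

The default single-sample benchmark — 1,000 events (500 per type) among
2,000 genes at ~50x mean exonic depth with planted TR in [0.3, 0.9] —
represents a 50M-read experiment; lower sequencing depths are emulated by
scaling the mean depth (5x for a 5M-read equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import Exon, GeneModel, IndependentIntron, Transcript, write_gtf
from .coverage import ArrayCoverageSource, write_bedgraph

PAS_MOTIF = "AATAAA"
PAS_OFFSET = 21


@dataclass(frozen=True)
class DifferentialSpec:
    """Paired case/control benchmark layout (all differential events Type 1)."""

    n_diff: int = 1000
    n_null: int = 1000
    n_replicates: int = 3
    tr_low: tuple[float, float] = (0.25, 0.40)   # smaller per-condition TR
    tr_delta: tuple[float, float] = (0.25, 0.40)  # planted |TR1 - TR2|, > 0.2


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    n_type1: int = 500
    n_type2: int = 500
    mean_depth: float = 50.0            # mean exonic depth (~50x == 50M reads)
    tr_range: tuple[float, float] = (0.3, 0.9)    # planted Type 1 TR
    tr2_range: tuple[float, float] = (0.85, 1.0)  # planted Type 2 TR (block
                                                  # must clear the 80% boundary rule)
    bg_frac: float = 0.02               # background intronic depth fraction
    top_frac: float = 0.5               # events go to this top expression quantile
    dispersion: float = 3.0             # Gamma shape of the expression mixture
    exon_count: tuple[int, int] = (3, 5)
    exon_len: tuple[int, int] = (150, 300)
    intron_len: tuple[int, int] = (900, 1800)
    intergenic: int = 500
    genes_per_chrom: int = 250
    read_len: int = 50
    seed: int = 0
    n_decoys: int | None = None         # default: one per event, in non-event genes
    noiseless: bool = False             # deterministic depths (round(lambda))
    with_genome: bool = True
    differential: DifferentialSpec | None = None


@dataclass
class TruthEvent:
    gene_id: str
    chrom: str
    strand: str
    pos: int
    ipa_type: int
    tr: float                      # planted TR (condition 1 for paired designs)
    c2_region: tuple[int, int]     # planted elevated interval
    intron: tuple[int, int]
    tr_case: float | None = None   # second-condition TR for paired designs
    is_differential: bool = False


@dataclass
class DecoySite:
    gene_id: str
    chrom: str
    strand: str
    pos: int
    intron: tuple[int, int]


@dataclass
class SimSample:
    config: SimConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    coverage: ArrayCoverageSource
    truth: list[TruthEvent]
    decoys: list[DecoySite]
    lam: np.ndarray
    genome: dict[str, str] | None = None

    def site_entries(self) -> list[tuple[str, int, str, str]]:
        """Truth + decoy positions as database-style BED entries."""
        entries = [
            (t.chrom, t.pos, t.strand, f"truth|{t.gene_id}") for t in self.truth
        ] + [
            (d.chrom, d.pos, d.strand, f"decoy|{d.gene_id}") for d in self.decoys
        ]
        entries.sort(key=lambda x: (x[0], x[1]))
        return entries


@dataclass
class SimPair:
    config: SimConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    truth: list[TruthEvent]
    decoys: list[DecoySite]
    control: list[ArrayCoverageSource]
    case: list[ArrayCoverageSource]
    lam: np.ndarray
    genome: dict[str, str] | None = None

    def site_entries(self) -> list[tuple[str, int, str, str]]:
        entries = [
            (t.chrom, t.pos, t.strand, f"truth|{t.gene_id}") for t in self.truth
        ] + [
            (d.chrom, d.pos, d.strand, f"decoy|{d.gene_id}") for d in self.decoys
        ]
        entries.sort(key=lambda x: (x[0], x[1]))
        return entries


# ---------------------------------------------------------------- layout


def _make_layout(cfg: SimConfig, rng) -> tuple[list[GeneModel], dict[str, int]]:
    genes: list[GeneModel] = []
    cursors: dict[str, int] = {}
    for i in range(cfg.n_genes):
        chrom = f"chr{i // cfg.genes_per_chrom + 1}"
        cursor = cursors.get(chrom, cfg.intergenic)
        n_ex = int(rng.integers(cfg.exon_count[0], cfg.exon_count[1] + 1))
        ex_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, n_ex)
        in_lens = rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1, max(n_ex - 1, 0))
        strand = "+" if rng.random() < 0.5 else "-"
        exons, pos = [], cursor
        for j in range(n_ex):
            exons.append(Exon(chrom=chrom, start=pos, end=pos + int(ex_lens[j])))
            pos += int(ex_lens[j])
            if j < n_ex - 1:
                pos += int(in_lens[j])
        gid = f"g{i:05d}"
        tx = Transcript(
            id=f"{gid}.t1",
            exons=exons,
            cds_start=exons[0].start + 3,
            cds_end=exons[-1].end - 3,
        )
        genes.append(GeneModel(gene_id=gid, chrom=chrom, strand=strand, transcripts=[tx]).finalize())
        cursors[chrom] = pos + cfg.intergenic
    chrom_sizes = {c: cur + cfg.intergenic for c, cur in cursors.items()}
    return genes, chrom_sizes


def _draw_lambda(cfg: SimConfig, rng) -> np.ndarray:
    if cfg.noiseless:
        return np.full(cfg.n_genes, cfg.mean_depth, dtype=float)
    return rng.gamma(cfg.dispersion, cfg.mean_depth / cfg.dispersion, cfg.n_genes)


def _eligible_genes(lam: np.ndarray, top_frac: float) -> np.ndarray:
    cutoff = np.quantile(lam, 1.0 - top_frac)
    return np.flatnonzero(lam >= cutoff)


def _plant_type1(gene: GeneModel, intron: IndependentIntron, rng):
    ilen = len(intron)
    u = int(rng.integers(200, ilen - 250))
    if gene.strand == "+":
        pos = intron.start + u
        region = (intron.start, pos)
    else:
        pos = intron.end - 1 - u
        region = (pos + 1, intron.end)
    return pos, region


def _plant_type2(gene: GeneModel, intron: IndependentIntron, rng):
    ilen = len(intron)
    blen = int(rng.integers(100, 251))
    gap = int(rng.integers(150, ilen - blen - 200))
    if gene.strand == "+":
        block = (intron.start + gap, intron.start + gap + blen)
        pos = block[1] - 1
    else:
        block = (intron.end - gap - blen, intron.end - gap)
        pos = block[0]
    return pos, block


def _pick_intron(gene: GeneModel, rng) -> IndependentIntron:
    introns = gene.independent_introns
    return introns[int(rng.integers(len(introns)))]


def _plan_decoys(cfg: SimConfig, genes, event_idx: set[int], n_decoys: int, rng):
    pool = sorted(set(range(cfg.n_genes)) - event_idx)
    if n_decoys > len(pool):
        raise ValueError("not enough non-event genes to host the requested decoys")
    chosen = rng.choice(pool, size=n_decoys, replace=False)
    decoys = []
    for gi in sorted(int(x) for x in chosen):
        g = genes[gi]
        intron = _pick_intron(g, rng)
        u = int(rng.integers(200, len(intron) - 200))
        pos = intron.start + u if g.strand == "+" else intron.end - 1 - u
        decoys.append(
            DecoySite(
                gene_id=g.gene_id, chrom=g.chrom, strand=g.strand, pos=pos,
                intron=(intron.start, intron.end),
            )
        )
    return decoys


# ---------------------------------------------------------------- coverage


def _render_coverage(
    cfg: SimConfig,
    genes: list[GeneModel],
    lam: np.ndarray,
    overlays: list[tuple[str, tuple[int, int], float]],
    chrom_sizes: dict[str, int],
    rng,
) -> ArrayCoverageSource:
    arrays = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_sizes.items()}

    def draw(mean: float, size: int) -> np.ndarray:
        if cfg.noiseless:
            return np.full(size, int(round(mean)), dtype=np.int32)
        return rng.poisson(mean, size).astype(np.int32)

    for g, lv in zip(genes, lam):
        arr = arrays[g.chrom]
        for s, e in g.exon_union:
            arr[s:e] = draw(lv, e - s)
        for intron in g.independent_introns:
            arr[intron.start : intron.end] = draw(cfg.bg_frac * lv, len(intron))
    for chrom, (s, e), depth in overlays:
        arrays[chrom][s:e] = draw(depth, e - s)
    return ArrayCoverageSource(arrays)


# ---------------------------------------------------------------- genome


def _make_genome(
    cfg: SimConfig,
    chrom_sizes: dict[str, int],
    sites: list[tuple[str, int, str]],
    rng,
) -> dict[str, str]:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms: dict[str, bytearray] = {}
    for chrom in sorted(chrom_sizes):
        raw = lut[rng.integers(0, 4, chrom_sizes[chrom])]
        chroms[chrom] = bytearray(raw.tobytes())
    fwd = PAS_MOTIF.encode()
    rev = PAS_MOTIF.encode().translate(bytes.maketrans(b"ACGT", b"TGCA"))[::-1]
    for chrom, pos, strand in sites:
        buf = chroms[chrom]
        if strand == "+":
            buf[pos - PAS_OFFSET : pos - PAS_OFFSET + 6] = fwd
        else:
            buf[pos + PAS_OFFSET - 5 : pos + PAS_OFFSET + 1] = rev
    return {c: b.decode("ascii") for c, b in chroms.items()}


# ---------------------------------------------------------------- entry points


def simulate_sample(cfg: SimConfig) -> SimSample:
    """Generate one sample with planted Type 1 / Type 2 events and truth."""
    n_events = cfg.n_type1 + cfg.n_type2
    if n_events > cfg.n_genes:
        raise ValueError("more events requested than genes available")
    rng = np.random.default_rng(cfg.seed)
    genes, chrom_sizes = _make_layout(cfg, rng)
    lam = _draw_lambda(cfg, rng)
    eligible = _eligible_genes(lam, cfg.top_frac)
    if n_events > len(eligible):
        raise ValueError(
            f"{n_events} events requested but only {len(eligible)} genes fall in "
            f"the top {cfg.top_frac:.0%} expression quantile"
        )
    chosen = rng.choice(eligible, size=n_events, replace=False)
    types = np.array([1] * cfg.n_type1 + [2] * cfg.n_type2)
    rng.shuffle(types)
    truth: list[TruthEvent] = []
    overlays: list[tuple[str, tuple[int, int], float]] = []
    for gi, ipa_type in zip((int(x) for x in chosen), types):
        g = genes[gi]
        intron = _pick_intron(g, rng)
        if ipa_type == 1:
            pos, region = _plant_type1(g, intron, rng)
            tr = float(rng.uniform(*cfg.tr_range))
        else:
            pos, region = _plant_type2(g, intron, rng)
            tr = float(rng.uniform(*cfg.tr2_range))
        truth.append(
            TruthEvent(
                gene_id=g.gene_id, chrom=g.chrom, strand=g.strand, pos=pos,
                ipa_type=int(ipa_type), tr=tr, c2_region=region,
                intron=(intron.start, intron.end),
            )
        )
        overlays.append((g.chrom, region, tr * lam[gi]))
    n_decoys = cfg.n_decoys if cfg.n_decoys is not None else n_events
    n_decoys = min(n_decoys, cfg.n_genes - n_events)
    decoys = _plan_decoys(cfg, genes, {int(x) for x in chosen}, n_decoys, rng)
    cov = _render_coverage(cfg, genes, lam, overlays, chrom_sizes, rng)
    genome = None
    if cfg.with_genome:
        planted = [(t.chrom, t.pos, t.strand) for t in truth] + [
            (d.chrom, d.pos, d.strand) for d in decoys
        ]
        genome = _make_genome(cfg, chrom_sizes, planted, rng)
    truth.sort(key=lambda t: (t.chrom, t.pos))
    return SimSample(
        config=cfg, genes=genes, chrom_sizes=chrom_sizes, coverage=cov,
        truth=truth, decoys=decoys, lam=lam, genome=genome,
    )


def simulate_pair(cfg: SimConfig) -> SimPair:
    """Generate paired case/control samples with replicates and differential truth."""
    spec = cfg.differential
    if spec is None:
        raise ValueError("cfg.differential must be set for simulate_pair")
    n_events = spec.n_diff + spec.n_null
    rng = np.random.default_rng(cfg.seed)
    genes, chrom_sizes = _make_layout(cfg, rng)
    lam = _draw_lambda(cfg, rng)
    eligible = _eligible_genes(lam, cfg.top_frac)
    if n_events > len(eligible):
        raise ValueError(
            f"{n_events} events requested but only {len(eligible)} eligible genes"
        )
    chosen = rng.choice(eligible, size=n_events, replace=False)
    truth: list[TruthEvent] = []
    ov_control: list[tuple[str, tuple[int, int], float]] = []
    ov_case: list[tuple[str, tuple[int, int], float]] = []
    for k, gi in enumerate(int(x) for x in chosen):
        g = genes[gi]
        intron = _pick_intron(g, rng)
        pos, region = _plant_type1(g, intron, rng)
        if k < spec.n_diff:
            lo = float(rng.uniform(*spec.tr_low))
            hi = lo + float(rng.uniform(*spec.tr_delta))
            tr_ctrl, tr_case = (lo, hi) if rng.random() < 0.5 else (hi, lo)
            is_diff = True
        else:
            tr_ctrl = tr_case = float(rng.uniform(0.3, 0.6))
            is_diff = False
        truth.append(
            TruthEvent(
                gene_id=g.gene_id, chrom=g.chrom, strand=g.strand, pos=pos,
                ipa_type=1, tr=tr_ctrl, tr_case=tr_case, c2_region=region,
                intron=(intron.start, intron.end), is_differential=is_diff,
            )
        )
        ov_control.append((g.chrom, region, tr_ctrl * lam[gi]))
        ov_case.append((g.chrom, region, tr_case * lam[gi]))
    n_decoys = cfg.n_decoys if cfg.n_decoys is not None else spec.n_diff
    n_decoys = min(n_decoys, cfg.n_genes - n_events)
    decoys = _plan_decoys(cfg, genes, {int(x) for x in chosen}, n_decoys, rng)
    control, case = [], []
    for overlays, bucket in ((ov_control, control), (ov_case, case)):
        for _rep in range(spec.n_replicates):
            child = np.random.default_rng(int(rng.integers(2**31)))
            bucket.append(_render_coverage(cfg, genes, lam, overlays, chrom_sizes, child))
    genome = None
    if cfg.with_genome:
        planted = [(t.chrom, t.pos, t.strand) for t in truth] + [
            (d.chrom, d.pos, d.strand) for d in decoys
        ]
        genome = _make_genome(cfg, chrom_sizes, planted, rng)
    truth.sort(key=lambda t: (t.chrom, t.pos))
    return SimPair(
        config=cfg, genes=genes, chrom_sizes=chrom_sizes, truth=truth,
        decoys=decoys, control=control, case=case, lam=lam, genome=genome,
    )


# ---------------------------------------------------------------- writers


def write_truth_tsv(truth: list[TruthEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tchrom\tstrand\tpos\ttype\ttr\ttr_case\tis_differential\t"
            "region_start\tregion_end\n"
        )
        for t in truth:
            tc = "" if t.tr_case is None else f"{t.tr_case:.4f}"
            fh.write(
                f"{t.gene_id}\t{t.chrom}\t{t.strand}\t{t.pos}\t{t.ipa_type}\t"
                f"{t.tr:.4f}\t{tc}\t{int(t.is_differential)}\t"
                f"{t.c2_region[0]}\t{t.c2_region[1]}\n"
            )


def read_truth_tsv(path: str) -> list[TruthEvent]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("gene_id")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                TruthEvent(
                    gene_id=f[0], chrom=f[1], strand=f[2], pos=int(f[3]),
                    ipa_type=int(f[4]), tr=float(f[5]),
                    tr_case=float(f[6]) if f[6] else None,
                    is_differential=bool(int(f[7])),
                    c2_region=(int(f[8]), int(f[9])),
                    intron=(int(f[8]), int(f[9])),
                )
            )
    return out


def write_genome_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sites_bed(entries: list[tuple[str, int, str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand, name in entries:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{name}\t0\t{strand}\n")


def write_sample(sample: SimSample, outdir: str) -> dict[str, str]:
    """Write FASTA/GTF/bedGraph/BED/truth for a simulated sample; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gtf": os.path.join(outdir, "annotation.gtf"),
        "bedgraph": os.path.join(outdir, "coverage.bedgraph"),
        "sites": os.path.join(outdir, "sites.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_gtf(sample.genes, paths["gtf"])
    write_bedgraph(sample.coverage.arrays, paths["bedgraph"])
    write_sites_bed(sample.site_entries(), paths["sites"])
    write_truth_tsv(sample.truth, paths["truth"])
    if sample.genome is not None:
        paths["fasta"] = os.path.join(outdir, "genome.fa")
        write_genome_fasta(sample.genome, paths["fasta"])
    return paths


# ---------------------------------------------------------------- read-level mode


def depth_to_intervals(arr: np.ndarray) -> list[tuple[int, int]]:
    """Decompose a depth profile into intervals whose pileup reproduces it exactly."""
    out: list[tuple[int, int]] = []
    stack: list[int] = []
    prev = 0
    for i, d in enumerate(int(x) for x in arr):
        if d > prev:
            stack.extend([i] * (d - prev))
        elif d < prev:
            for _ in range(prev - d):
                out.append((stack.pop(), i))
        prev = d
    for s in stack:
        out.append((s, len(arr)))
    return out


def write_bam(arrays: dict[str, np.ndarray], path: str, index: bool = True) -> None:
    """Synthesize a coordinate-sorted BAM whose pileup matches ``arrays``.

    Reads are coverage-preserving fragments (variable length), not
    fixed-length sequencer reads; they exist to exercise BAM-input code
    paths end to end.
    """
    import pysam

    chroms = sorted(arrays)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(len(arrays[c]))} for c in chroms],
    }
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for tid, chrom in enumerate(chroms):
            ivals = sorted(depth_to_intervals(np.asarray(arrays[chrom])))
            for k, (s, e) in enumerate(ivals):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"{chrom}_{k}"
                a.flag = 0
                a.reference_id = tid
                a.reference_start = s
                a.mapping_quality = 60
                a.cigartuples = [(0, e - s)]
                a.query_sequence = "A" * (e - s)
                bam.write(a)
    if index:
        pysam.index(path)


def scaled_config(cfg: SimConfig, depth_factor: float) -> SimConfig:
    """Same layout/truth seed, exonic depth scaled (e.g. 0.1 for 5M vs 50M)."""
    return replace(cfg, mean_depth=cfg.mean_depth * depth_factor)
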