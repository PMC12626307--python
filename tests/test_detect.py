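import numpy as np
import pytest

from ipascan.coverage import ArrayCoverageSource
from ipascan.detect import (
    DetectParams,
    compute_c1,
    detect_sample,
    detect_type1,
    detect_type2,
    find_cryptic_exon,
)
from ipascan.sites import CandidateSite, build_catalog
from ipascan.simulate import SimConfig, simulate_sample

from conftest import flat_coverage, make_gene

PARAMS = DetectParams()


def site_at(gene, pos, source="db"):
    intron = next(
        i for i in gene.independent_introns if i.start <= pos < i.end
    )
    return CandidateSite(
        chrom=gene.chrom, pos=pos, strand=gene.strand, source=source,
        gene_id=gene.gene_id, intron=intron,
    )


class TestComputeC1:
    def test_two_exon_mean(self):
        g = make_gene(exon_lists=(((0, 10), (20, 30)),))
        cov = flat_coverage(40, [(0, 10, 10), (20, 30, 20)])
        assert compute_c1(g, cov) == 15.0

    def test_zero_coverage(self):
        g = make_gene(exon_lists=(((0, 10), (20, 30)),))
        assert compute_c1(g, flat_coverage(40, [])) == 0.0

    def test_uniform_depth(self):
        g = make_gene(exon_lists=(((5, 25),),))
        assert compute_c1(g, flat_coverage(30, [(5, 25, 7)])) == 7.0


class TestType1:
    def setup_method(self):
        # exons [0,100) and [2000,2100); independent intron [100,2000)
        self.gene = make_gene()

    def _cov(self, exon_depth, intron_depth, site, tail_depth=2):
        return flat_coverage(
            2100,
            [
                (0, 100, exon_depth), (2000, 2100, exon_depth),
                (100, site, intron_depth), (site, 2000, tail_depth),
            ],
        )

    def test_event_emitted_with_expected_tr(self):
        cov = self._cov(100, 40, 700)
        ev = detect_type1(site_at(self.gene, 700), self.gene.independent_introns[0], 100.0, cov)
        assert ev is not None and ev.ipa_type == 1
        assert ev.tr == pytest.approx(0.4) and ev.c2 == pytest.approx(40.0)
        assert ev.tr == pytest.approx(ev.c2 / ev.c1, abs=1e-9)

    def test_tr_below_threshold_filtered(self):
        cov = self._cov(100, 15, 700)
        assert detect_type1(site_at(self.gene, 700), self.gene.independent_introns[0], 100.0, cov) is None

    def test_low_c2_filtered_regardless_of_tr(self):
        cov = self._cov(20, 8, 700, tail_depth=0)
        # TR = 0.4 but C2 = 8 <= 10
        assert detect_type1(site_at(self.gene, 700), self.gene.independent_introns[0], 20.0, cov) is None

    def test_no_downstream_drop_rejected(self):
        # uniformly retained intron: no polyA signature
        cov = self._cov(100, 40, 700, tail_depth=40)
        assert detect_type1(site_at(self.gene, 700), self.gene.independent_introns[0], 100.0, cov) is None

    def test_gapped_profile_rejected(self):
        # coverage absent at the exon-intron junction: Type 2 shape, not Type 1
        cov = flat_coverage(
            2100,
            [(0, 100, 100), (2000, 2100, 100), (500, 700, 40)],
        )
        assert detect_type1(site_at(self.gene, 699), self.gene.independent_introns[0], 100.0, cov) is None

    def test_minus_strand_mirror(self):
        gene = make_gene(strand="-")
        cov = flat_coverage(
            2100,
            [(0, 100, 100), (2000, 2100, 100), (1300, 2000, 40), (100, 1300, 2)],
        )
        ev = detect_type1(site_at(gene, 1299), gene.independent_introns[0], 100.0, cov)
        assert ev is not None and ev.tr == pytest.approx(0.4)


class TestCrypticExon:
    def setup_method(self):
        self.gene = make_gene()
        self.intron = self.gene.independent_introns[0]

    def test_step_profile_recovers_block_against_sliding_oracle(self):
        # intron depth 1 for 300 nt, then 90 for 200 nt ending at the site
        cov = flat_coverage(
            2100, [(0, 100, 100), (2000, 2100, 100), (100, 400, 1), (400, 600, 90)]
        )
        site = site_at(self.gene, 599)
        ce = find_cryptic_exon(site, self.intron, 100.0, cov)
        assert ce == (400, 600)
        # oracle: earliest start whose suffix mean clears 0.8*c1, advanced
        # past any low edge bases, subject to length and gap rules
        arr = cov.fetch("chr1", self.intron.start, 600)
        start = next(
            s for s in range(len(arr))
            if arr[s:].mean() >= 0.8 * 100 and len(arr) - s <= PARAMS.max_ce_len
        )
        while arr[start] < PARAMS.ce_edge_frac * 100:
            start += 1
        assert len(arr) - start >= PARAMS.min_ce_len
        assert start >= PARAMS.min_gap
        assert arr[start - PARAMS.min_gap : start].mean() < 0.2 * 100
        assert ce == (self.intron.start + start, 600)

    def test_uniform_half_coverage_never_reaches_boundary(self):
        cov = flat_coverage(2100, [(0, 100, 100), (2000, 2100, 100), (100, 2000, 50)])
        assert find_cryptic_exon(site_at(self.gene, 999), self.intron, 100.0, cov) is None

    def test_block_contiguous_with_exon_fails_gap_rule(self):
        cov = flat_coverage(2100, [(0, 100, 100), (2000, 2100, 100), (100, 300, 90)])
        assert find_cryptic_exon(site_at(self.gene, 299), self.intron, 100.0, cov) is None


class TestType2:
    def setup_method(self):
        self.gene = make_gene()
        self.intron = self.gene.independent_introns[0]

    def _cov(self, exon_depth, block_depth):
        return flat_coverage(
            2100,
            [(0, 100, exon_depth), (2000, 2100, exon_depth), (400, 600, block_depth)],
        )

    def test_cryptic_block_event(self):
        ev = detect_type2(site_at(self.gene, 599), self.intron, 100.0, self._cov(100, 90))
        assert ev is not None and ev.ipa_type == 2
        assert ev.cryptic_exon == (400, 600)
        assert ev.tr == pytest.approx(0.9)

    def test_tr_may_exceed_one(self):
        ev = detect_type2(site_at(self.gene, 599), self.intron, 60.0, self._cov(60, 90))
        assert ev is not None and ev.tr == pytest.approx(1.5)

    def test_no_qualifying_block_returns_none(self):
        ev = detect_type2(site_at(self.gene, 599), self.intron, 100.0, self._cov(100, 30))
        assert ev is None


class TestDetectSample:
    def test_type1_takes_precedence_and_one_event_per_intron(self):
        gene = make_gene()
        cov = flat_coverage(
            2100,
            [(0, 100, 100), (2000, 2100, 100), (100, 700, 50), (700, 2000, 1)],
        )
        # the site at 400 fails the downstream-drop check (coverage continues
        # at 50); only the true truncation point at 700 is reported, as Type 1
        sites = [site_at(gene, 400), site_at(gene, 700)]
        events = detect_sample([gene], sites, cov)
        assert len(events) == 1
        assert events[0].pos == 700 and events[0].ipa_type == 1

    def test_highest_tr_site_wins_within_intron(self):
        gene = make_gene()
        # site A at 400 sees mean 50 over [100,400); site B at 1000 sees a
        # diluted window -> lower TR
        cov = flat_coverage(
            2100,
            [(0, 100, 100), (2000, 2100, 100), (100, 400, 50), (400, 1000, 10)],
        )
        events = detect_sample([gene], [site_at(gene, 400), site_at(gene, 1000)], cov)
        assert len(events) == 1 and events[0].pos == 400

    def test_unexpressed_gene_skipped(self):
        gene = make_gene()
        cov = flat_coverage(2100, [(100, 700, 50)])
        assert detect_sample([gene], [site_at(gene, 700)], cov) == []

    def test_gene_without_candidates_yields_nothing(self, small_sample):
        assert detect_sample(small_sample.genes, [], small_sample.coverage) == []

    def test_all_emitted_events_satisfy_filters(self, small_sample):
        catalog = build_catalog(small_sample.genes, db_sites=small_sample.site_entries())
        events = detect_sample(small_sample.genes, catalog, small_sample.coverage)
        assert events
        for e in events:
            assert e.tr >= 0.2 and e.c2 > 10
            assert e.tr == pytest.approx(e.c2 / e.c1, abs=1e-9)
            assert (e.ipa_type == 2) == (e.cryptic_exon is not None)
            if e.cryptic_exon:
                assert e.site.intron.start <= e.cryptic_exon[0] < e.cryptic_exon[1] <= e.site.intron.end
        # precedence: one event per intron at most
        introns = [(e.gene_id, e.site.intron.start) for e in events]
        assert len(introns) == len(set(introns))

    def test_tr_is_scale_invariant(self, small_sample):
        catalog = build_catalog(small_sample.genes, db_sites=small_sample.site_entries())
        base = detect_sample(small_sample.genes, catalog, small_sample.coverage)
        scaled_cov = ArrayCoverageSource(
            {c: a * 3 for c, a in small_sample.coverage.arrays.items()}
        )
        scaled = detect_sample(small_sample.genes, catalog, scaled_cov)
        base_by_key = {(e.gene_id, e.pos): e for e in base}
        for e in scaled:
            b = base_by_key.get((e.gene_id, e.pos))
            if b is not None:
                assert e.tr == pytest.approx(b.tr, rel=1e-9)
                assert e.c2 == pytest.approx(3 * b.c2, rel=1e-9)

    def test_noiseless_simulation_recovers_planted_tr(self):
        cfg = SimConfig(
            n_genes=40, n_type1=8, n_type2=8, genes_per_chrom=20,
            seed=11, noiseless=True, mean_depth=100.0,
        )
        sample = simulate_sample(cfg)
        catalog = build_catalog(sample.genes, db_sites=sample.site_entries())
        events = detect_sample(sample.genes, catalog, sample.coverage)
        truth = {(t.chrom, t.pos): t for t in sample.truth}
        matched = 0
        for e in events:
            t = truth.get((e.chrom, e.pos))
            if t is not None:
                matched += 1
                assert e.tr == pytest.approx(t.tr, abs=0.02)
                assert e.ipa_type == t.ipa_type
        assert matched == len(sample.truth)
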