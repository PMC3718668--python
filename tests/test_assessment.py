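"""WGBS-style calling, specificity/sensitivity, repeatability, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mspjiseq.assessment import (
    MetageneProfile,
    PeakRegion,
    common_peaks,
    density_value_fn,
    fragment_uniqueness,
    mc_fraction_value_fn,
    metagene_profile,
    normalize_gene_methylation,
    read_wgbs_tsv,
    replicate_correlation,
    restrict_calls,
    specificity_sensitivity,
    wgbs_call,
    write_wgbs_tsv,
)
from mspjiseq.caller import LocusIndex, SiteCall
from mspjiseq.genome import Genome, GenomeSequence
from mspjiseq.patterns import CnnrLocus, scan_cnnr_loci

from conftest import random_genome


def wgbs_df(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "methylated_reads", "total_reads"]
    )


class TestWgbsCall:
    def test_fully_methylated_site_called(self):
        df = wgbs_df([("c", 1, "+", 10, 10)])
        # closed-form binomial tail: P(X >= 10 | n=10, p=0.01) = 1e-20
        assert sps.binom.sf(9, 10, 0.01) == pytest.approx(1e-20, rel=1e-6)
        assert wgbs_call(df, 0.01, 0.05) == {("c", 1, "+")}

    def test_unmethylated_site_not_called(self):
        df = wgbs_df([("c", 1, "+", 0, 10)])
        assert wgbs_call(df, 0.01, 0.05, "binomial") == set()
        assert wgbs_call(df, 0.01, 0.05, "any_read") == set()

    def test_any_read_mode_single_supporting_read(self):
        df = wgbs_df([("c", 1, "+", 1, 10)])
        assert wgbs_call(df, 0.01, 0.05, "any_read") == {("c", 1, "+")}

    def test_uncovered_site_untested(self):
        df = wgbs_df([("c", 1, "+", 0, 0), ("c", 2, "+", 8, 8)])
        assert wgbs_call(df) == {("c", 2, "+")}

    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            wgbs_call(wgbs_df([]), error_rate=0.0)

    def test_type_one_error_controlled(self):
        """Null sites called at FDR q stay at or below q (within 3 s.e.)."""
        rng = np.random.default_rng(8)
        n = 10_000
        totals = rng.poisson(10, size=n)
        meth = rng.binomial(totals, 0.01)
        df = wgbs_df([("c", i, "+", int(m), int(t))
                      for i, (m, t) in enumerate(zip(meth, totals))])
        called = wgbs_call(df, error_rate=0.01, fdr=0.05)
        q = 0.05
        assert len(called) / n <= q + 3 * np.sqrt(q * (1 - q) / n)


class TestUniqueness:
    def test_locus_in_random_genome_unique(self):
        g = random_genome(31, length=10_000, gc=0.5)
        loci = [l for l in scan_cnnr_loci(g)
                if l.category == "YNCGNR" and l.strand == "+" and 20 < l.pos < 9000]
        assert loci
        unique, ok = fragment_uniqueness(g, loci[0])
        assert unique and ok

    def test_locus_in_duplicated_block_repeated(self):
        block = random_genome(32, length=1000, gc=0.5)["rand"].seq
        g = Genome([GenomeSequence("c", block + block)])
        loci = [l for l in scan_cnnr_loci(g)
                if l.category == "YNCGNR" and l.strand == "+" and 20 < l.pos < 900]
        assert loci
        unique, ok = fragment_uniqueness(g, loci[0])
        assert not unique and ok

    def test_edge_locus_flagged(self):
        g = Genome([GenomeSequence("c", "TACGTA" + "A" * 60)])
        locus = CnnrLocus("c", 2, "+", "CG", "YNCGNR", 1)
        unique, ok = fragment_uniqueness(g, locus)
        assert not ok and not unique

    def test_minus_locus_uses_partner_window(self):
        g = random_genome(33, length=5000, gc=0.5)
        loci = [l for l in scan_cnnr_loci(g)
                if l.category == "YNCGNR" and 20 < l.pos < 4900]
        plus = next(l for l in loci if l.strand == "+")
        minus = next(l for l in loci if l.strand == "-" and l.pos == plus.pos + 1)
        assert fragment_uniqueness(g, plus) == fragment_uniqueness(g, minus)


class TestSpecificitySensitivity:
    def test_identical_sets(self):
        keys = {("c", 1, "+"), ("c", 5, "-")}
        assert specificity_sensitivity(keys, set(keys)) == (1.0, 1.0)

    def test_subset_recovery(self):
        wgbs = {("c", i, "+") for i in range(10)}
        mspji = {("c", i, "+") for i in range(5)}
        assert specificity_sensitivity(mspji, wgbs) == (1.0, 0.5)

    def test_swap_exchanges_roles(self):
        a = {("c", i, "+") for i in range(8)}
        b = {("c", i, "+") for i in range(4, 16)}
        spec, sens = specificity_sensitivity(a, b)
        spec2, sens2 = specificity_sensitivity(b, a)
        assert (spec, sens) == (sens2, spec2)

    def test_empty_test_set_flagged(self):
        with pytest.warns(UserWarning):
            spec, sens = specificity_sensitivity(set(), {("c", 1, "+")})
        assert spec is None and sens == 0.0

    def test_planted_overlap_construction(self):
        """20% reference-only and 5% test-only sites give (0.95, 0.80)."""
        rng = np.random.default_rng(5)
        shared = {("c", int(p), "+") for p in rng.choice(10**6, 800, replace=False)}
        wgbs = shared | {("c", int(p), "-") for p in rng.choice(10**6, 200, replace=False)}
        extra = {("x", int(p), "+") for p in rng.choice(10**6, 42, replace=False)}
        mspji = shared | extra
        spec, sens = specificity_sensitivity(mspji, wgbs)
        assert spec == pytest.approx(800 / 842, abs=1e-12)
        assert sens == pytest.approx(0.80, abs=1e-12)


class TestPeaks:
    def test_common_peaks_intersection(self):
        a = [PeakRegion("c", 0, 100), PeakRegion("c", 200, 300)]
        b = [PeakRegion("c", 50, 250)]
        common = common_peaks(a, b)
        assert [(p.start, p.end) for p in common] == [(50, 100), (200, 250)]

    def test_no_overlap(self):
        assert common_peaks([PeakRegion("c", 0, 10)], [PeakRegion("c", 20, 30)]) == []

    def test_restrict_calls_filters_category_and_peaks(self):
        g = random_genome(34, length=5000, gc=0.5)
        loci = scan_cnnr_loci(g)
        peaks = [PeakRegion("rand", 1000, 3000)]
        keys = restrict_calls(loci, peaks, g)
        for chrom, pos, strand in keys:
            assert 1000 <= pos < 3000


class TestReplicateCorrelation:
    def _calls(self, g, depths):
        loci = [l for l in scan_cnnr_loci(g) if l.strand == "+"][: len(depths)]
        return [SiteCall(l, d) for l, d in zip(loci, depths)]

    def test_identical_replicates(self):
        g = random_genome(35, length=4000)
        rng = np.random.default_rng(0)
        calls = self._calls(g, rng.integers(1, 30, size=60).tolist())
        peaks = [PeakRegion("rand", s, s + 400) for s in range(0, 4000, 400)]
        assert replicate_correlation(calls, calls, peaks, "depth") == pytest.approx(1.0)
        assert replicate_correlation(calls, calls, peaks, "site_count") == pytest.approx(1.0)

    def test_permuted_replicate_near_zero(self):
        rng = np.random.default_rng(1)
        n_peaks = 1000
        g = Genome([GenomeSequence("c", "A" * 10)])  # loci unused below
        peaks = [PeakRegion("c", i * 10, i * 10 + 10) for i in range(n_peaks)]
        depths = rng.integers(1, 50, size=n_peaks)
        loci = [CnnrLocus("c", i * 10 + 3, "+", "CG") for i in range(n_peaks)]
        rep1 = [SiteCall(l, int(d)) for l, d in zip(loci, depths)]
        perm = rng.permutation(depths)
        rep2 = [SiteCall(l, int(d)) for l, d in zip(loci, perm)]
        r = replicate_correlation(rep1, rep2, peaks, "depth")
        assert abs(r) < 3 / np.sqrt(n_peaks)

    def test_attenuation_by_added_noise(self):
        """r against a noisy copy matches the closed-form attenuation."""
        rng = np.random.default_rng(2)
        n = 2000
        depths = rng.integers(1, 100, size=n).astype(float)
        sigma = depths.std()  # noise as large as the signal -> r ~ 1/sqrt(2)
        noisy = depths + rng.normal(0, sigma, size=n)
        expected = 1 / np.sqrt(2)
        r = np.corrcoef(depths, noisy)[0, 1]
        assert abs(r - expected) < 3 * (1 - expected**2) / np.sqrt(n)

    def test_too_few_peaks(self):
        with pytest.raises(ValueError):
            replicate_correlation([], [], [PeakRegion("c", 0, 10)])

    def test_zero_variance_flagged(self):
        peaks = [PeakRegion("c", i * 10, i * 10 + 10) for i in range(5)]
        with pytest.warns(UserWarning):
            r = replicate_correlation([], [], peaks)
        assert np.isnan(r)


def _uniform_calls(length, step, depth=2, chrom="c"):
    return [
        SiteCall(CnnrLocus(chrom, p, "+", "CG"), depth)
        for p in range(3, length - 3, step)
    ]


class TestMetagene:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])

    def test_uniform_methylation_flat_profile(self):
        calls = _uniform_calls(20_000, 10)
        genes = self._genes([("c", 2000, 4000, "+", "g1"), ("c", 6000, 9000, "+", "g2")])
        prof = metagene_profile(genes, density_value_fn(calls), {"c": 20_000})
        assert prof.body_bins == pytest.approx([prof.body_bins[0]] * 20, rel=0.02)
        assert prof.upstream == pytest.approx([prof.upstream[0]] * 10, rel=0.02)

    def test_minus_strand_gene_mirrors_plus(self):
        rng = np.random.default_rng(3)
        positions = sorted(rng.choice(range(3, 9990), size=600, replace=False))
        calls = [SiteCall(CnnrLocus("c", int(p), "+", "CG"), 1) for p in positions]
        fn = density_value_fn(calls)
        plus = metagene_profile(
            self._genes([("c", 3000, 5000, "+", "g")]), fn, {"c": 10_000}
        )
        minus = metagene_profile(
            self._genes([("c", 3000, 5000, "-", "g")]), fn, {"c": 10_000}
        )
        assert minus.body_bins == pytest.approx(plus.body_bins[::-1])
        assert minus.upstream == pytest.approx(plus.downstream[::-1])

    def test_planted_tss_tts_depletion_recovered(self):
        """Calls removed near gene ends reappear as dips at bins 1 and 20."""
        genes = self._genes([("c", s, s + 2000, "+", f"g{s}")
                             for s in range(2000, 38_000, 4000)])
        calls = []
        for p in range(3, 40_000 - 3, 8):
            near_edge = any(
                abs(p - r.start) < 200 or abs(p - r.end) < 200
                for r in genes.itertuples()
            )
            if not near_edge:
                calls.append(SiteCall(CnnrLocus("c", p, "+", "CG"), 1))
        prof = metagene_profile(genes, density_value_fn(calls), {"c": 40_000})
        mid = np.mean(prof.body_bins[8:12])
        assert prof.body_bins[0] < 0.5 * mid
        assert prof.body_bins[-1] < 0.5 * mid

    def test_translation_invariance(self):
        shift = 1234
        calls = _uniform_calls(30_000, 7)
        shifted = [SiteCall(CnnrLocus("c", c.locus.pos + shift, "+", "CG"), c.depth)
                   for c in calls]
        genes = self._genes([("c", 5000, 8000, "+", "g")])
        genes2 = self._genes([("c", 5000 + shift, 8000 + shift, "+", "g")])
        p1 = metagene_profile(genes, density_value_fn(calls), {"c": 40_000})
        p2 = metagene_profile(genes2, density_value_fn(shifted), {"c": 40_000})
        assert p1.body_bins == pytest.approx(p2.body_bins)
        assert p1.upstream == pytest.approx(p2.upstream)

    def test_short_region_skipped(self):
        genes = self._genes([("c", 0, 10, "+", "tiny"), ("c", 100, 2100, "+", "ok")])
        with pytest.warns(UserWarning):
            prof = metagene_profile(genes, density_value_fn([]), {"c": 5000})
        assert prof.n_regions == 1

    def test_mc_fraction_value_fn(self):
        g = random_genome(36, length=2000)
        loci = scan_cnnr_loci(g)
        idx = LocusIndex(loci)
        called = [SiteCall(l, 1) for l in loci[: len(loci) // 2]]
        fn = mc_fraction_value_fn(called, idx)
        v = fn("rand", 0, 2000)
        assert v == pytest.approx(len(called) / len(loci))


class TestNormalizeGenes:
    def test_average_gene_is_one_and_cold_gene_zero(self):
        calls = _uniform_calls(20_000, 10)
        # remove all calls inside the cold gene
        calls = [c for c in calls if not 6000 <= c.locus.pos < 8000]
        genes = pd.DataFrame(
            [("c", 2000, 4000, "+", "warm"), ("c", 6000, 8000, "+", "cold")],
            columns=["chrom", "start", "end", "strand", "gene_id"],
        )
        g = Genome([GenomeSequence("c", "A" * 20_000)])
        out = normalize_gene_methylation(genes, density_value_fn(calls), g)
        cold = out[out.gene_id == "cold"].body_norm.iloc[0]
        warm = out[out.gene_id == "warm"].body_norm.iloc[0]
        assert cold == 0.0
        assert warm > 1.0  # genome mean includes the cold region

    def test_two_planted_classes_separate(self):
        hi = [SiteCall(CnnrLocus("c", p, "+", "CG"), 1) for p in range(1000, 3000, 10)]
        lo = [SiteCall(CnnrLocus("c", p, "+", "CG"), 1) for p in range(5000, 7000, 40)]
        genes = pd.DataFrame(
            [("c", 1000, 3000, "+", "hi"), ("c", 5000, 7000, "+", "lo")],
            columns=["chrom", "start", "end", "strand", "gene_id"],
        )
        g = Genome([GenomeSequence("c", "A" * 10_000)])
        out = normalize_gene_methylation(genes, density_value_fn(hi + lo), g)
        ratio = (out[out.gene_id == "hi"].body_norm.iloc[0]
                 / out[out.gene_id == "lo"].body_norm.iloc[0])
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_zero_genome_mean_rejected(self):
        genes = pd.DataFrame([("c", 0, 100, "+", "g")],
                             columns=["chrom", "start", "end", "strand", "gene_id"])
        g = Genome([GenomeSequence("c", "A" * 200)])
        with pytest.raises(ValueError):
            normalize_gene_methylation(genes, density_value_fn([]), g)


class TestWgbsIO:
    def test_tsv_roundtrip(self, tmp_path):
        df = wgbs_df([("c", 1, "+", 3, 9), ("c", 7, "-", 0, 4)])
        path = tmp_path / "w.tsv"
        write_wgbs_tsv(df, path)
        assert read_wgbs_tsv(path).equals(df)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"chrom": ["c"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_wgbs_tsv(path)
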