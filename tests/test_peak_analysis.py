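import numpy as np
import pandas as pd
import pytest
from scipy import stats

from occutarget import peak_analysis as pa
from occutarget.synthetic_data import SimulationConfig, make_genome

from conftest import make_gene, make_peak, random_genes, random_peaks
from _oracles import annotate_bruteforce, intersect_bruteforce, nearest_gene_bruteforce


def spans(peak_set):
    return {(p.chrom, p.start, p.end) for p in peak_set.peaks}


class TestIntersectReplicates:
    def test_one_bp_overlap_suffices(self):
        a = [make_peak("chr1", 100, 200, "a1")]
        b = [make_peak("chr1", 199, 300, "b1", replicate="r2")]
        assert spans(pa.intersect_replicates(a, b)) == {("chr1", 100, 300)}

    def test_half_open_abutment_is_no_overlap(self):
        a = [make_peak("chr1", 100, 200, "a1")]
        b = [make_peak("chr1", 200, 300, "b1", replicate="r2")]
        assert spans(pa.intersect_replicates(a, b)) == set()

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            res = pa.intersect_replicates([], [make_peak("chr1", 0, 10, "b")])
        assert res.peaks == ()

    def test_symmetric_and_idempotent(self):
        rng = np.random.default_rng(17)
        a = random_peaks(rng, 60, prefix="a")
        b = random_peaks(rng, 60, prefix="b")
        ab = pa.intersect_replicates(a, b)
        ba = pa.intersect_replicates(b, a)
        assert spans(ab) == spans(ba)
        # a set intersected with itself returns its own merged regions
        aa = pa.intersect_replicates(a, a)
        merged = intersect_bruteforce(
            [(p.chrom, p.start, p.end) for p in a],
            [(p.chrom, p.start, p.end) for p in a],
        )
        assert spans(aa) == merged

    def test_output_non_overlapping(self):
        rng = np.random.default_rng(3)
        a = random_peaks(rng, 150, prefix="a")
        b = random_peaks(rng, 150, prefix="b")
        res = sorted(spans(pa.intersect_replicates(a, b)))
        for (c1, s1, e1), (c2, s2, e2) in zip(res, res[1:]):
            assert c1 != c2 or e1 <= s2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, 200, prefix="a", max_width=4000)
        b = random_peaks(rng, 200, prefix="b", max_width=4000)
        got = spans(pa.intersect_replicates(a, b))
        want = intersect_bruteforce(
            [(p.chrom, p.start, p.end) for p in a],
            [(p.chrom, p.start, p.end) for p in b],
        )
        assert got == want


class TestClassifyTemporal:
    def _sets(self, *span_lists):
        out = {}
        for tp, sl in zip(("t1", "t2", "t3"), span_lists):
            peaks = tuple(
                make_peak("chr1", s, e, f"{tp}_p{i}", timepoint=tp)
                for i, (s, e) in enumerate(sl)
            )
            out[tp] = pa.ReproduciblePeakSet(tp, peaks)
        return out

    def test_identical_sets_are_constitutive(self):
        sets = self._sets([(100, 200)], [(100, 200)], [(100, 200)])
        summ = pa.classify_temporal(sets)
        assert summ.n_regions == 1
        assert summ.constitutive_fraction == 1.0
        assert summ.class_counts == {frozenset({"t1", "t2", "t3"}): 1}

    def test_disjoint_sets_are_unique(self):
        sets = self._sets([(0, 10)], [(100, 110)], [(200, 210)])
        summ = pa.classify_temporal(sets)
        assert summ.n_regions == 3
        assert summ.unique_fraction == 1.0

    def test_counts_sum_to_region_count(self, default_dataset):
        from occutarget.pipeline import reproducible_sets

        sets = reproducible_sets(default_dataset.peaks)
        summ = pa.classify_temporal(sets)
        assert sum(summ.class_counts.values()) == summ.n_regions

    def test_planted_constitutive_regions_all_recovered(self):
        # zero jitter + every planted region constitutive: the reproducible
        # sets equal the merged planted regions and every merged region is
        # classified {t1, t2, t3}
        cfg = SimulationConfig.tiny(
            seed=5, target_class="t1,t2,t3", replicate_jitter_sd=0.0, n_noise_peaks=0
        )
        from occutarget.pipeline import reproducible_sets
        from occutarget.synthetic_data import simulate_dataset

        ds = simulate_dataset(cfg, include_coverage=False)
        sets = reproducible_sets(ds.peaks)
        planted = intersect_bruteforce(
            [(r["chrom"], r["start"], r["end"]) for r in ds.truth.regions],
            [(r["chrom"], r["start"], r["end"]) for r in ds.truth.regions],
        )
        for tp in ("t1", "t2", "t3"):
            assert spans(sets[tp]) == planted
        summ = pa.classify_temporal(sets)
        assert summ.constitutive_fraction == 1.0
        assert summ.n_regions == len(planted)


class TestNearestGene:
    def test_overlap_gives_distance_zero(self):
        genes = [make_gene("gA", "chr1", 1000, 2000, "+")]
        df = pa.assign_nearest_gene([make_peak("chr1", 1500, 1600, "p")], genes)
        assert df.loc[0, "gene_id"] == "gA"
        assert df.loc[0, "signed_distance"] == 0

    def test_equidistant_tie_breaks_lexicographically(self):
        # peak midway between two genes, TSS gaps also equal
        genes = [
            make_gene("gB", "chr1", 0, 1000, "-"),
            make_gene("gA", "chr1", 3000, 4000, "+"),
        ]
        df = pa.assign_nearest_gene([make_peak("chr1", 1500, 2500, "p")], genes)
        assert df.loc[0, "gene_id"] == "gA"

    def test_strand_sign_convention(self):
        plus = [make_gene("gp", "chr1", 5000, 6000, "+")]
        df = pa.assign_nearest_gene([make_peak("chr1", 4000, 4500, "p")], plus)
        assert df.loc[0, "signed_distance"] == -500  # upstream of + gene
        minus = [make_gene("gm", "chr1", 5000, 6000, "-")]
        df = pa.assign_nearest_gene([make_peak("chr1", 4000, 4500, "p")], minus)
        assert df.loc[0, "signed_distance"] == 500  # downstream of - gene

    def test_geneless_chromosome_flagged(self):
        genes = [make_gene("gA", "chr1", 0, 100, "+")]
        with pytest.warns(UserWarning):
            df = pa.assign_nearest_gene([make_peak("chr9", 0, 10, "p")], genes)
        assert df.loc[0, "unassigned"]
        assert df.loc[0, "gene_id"] is None

    @pytest.mark.parametrize("overlapping", [True, False])
    def test_matches_exhaustive_scan(self, overlapping):
        rng = np.random.default_rng(42 if overlapping else 43)
        genes = random_genes(rng, 100, allow_overlap=overlapping)
        peaks = random_peaks(rng, 1000)
        df = pa.assign_nearest_gene(peaks, genes)
        gene_tuples = [
            (g.gene_id, g.chrom, g.span.start, g.span.end, g.strand) for g in genes
        ]
        for p, row in zip(peaks, df.itertuples()):
            want = nearest_gene_bruteforce((p.chrom, p.start, p.end), gene_tuples)
            assert (row.gene_id, row.signed_distance) == want


class TestPeaksPerGene:
    def test_all_peaks_one_gene(self):
        df = pd.DataFrame(
            {"gene_id": ["g1"] * 3, "peak_id": list("abc"), "signed_distance": 0}
        )
        res = pa.peaks_per_gene(df)
        assert res.histogram == {3: 1} and res.mean == 3.0

    def test_one_peak_per_gene(self):
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(4)], "peak_id": list("abcd")}
        )
        res = pa.peaks_per_gene(df)
        assert res.mean == 1.0 and res.fraction_multi == 0.0

    def test_clustered_planting_matches_ledger(self, default_dataset):
        ds = default_dataset
        genes_by_id = ds.genes_by_id()
        # direct peaks-per-bound-gene of planted target regions
        counts = {}
        for r in ds.truth.regions:
            if r["target"]:
                counts[r["target"]] = counts.get(r["target"], 0) + 1
        assert np.isclose(
            np.mean(list(counts.values())),
            ds.truth.summaries["target_peaks_per_bound_gene"],
        )
        assert ds.truth.summaries["fraction_bound_genes_multi"] > 0.5


class TestPeaksPerGeneNull:
    def test_small_iterations_warn(self):
        genes = [make_gene("gA", "chr1", 0, 1000, "+")]
        peaks = [make_peak("chr1", 0, 100, "p")]
        with pytest.warns(UserWarning, match="uninformative"):
            pa.peaks_per_gene_null(peaks, genes, {"chr1": 10_000}, iterations=5)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        genes = random_genes(rng, 20, allow_overlap=False, length=200_000)
        peaks = random_peaks(rng, 30, length=195_000, max_width=500)
        a = pa.peaks_per_gene_null(peaks, genes, {"chr1": 200_000}, 50, seed=9)
        b = pa.peaks_per_gene_null(peaks, genes, {"chr1": 200_000}, 50, seed=9)
        np.testing.assert_array_equal(a.null_means, b.null_means)
        assert a.empirical_p == b.empirical_p

    def test_uniform_tiling_matches_occupancy_expectation(self):
        # genes tile the chromosome with no gaps; peaks are narrow relative to
        # gene size, so the mean peaks per hit gene follows the multinomial
        # occupancy formula n / (G * (1 - (1 - 1/G)^n))
        G, L = 20, 200_000
        size = L // G
        genes = [
            make_gene(f"g{i:02d}", "chr1", i * size, (i + 1) * size, "+")
            for i in range(G)
        ]
        peaks = [make_peak("chr1", 0, 10, f"p{i}") for i in range(30)]
        res = pa.peaks_per_gene_null(peaks, genes, {"chr1": L}, iterations=400, seed=2)
        n = 30
        expect = n / (G * (1 - (1 - 1 / G) ** n))
        assert abs(np.nanmean(res.null_means) - expect) < 0.05

    def test_observed_at_null_median_gives_half_p(self):
        rng = np.random.default_rng(7)
        genes = random_genes(rng, 25, allow_overlap=False, length=300_000)
        widths = [400] * 40
        sizes = {"chr1": 300_000}
        # take one null draw as the observation
        from occutarget._rng import stream
        from occutarget.peak_analysis import _place_random

        r = stream(123, "obs_draw")
        ci, starts = _place_random(
            np.array(widths), ["chr1"], np.array([300_000]), r
        )
        peaks = [
            make_peak("chr1", int(s), int(s) + w, f"p{i}")
            for i, (s, w) in enumerate(zip(starts, widths))
        ]
        res = pa.peaks_per_gene_null(peaks, genes, sizes, iterations=199, seed=5)
        assert 0.05 < res.empirical_p <= 1.0  # not in the extreme tail


class TestAnnotateFeature:
    def test_promoter_precedence(self):
        g = make_gene("gA", "chr1", 1000, 3000, "+", exons=[(1000, 1500), (2500, 3000)])
        df = pa.annotate_feature([make_peak("chr1", 900, 1100, "p")], [g])
        assert df.loc[0, "category"] == "promoter"

    def test_intron_between_exons(self):
        g = make_gene("gA", "chr1", 1000, 9000, "+", exons=[(1000, 1500), (8500, 9000)])
        df = pa.annotate_feature([make_peak("chr1", 4000, 4100, "p")], [g])
        assert df.loc[0, "category"] == "intron"

    def test_intergenic(self):
        g = make_gene("gA", "chr1", 1000, 2000, "+")
        df = pa.annotate_feature([make_peak("chr1", 50_000, 50_100, "p")], [g])
        assert df.loc[0, "category"] == "intergenic"

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        genes = []
        for i in range(40):
            s = int(rng.integers(0, 900_000))
            w = int(rng.integers(1000, 8000))
            strand = "+" if rng.random() < 0.5 else "-"
            mid = s + w // 2
            genes.append(
                make_gene(f"g{i:02d}", "chr1", s, s + w, strand, exons=[(s, mid), (mid + w // 4, s + w)])
            )
        peaks = random_peaks(rng, 400)
        df = pa.annotate_feature(peaks, genes, promoter_window=500)
        gene_tuples = [
            (
                g.gene_id,
                g.chrom,
                g.span.start,
                g.span.end,
                g.strand,
                [(e.start, e.end) for e in g.exons],
            )
            for g in genes
        ]
        for p, row in zip(peaks, df.itertuples()):
            assert row.category == annotate_bruteforce(
                (p.chrom, p.start, p.end), gene_tuples, 500
            )


class TestProfiles:
    def test_center_on_plus_tss_is_zero(self):
        g = make_gene("gA", "chr1", 5000, 8000, "+")
        prof = pa.tss_distance_profile([make_peak("chr1", 4950, 5050, "p")], [g], bin=100)
        assert prof.distances.tolist() == [0]

    def test_minus_strand_five_prime_is_negative(self):
        g = make_gene("gA", "chr1", 5000, 8000, "-")  # tss = 7999
        # peak center 100 bp genomically right of the tss = 5' of a minus gene
        prof = pa.tss_distance_profile([make_peak("chr1", 8050, 8150, "p")], [g], bin=50)
        assert prof.distances.tolist() == [-101]

    def test_planted_tss_proximal_peaks_mode_at_zero(self):
        rng = np.random.default_rng(9)
        genes = random_genes(rng, 50, allow_overlap=False, length=2_000_000)
        peaks = []
        for i, g in enumerate(genes):
            c = int(g.tss + rng.normal(0, 200))
            peaks.append(make_peak("chr1", max(0, c - 50), max(0, c - 50) + 100, f"p{i}"))
        prof = pa.tss_distance_profile(peaks, genes, bin=500, range_bp=5000)
        zero_bin = np.searchsorted(prof.bin_edges, 0, side="right") - 1
        assert prof.counts.argmax() == zero_bin

    def test_width_summary(self):
        peaks = [make_peak("chr1", 0, w, f"p{w}") for w in (100, 200, 300, 400, 500)]
        summ = pa.width_summary(peaks)
        assert summ["median"] == 300 and summ["n"] == 5
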