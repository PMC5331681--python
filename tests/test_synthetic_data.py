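import filecmp
import json
import math

import numpy as np
import pandas as pd
import pytest

from occutarget import genome_io as gio
from occutarget import pausing_analysis as pz
from occutarget import target_calling as tc
from occutarget.synthetic_data import (
    GroundTruth,
    SimulationConfig,
    end_to_end_fixture,
    make_genome,
    simulate_dataset,
    simulate_de,
)


class TestMakeGenome:
    def test_empty_annotation(self):
        genes, sizes = make_genome(SimulationConfig.tiny(n_genes=0))
        assert genes == [] and len(sizes) == 2

    def test_genes_non_overlapping_and_on_chrom(self):
        genes, sizes = make_genome(SimulationConfig.tiny(n_genes=100, seed=2))
        assert len(genes) == 100
        by_chrom = {}
        for g in genes:
            assert 0 <= g.span.start < g.span.end <= sizes[g.chrom]
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.span.start)
            for a, b in zip(gs, gs[1:]):
                assert a.span.end <= b.span.start

    def test_infeasible_packing_reports_requirement(self):
        cfg = SimulationConfig.tiny(n_genes=500, chrom_length=100_000)
        with pytest.raises(ValueError, match="length >="):
            make_genome(cfg)

    def test_gene_length_distribution_mean(self):
        # sample mean across seeds within 3 SE of the clipped-lognormal mean
        cfg0 = SimulationConfig.default()
        means = []
        for seed in range(20):
            genes, _ = make_genome(SimulationConfig.default(n_genes=300, seed=seed))
            means.append(np.mean([g.length for g in genes]))
        mu, sd = cfg0.gene_length_meanlog, cfg0.gene_length_sdlog
        rng = np.random.default_rng(0)
        ref = np.clip(
            rng.lognormal(mu, sd, 200_000), cfg0.min_gene_length, cfg0.chrom_length // 10
        )
        se = ref.std() / math.sqrt(300 * 20)
        assert abs(np.mean(means) - ref.mean()) < 3 * se + 5.0


class TestPlantPeaks:
    def test_zero_jitter_recovers_planted_regions(self):
        from occutarget.peak_analysis import intersect_replicates

        cfg = SimulationConfig.tiny(seed=9, replicate_jitter_sd=0.0)
        ds = simulate_dataset(cfg, include_coverage=False)
        for tp in ("t1", "t2", "t3"):
            rep = intersect_replicates(ds.peaks[(tp, "r1")], ds.peaks[(tp, "r2")])
            planted = {
                (r["chrom"], r["start"], r["end"])
                for r in ds.truth.regions
                if tp in r["membership"].split(",")
            }
            got = {(p.chrom, p.start, p.end) for p in rep.peaks}
            # merged planted regions may fuse overlapping ones; every planted
            # base must be covered and no extra bases appear
            for c, s, e in planted:
                assert any(gc == c and gs <= s and e <= ge for gc, gs, ge in got)

    def test_multi_peak_fraction_near_paper_motivated_value(self):
        fracs = []
        for seed in range(10):
            ds = simulate_dataset(
                SimulationConfig.default(seed=seed), include_coverage=False
            )
            fracs.append(ds.truth.summaries["fraction_bound_genes_multi"])
        # peaks-per-target ~ max(1, Poisson(2.5)) puts most bound genes >= 2
        assert 0.55 < np.mean(fracs) < 0.95

    def test_replicate_jitter_keeps_regions_reproducible(self, default_dataset):
        from occutarget.pipeline import reproducible_sets

        ds = default_dataset
        sets = reproducible_sets(ds.peaks)
        for tp in ("t1", "t2", "t3"):
            n_planted = sum(
                1 for r in ds.truth.regions if tp in r["membership"].split(",")
            )
            # merging can only reduce the count; jitter loss must be negligible
            assert len(sets[tp].peaks) >= 0.9 * n_planted - 5
            assert len(sets[tp].peaks) <= n_planted


class TestSimulateDE:
    def test_padj_bounded(self, default_dataset):
        for df in default_dataset.de.values():
            assert df["padj"].between(0, 1).all()

    def test_zero_noise_targets_have_exact_effect(self):
        cfg = SimulationConfig.tiny(seed=3, de_noise_sd=0.0, de_effect=-1.0)
        ds = simulate_dataset(cfg, include_coverage=False)
        targets = set(ds.truth.true_targets)
        for df in ds.de.values():
            sub = df[df["gene_id"].isin(targets)]
            assert (sub["log2fc"] == -1.0).all()

    def test_null_de_rate_calibration(self):
        # no planted effect: DE call rate ~ null_de_rate plus the small
        # residual from null genes crossing both thresholds by chance
        rates = []
        for seed in range(20):
            cfg = SimulationConfig.tiny(
                n_genes=300,
                chrom_length=1_500_000,
                n_true_targets=0,
                de_effect=0.0,
                seed=seed,
            )
            ds = simulate_dataset(cfg, include_coverage=False)
            sets = tc.classify_de(ds.de["t1"])
            rates.append((len(sets["down"]) + len(sets["up"])) / 300)
        assert 0.03 < np.mean(rates) < 0.09


class TestSimulateCoverage:
    def test_noise_off_recovers_ratios_exactly(self):
        cfg = SimulationConfig.tiny(seed=7, coverage_noise=False)
        ds = simulate_dataset(cfg)
        table = pz.pausing_table(ds.genes, ds.coverage)
        for row in table.itertuples():
            if row.excluded or np.isnan(row.ratio):
                continue
            assert math.isclose(
                row.ratio, ds.truth.true_pausing_ratio[row.gene_id], rel_tol=1e-9
            )

    def test_total_coverage_matches_depth(self):
        cfg = SimulationConfig.tiny(seed=8, coverage_noise=False)
        ds = simulate_dataset(cfg)
        total = ds.coverage.plus.total() + ds.coverage.minus.total()
        assert math.isclose(total, cfg.read_depth, rel_tol=1e-6)

    def test_poisson_noise_preserves_depth_within_error(self):
        cfg = SimulationConfig.tiny(seed=8, coverage_noise=True)
        ds = simulate_dataset(cfg)
        total = ds.coverage.plus.total() + ds.coverage.minus.total()
        # total of ~read_depth Poisson counts: SE ~ sqrt(depth)
        assert abs(total - cfg.read_depth) < 4 * math.sqrt(cfg.read_depth)

    def test_planted_separation_detected(self, tiny_dataset):
        ds = tiny_dataset
        table = pz.pausing_table(ds.genes, ds.coverage)
        res = pz.compare_sets(
            table,
            set(ds.truth.true_targets),
            {g.gene_id for g in ds.genes},
            n_perm=999,
            seed=1,
        )
        assert res.p_value == 1 / 1000


class TestEndToEnd:
    def test_fixture_files_validate_and_round_trip(self, tmp_path):
        cfg = SimulationConfig.tiny(seed=13)
        out = end_to_end_fixture(cfg, tmp_path / "d1")
        ds = out["dataset"]
        genes_back = gio.read_genes(tmp_path / "d1" / "genes.gtf", format="gtf")
        assert {g.gene_id for g in genes_back} == {g.gene_id for g in ds.genes}
        sizes = gio.read_chrom_sizes(tmp_path / "d1" / "chrom.sizes")
        assert sizes == ds.chrom_sizes
        peaks_back = gio.read_peaks(
            tmp_path / "d1" / "peaks_t2_r1.bed", timepoint="t2", replicate="r1",
            chrom_sizes=sizes,
        )
        assert len(peaks_back) == len(ds.peaks[("t2", "r1")])
        de_back = gio.read_de_table(tmp_path / "d1" / "de_t1.tsv")
        pd.testing.assert_frame_equal(de_back, ds.de["t1"])
        cov = gio.read_coverage(
            tmp_path / "d1" / "coverage_plus.bedGraph", chrom_sizes=sizes, strand="+"
        )
        np.testing.assert_allclose(
            cov.values("chr1", 0, sizes["chr1"]),
            ds.coverage.plus.values("chr1", 0, sizes["chr1"]),
            atol=1e-6,
        )
        truth = GroundTruth(**json.loads((tmp_path / "d1" / "ground_truth.json").read_text()))
        assert truth.true_targets == ds.truth.true_targets

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig.tiny(seed=21)
        end_to_end_fixture(cfg, tmp_path / "a")
        end_to_end_fixture(cfg, tmp_path / "b")
        names = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert not mismatch and not errors

    def test_tiny_preset_pipeline_finds_targets(self, tiny_dataset):
        from occutarget.pipeline import call_targets_from_dataset

        _, res = call_targets_from_dataset(tiny_dataset, seed=3)
        assert len(res.union) > 0
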