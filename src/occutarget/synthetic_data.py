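"""Synthetic genomes, peaks, DE tables, and coverage with known ground truth.

The generator emulates the inputs the pipeline consumes in a corepressor
ChIP-seq / RNA-seq study: a toy multi-chromosome annotation of non-overlapping
genes; planted binding peaks clustered at or inside a chosen set of true
target genes (plus uniformly placed noise peaks), emitted per timepoint and
replicate with edge jitter so replicate intersection is exercised; DE tables
in which true targets are down-regulated under overexpression with a
configurable effect size and noise; and stranded coverage tracks giving true
targets an elevated promoter-proximal to gene-body density ratio.

Every sampled quantity is recorded in a :class:`GroundTruth` ledger, so each
pipeline stage can be checked against what was actually planted.  All
randomness derives from ``config.seed`` through named streams: the same
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import stream
from .genome_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    StrandedCoverage,
    write_bedgraph,
    write_chrom_sizes,
    write_genes_bed12,
    write_genes_gtf,
    write_peaks,
    write_tsv,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "make_genome",
    "plant_peaks",
    "simulate_de",
    "simulate_coverage",
    "simulate_dataset",
    "end_to_end_fixture",
]

TIMEPOINTS = ("t1", "t2", "t3")
REPLICATES = ("r1", "r2")

# Temporal membership weights for planted binding regions: most sites are
# unique to one window, a small minority constitutive, and the t1&t2-only
# and t1&t3-only classes are rare.
DEFAULT_CLASS_WEIGHTS: Dict[str, float] = {
    "t1": 0.12,
    "t2": 0.27,
    "t3": 0.19,
    "t1,t2": 0.03,
    "t1,t3": 0.01,
    "t2,t3": 0.29,
    "t1,t2,t3": 0.09,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults defining the standard
    simulated conditions: 2000 genes on 5 chromosomes, 50 true repression
    targets carrying ~2.5 clustered peaks each (median width ~600 bp),
    uniform noise peaks, a -1.5 mean log2 fold-change for targets under
    overexpression, a 5% spurious DE rate, and a 5:1 target vs 1:1 background
    proximal/body coverage ratio."""

    n_chroms: int = 5
    chrom_length: int = 3_000_000
    n_genes: int = 2000
    gene_length_meanlog: float = math.log(2000.0)
    gene_length_sdlog: float = 0.6
    min_gene_length: int = 700
    min_gene_gap: int = 200
    exons_per_gene: Tuple[int, int] = (2, 5)
    n_true_targets: int = 50
    peaks_per_target_mean: float = 2.5
    peak_width_meanlog: float = math.log(600.0)
    peak_width_sdlog: float = 0.35
    min_peak_width: int = 50
    peak_placement_sd: float = 200.0
    edge_fraction: float = 0.5
    n_noise_peaks: int = 300
    replicate_jitter_sd: float = 10.0
    temporal_class_weights: Tuple[Tuple[str, float], ...] = tuple(
        DEFAULT_CLASS_WEIGHTS.items()
    )
    target_class: Optional[str] = None  # None: sample target regions like any other
    de_effect: float = -1.5
    de_noise_sd: float = 0.4
    null_de_rate: float = 0.05
    pausing_ratio_targets: float = 5.0
    pausing_ratio_background: float = 1.0
    proximal_window: int = 300
    read_depth: float = 1_000_000.0
    coverage_noise: bool = True
    coverage_step: int = 25
    seed: int = 0

    @classmethod
    def default(cls, **overrides) -> "SimulationConfig":
        return cls(**overrides)

    @classmethod
    def tiny(cls, **overrides) -> "SimulationConfig":
        """A preset small enough for the full pipeline to run in seconds."""
        base = dict(
            n_chroms=2,
            chrom_length=400_000,
            n_genes=60,
            n_true_targets=8,
            n_noise_peaks=30,
            read_depth=200_000.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def genome_scale(cls, **overrides) -> "SimulationConfig":
        """Roughly fly-genome-sized annotation; slow, for manual exploration."""
        base = dict(
            n_chroms=6,
            chrom_length=20_000_000,
            n_genes=13_000,
            n_true_targets=200,
            n_noise_peaks=3_000,
            read_depth=10_000_000.0,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def class_weights(self) -> Dict[str, float]:
        return dict(self.temporal_class_weights)


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted."""

    true_targets: List[str] = field(default_factory=list)
    regions: List[dict] = field(default_factory=list)  # planted binding regions
    true_log2fc: Dict[str, Dict[str, float]] = field(default_factory=dict)  # tp -> gene -> lfc
    true_pausing_ratio: Dict[str, float] = field(default_factory=dict)
    summaries: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticDataset:
    """A complete in-memory synthetic study."""

    config: SimulationConfig
    genes: List[GeneModel]
    chrom_sizes: Dict[str, int]
    peaks: Dict[Tuple[str, str], List[Peak]]  # (timepoint, replicate) -> peaks
    de: Dict[str, pd.DataFrame]  # timepoint -> DE table
    coverage: StrandedCoverage
    truth: GroundTruth

    def genes_by_id(self) -> Dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


# ---------------------------------------------------------------------------
# genome


def make_genome(config: SimulationConfig) -> Tuple[List[GeneModel], Dict[str, int]]:
    """Non-overlapping gene models on equally sized chromosomes.

    Strands are assigned 1:1 at random; each gene gets 2-5 exons (first and
    last segments exonic).  Raises when the requested genes cannot be packed,
    reporting the chromosome length that would suffice.
    """
    rng = stream(config.seed, "make_genome")
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    if config.n_genes == 0:
        return [], chrom_sizes
    lengths = np.clip(
        rng.lognormal(config.gene_length_meanlog, config.gene_length_sdlog, config.n_genes),
        config.min_gene_length,
        config.chrom_length // 10,
    ).astype(np.int64)
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    genes: List[GeneModel] = []
    total_exonic = 0
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        ls = lengths[idxs]
        needed = int(ls.sum() + (len(idxs) + 1) * config.min_gene_gap)
        if needed > config.chrom_length:
            raise ValueError(
                f"cannot pack {len(idxs)} genes on {chrom}: need chromosome "
                f"length >= {needed}"
            )
        slack = config.chrom_length - int(ls.sum()) - (len(idxs) + 1) * config.min_gene_gap
        w = rng.random(len(idxs) + 1) + 0.05
        extra = np.floor(w / w.sum() * slack).astype(np.int64)
        gaps = extra + config.min_gene_gap
        pos = 0
        for j, gi in enumerate(idxs):
            pos += int(gaps[j])
            start, end = pos, pos + int(ls[j])
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _make_exons(chrom, start, end, strand, config, rng)
            g = GeneModel(
                f"g{gi:05d}", GenomicInterval(chrom, start, end, strand), exons
            )
            total_exonic += g.exonic_bases
            genes.append(g)
            pos = end
    return genes, chrom_sizes


def _make_exons(chrom, start, end, strand, config, rng) -> Tuple[GenomicInterval, ...]:
    length = end - start
    lo, hi = config.exons_per_gene
    k = int(rng.integers(lo, hi + 1))
    n_seg = 2 * k - 1
    if length < n_seg * 20:
        return (GenomicInterval(chrom, start, end, strand),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False))
    bounds = np.concatenate(([0], cuts, [length]))
    exons = []
    for s_i in range(0, n_seg, 2):  # even segments are exons; ends are exonic
        s, e = int(bounds[s_i]), int(bounds[s_i + 1])
        if e > s:
            exons.append(GenomicInterval(chrom, start + s, start + e, strand))
    return tuple(exons)


# ---------------------------------------------------------------------------
# peaks


def plant_peaks(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    truth: GroundTruth,
) -> Dict[Tuple[str, str], List[Peak]]:
    """Plant clustered peaks at true targets plus uniform noise peaks.

    Target peaks are centered either at a gene boundary or uniformly inside
    the gene (``edge_fraction`` controls the mix) with Normal jitter of
    ``peak_placement_sd``.  Each planted region gets a temporal membership
    class; for every timepoint in the class the region is emitted into both
    replicates with small independent edge jitter, so replicate intersection
    recovers essentially all planted regions at the default jitter.
    """
    rng = stream(config.seed, "plant_peaks")
    gene_list = list(genes)
    if config.n_true_targets > len(gene_list):
        raise ValueError("more true targets than genes")
    target_idx = rng.choice(len(gene_list), size=config.n_true_targets, replace=False)
    targets = [gene_list[i] for i in sorted(target_idx)]
    truth.true_targets = [g.gene_id for g in targets]

    weights = config.class_weights
    classes = list(weights)
    probs = np.array([weights[c] for c in classes], dtype=float)
    probs /= probs.sum()

    regions: List[dict] = []

    def sample_class() -> str:
        if config.target_class is not None:
            return config.target_class
        return classes[int(rng.choice(len(classes), p=probs))]

    def add_region(chrom, center, width, target_gene, kind):
        L = chrom_sizes[chrom]
        width = int(max(config.min_peak_width, min(width, L)))
        start = int(np.clip(center - width // 2, 0, L - width))
        regions.append(
            {
                "region_id": f"reg{len(regions):05d}",
                "chrom": chrom,
                "start": start,
                "end": start + width,
                "target": target_gene,
                "kind": kind,
                "membership": sample_class() if kind == "target" else _noise_class(),
            }
        )

    def _noise_class() -> str:
        return classes[int(rng.choice(len(classes), p=probs))]

    for g in targets:
        n_pk = max(1, int(rng.poisson(config.peaks_per_target_mean)))
        for _ in range(n_pk):
            width = rng.lognormal(config.peak_width_meanlog, config.peak_width_sdlog)
            if rng.random() < config.edge_fraction:
                edge = g.span.start if rng.random() < 0.5 else g.span.end
                center = edge + rng.normal(0.0, config.peak_placement_sd)
            else:
                center = rng.uniform(g.span.start, g.span.end)
            add_region(g.chrom, center, width, g.gene_id, "target")
    chroms = list(chrom_sizes)
    lens = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    cprob = lens / lens.sum()
    for _ in range(config.n_noise_peaks):
        chrom = chroms[int(rng.choice(len(chroms), p=cprob))]
        width = rng.lognormal(config.peak_width_meanlog, config.peak_width_sdlog)
        center = rng.uniform(0, chrom_sizes[chrom])
        add_region(chrom, center, width, None, "noise")

    truth.regions = regions
    bound = {}
    for r in regions:
        if r["target"] is not None:
            bound[r["target"]] = bound.get(r["target"], 0) + 1
    truth.summaries["n_target_regions"] = float(
        sum(1 for r in regions if r["kind"] == "target")
    )
    truth.summaries["n_noise_regions"] = float(config.n_noise_peaks)
    truth.summaries["target_peaks_per_bound_gene"] = (
        float(np.mean(list(bound.values()))) if bound else float("nan")
    )
    truth.summaries["fraction_bound_genes_multi"] = (
        float(np.mean([v >= 2 for v in bound.values()])) if bound else float("nan")
    )

    peaks: Dict[Tuple[str, str], List[Peak]] = {
        (tp, rep): [] for tp in TIMEPOINTS for rep in REPLICATES
    }
    jit = config.replicate_jitter_sd
    for r in regions:
        member = r["membership"].split(",")
        width = r["end"] - r["start"]
        max_jit = max(1, width // 3)
        L = chrom_sizes[r["chrom"]]
        for tp in TIMEPOINTS:
            if tp not in member:
                continue
            for rep in REPLICATES:
                ds = int(np.clip(round(rng.normal(0.0, jit)), -max_jit, max_jit))
                de_ = int(np.clip(round(rng.normal(0.0, jit)), -max_jit, max_jit))
                s = int(np.clip(r["start"] + ds, 0, L - 1))
                e = int(np.clip(r["end"] + de_, s + 1, L))
                peaks[(tp, rep)].append(
                    Peak(
                        GenomicInterval(r["chrom"], s, e),
                        peak_id=f"{r['region_id']}_{tp}_{rep}",
                        timepoint=tp,
                        replicate=rep,
                    )
                )
    return peaks


# ---------------------------------------------------------------------------
# differential expression


def simulate_de(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
) -> Dict[str, pd.DataFrame]:
    """Per-timepoint DE tables emulating a DESeq2 overexpression contrast.

    True targets draw log2fc ~ Normal(de_effect, de_noise_sd) with a small
    adjusted p-value (Beta skewed toward zero); other genes draw
    log2fc ~ Normal(0, de_noise_sd) with padj ~ Uniform(0,1), except a
    ``null_de_rate`` fraction that is spuriously significant.
    """
    target_set = set(truth.true_targets)
    tables: Dict[str, pd.DataFrame] = {}
    for tp in TIMEPOINTS:
        rng = stream(config.seed, "simulate_de", TIMEPOINTS.index(tp))
        rows = []
        truth.true_log2fc[tp] = {}
        for g in genes:
            if g.gene_id in target_set:
                lfc = rng.normal(config.de_effect, config.de_noise_sd)
                padj = float(rng.beta(0.5, 200.0))
            else:
                if rng.random() < config.null_de_rate:
                    mag = 0.5 + rng.exponential(0.4)
                    lfc = mag if rng.random() < 0.5 else -mag
                    padj = float(rng.uniform(0.0, 0.05))
                else:
                    lfc = rng.normal(0.0, config.de_noise_sd)
                    padj = float(rng.uniform(0.0, 1.0))
            truth.true_log2fc[tp][g.gene_id] = float(lfc)
            rows.append({"gene_id": g.gene_id, "log2fc": float(lfc), "padj": padj})
        tables[tp] = pd.DataFrame(rows)
    return tables


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    truth: GroundTruth,
) -> StrandedCoverage:
    """Stranded coverage with an elevated proximal/body ratio at true targets.

    Each gene gets a piecewise-constant profile: the first
    ``proximal_window`` bases downstream of the TSS at ``ratio x`` the
    gene-body level, the body at a per-gene expression level; the whole
    genome is scaled so the total integrated coverage equals ``read_depth``.
    With ``coverage_noise`` on, Poisson counts are drawn per
    ``coverage_step``-bp step; intergenic background stays at zero.
    """
    rng = stream(config.seed, "simulate_coverage")
    target_set = set(truth.true_targets)
    plus = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    minus = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    w = config.proximal_window
    for g in genes:
        level = rng.lognormal(0.0, 0.5)
        ratio = (
            config.pausing_ratio_targets
            if g.gene_id in target_set
            else config.pausing_ratio_background
        )
        truth.true_pausing_ratio[g.gene_id] = float(ratio)
        arr = plus[g.chrom] if g.strand == "+" else minus[g.chrom]
        g0, g1 = g.span.start, g.span.end
        if g.strand == "+":
            arr[g0 : min(g0 + w, g1)] = level * ratio
            arr[min(g0 + w, g1) : g1] = level
        else:
            arr[max(g1 - w, g0) : g1] = level * ratio
            arr[g0 : max(g1 - w, g0)] = level
    raw_total = sum(a.sum() for a in plus.values()) + sum(
        a.sum() for a in minus.values()
    )
    scale = config.read_depth / raw_total if raw_total > 0 else 0.0
    for d in (plus, minus):
        for c in d:
            d[c] *= scale
    if config.coverage_noise:
        step = config.coverage_step
        for d in (plus, minus):
            for c in d:
                arr = d[c]
                pad = (-len(arr)) % step
                padded = np.concatenate([arr, np.zeros(pad)]) if pad else arr
                blocks = padded.reshape(-1, step)
                means = blocks.sum(axis=1)
                counts = np.where(means > 0, rng.poisson(means), 0.0)
                noisy = np.repeat(counts / step, step)[: len(arr)]
                d[c] = noisy
    truth.summaries["total_coverage"] = float(
        sum(a.sum() for a in plus.values()) + sum(a.sum() for a in minus.values())
    )
    return StrandedCoverage(
        plus=CoverageTrack(plus, strand="+"), minus=CoverageTrack(minus, strand="-")
    )


# ---------------------------------------------------------------------------
# whole datasets


def simulate_dataset(
    config: SimulationConfig, include_coverage: bool = True
) -> SyntheticDataset:
    """Generate the complete in-memory study for one configuration.

    ``include_coverage=False`` skips the (comparatively slow) coverage tracks
    for analyses that only need peaks and DE tables.
    """
    truth = GroundTruth()
    genes, chrom_sizes = make_genome(config)
    peaks = plant_peaks(config, genes, chrom_sizes, truth)
    de = simulate_de(config, genes, truth)
    if include_coverage:
        coverage = simulate_coverage(config, genes, chrom_sizes, truth)
    else:
        coverage = StrandedCoverage(
            plus=CoverageTrack({}, strand="+"), minus=CoverageTrack({}, strand="-")
        )
    truth.summaries["n_genes"] = float(len(genes))
    truth.summaries["total_exonic_bases"] = float(sum(g.exonic_bases for g in genes))
    return SyntheticDataset(
        config=config,
        genes=genes,
        chrom_sizes=chrom_sizes,
        peaks=peaks,
        de=de,
        coverage=coverage,
        truth=truth,
    )


def end_to_end_fixture(config: SimulationConfig, outdir) -> Dict[str, object]:
    """Write a complete runnable input directory plus the ground-truth JSON.

    Files: genes.gtf, genes.bed12, chrom.sizes, peaks_<tp>_<rep>.bed (x6),
    de_<tp>.tsv (x3), coverage_plus.bedGraph, coverage_minus.bedGraph,
    ground_truth.json.  Byte-identical for identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    paths: Dict[str, object] = {"dir": outdir, "dataset": ds}
    write_genes_gtf(ds.genes, outdir / "genes.gtf")
    write_genes_bed12(ds.genes, outdir / "genes.bed12")
    write_chrom_sizes(ds.chrom_sizes, outdir / "chrom.sizes")
    for (tp, rep), pk in ds.peaks.items():
        write_peaks(pk, outdir / f"peaks_{tp}_{rep}.bed")
    for tp, df in ds.de.items():
        write_tsv(df, outdir / f"de_{tp}.tsv")
    write_bedgraph(ds.coverage.plus, outdir / "coverage_plus.bedGraph")
    write_bedgraph(ds.coverage.minus, outdir / "coverage_minus.bedGraph")
    ds.truth.to_json(outdir / "ground_truth.json")
    paths["truth"] = ds.truth
    return paths
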