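import numpy as np
import pytest

from occutarget.genome_io import GeneModel, GenomicInterval, Peak
from occutarget.synthetic_data import SimulationConfig, simulate_dataset


def make_peak(chrom, start, end, peak_id="p", timepoint="t1", replicate="r1"):
    return Peak(GenomicInterval(chrom, start, end), peak_id, timepoint, replicate)


def make_gene(gene_id, chrom, start, end, strand="+", exons=()):
    return GeneModel(
        gene_id,
        GenomicInterval(chrom, start, end, strand),
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


def random_genes(rng, n, chrom="chr1", length=1_000_000, allow_overlap=True):
    """Random gene models; overlapping spans unless allow_overlap=False."""
    genes = []
    if allow_overlap:
        for i in range(n):
            s = int(rng.integers(0, length - 5000))
            w = int(rng.integers(500, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(make_gene(f"g{i:04d}", chrom, s, s + w, strand))
    else:
        pos = 0
        for i in range(n):
            pos += int(rng.integers(200, length // (2 * n)))
            w = int(rng.integers(500, length // (2 * n)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(make_gene(f"g{i:04d}", chrom, pos, pos + w, strand))
            pos += w
    return genes


def random_peaks(rng, n, chrom="chr1", length=1_000_000, max_width=2000, prefix="p"):
    peaks = []
    for i in range(n):
        s = int(rng.integers(0, length - max_width))
        w = int(rng.integers(1, max_width))
        peaks.append(make_peak(chrom, s, s + w, f"{prefix}{i:04d}"))
    return peaks


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(SimulationConfig.tiny(seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimulationConfig.default(seed=11), include_coverage=False)
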