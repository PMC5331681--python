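"""Peak-level analyses: replicate reproducibility, temporal dynamics,
nearest-gene assignment, genomic-feature annotation, and the Monte Carlo
peaks-per-gene null.

Binding-site catalogs from replicated ChIP-seq are reduced to
replicate-supported regions (>= 1 bp overlap between replicates by default),
classified by which developmental windows they recur in, assigned to their
closest gene, and compared against a null in which the same number of
intervals with the same width multiset is dropped uniformly at random on the
genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import stream
from .genome_io import GeneModel, GenomicInterval, Peak

__all__ = [
    "ReproduciblePeakSet",
    "TemporalSummary",
    "PeaksPerGene",
    "PeaksPerGeneNull",
    "intersect_replicates",
    "classify_temporal",
    "assign_nearest_gene",
    "peaks_per_gene",
    "peaks_per_gene_null",
    "annotate_feature",
    "tss_distance_profile",
    "width_summary",
]


@dataclass(frozen=True)
class ReproduciblePeakSet:
    """Replicate-supported, non-overlapping peak regions for one timepoint."""

    timepoint: str
    peaks: Tuple[Peak, ...]


# ---------------------------------------------------------------------------
# replicate intersection


def _components(intervals: List[Tuple[str, int, int, int]], min_overlap: int):
    """Group (chrom, start, end, tag) records into maximal overlap components.

    Two records are linked when they share >= min_overlap bp; components are
    the transitive closure.  Records sorted by (chrom, start); because the
    running maximum end determines the best possible overlap with any earlier
    member, a single sweep is exact.
    """
    comps: List[List[Tuple[str, int, int, int]]] = []
    cur: List[Tuple[str, int, int, int]] = []
    cur_chrom, cur_max_end = None, -1
    for rec in sorted(intervals, key=lambda r: (r[0], r[1], r[2])):
        chrom, start, end, _ = rec
        width = end - start
        joins = (
            cur
            and chrom == cur_chrom
            and width >= min_overlap
            and cur_max_end - start >= min_overlap
        )
        if joins:
            cur.append(rec)
            cur_max_end = max(cur_max_end, end)
        else:
            if cur:
                comps.append(cur)
            cur = [rec]
            cur_chrom, cur_max_end = chrom, end
    if cur:
        comps.append(cur)
    return comps


def intersect_replicates(
    rep_a: Sequence[Peak],
    rep_b: Sequence[Peak],
    min_overlap: int = 1,
    span: str = "union",
) -> ReproduciblePeakSet:
    """Derive replicate-supported peak regions (>= min_overlap bp shared).

    Each maximal group of mutually touching peaks from the combined set that
    contains at least one peak from each replicate is reported once.  By
    default the merged union span of the group is returned, preserving the
    full evidence extent; ``span='intersection'`` returns instead the overlap
    of the two per-replicate merged spans.
    """
    if span not in ("union", "intersection"):
        raise ValueError(f"unknown span mode {span!r}")
    tps = {p.timepoint for p in rep_a} | {p.timepoint for p in rep_b}
    if len(tps) > 1:
        raise ValueError(f"replicates span multiple timepoints: {sorted(tps)}")
    timepoint = next(iter(tps)) if tps else "t1"
    if not rep_a or not rep_b:
        warnings.warn("empty replicate peak set; no reproducible peaks")
        return ReproduciblePeakSet(timepoint, ())

    records = [(p.chrom, p.start, p.end, 0) for p in rep_a]
    records += [(p.chrom, p.start, p.end, 1) for p in rep_b]
    out: List[Peak] = []
    for comp in _components(records, min_overlap):
        tags = {tag for *_, tag in comp}
        if tags != {0, 1}:
            continue
        chrom = comp[0][0]
        if span == "union":
            s, e = min(r[1] for r in comp), max(r[2] for r in comp)
        else:
            sa = min(r[1] for r in comp if r[3] == 0), max(r[2] for r in comp if r[3] == 0)
            sb = min(r[1] for r in comp if r[3] == 1), max(r[2] for r in comp if r[3] == 1)
            s, e = max(sa[0], sb[0]), min(sa[1], sb[1])
            if e <= s:  # replicate spans can disconnect within a chained group
                s, e = min(sa[0], sb[0]), max(sa[1], sb[1])
        out.append(
            Peak(
                GenomicInterval(chrom, s, e),
                peak_id=f"{timepoint}_rp{len(out)}",
                timepoint=timepoint,
                replicate="merged",
            )
        )
    return ReproduciblePeakSet(timepoint, tuple(out))


# ---------------------------------------------------------------------------
# temporal classification


@dataclass(frozen=True)
class TemporalSummary:
    """Temporal membership of every merged binding region across timepoints."""

    regions: pd.DataFrame  # region_id, chrom, start, end, membership
    class_counts: Dict[FrozenSet[str], int]
    unique_fraction: float
    constitutive_fraction: float

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            {"membership": ",".join(sorted(k)), "count": v}
            for k, v in sorted(self.class_counts.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def classify_temporal(
    sets: Mapping[str, ReproduciblePeakSet], min_overlap: int = 1
) -> TemporalSummary:
    """Assign every binding region its temporal membership class.

    The peaks of all timepoints are pooled and merged into regions (transitive
    >= min_overlap bp overlap); a region's membership is the set of timepoints
    contributing at least one peak to it.  With three timepoints this yields
    the seven non-empty membership classes whose counts sum to the number of
    merged regions.
    """
    tp_order = list(sets)
    records = []
    for idx, tp in enumerate(tp_order):
        for p in sets[tp].peaks:
            records.append((p.chrom, p.start, p.end, idx))
    rows = []
    counts: Dict[FrozenSet[str], int] = {}
    for comp in _components(records, min_overlap):
        chrom = comp[0][0]
        s, e = min(r[1] for r in comp), max(r[2] for r in comp)
        member = frozenset(tp_order[tag] for *_, tag in comp)
        counts[member] = counts.get(member, 0) + 1
        rows.append(
            {
                "region_id": f"region{len(rows)}",
                "chrom": chrom,
                "start": s,
                "end": e,
                "membership": ",".join(sorted(member)),
            }
        )
    total = len(rows)
    unique = sum(v for k, v in counts.items() if len(k) == 1)
    constit = counts.get(frozenset(tp_order), 0) if tp_order else 0
    return TemporalSummary(
        regions=pd.DataFrame(
            rows, columns=["region_id", "chrom", "start", "end", "membership"]
        ),
        class_counts=counts,
        unique_fraction=unique / total if total else float("nan"),
        constitutive_fraction=constit / total if total else float("nan"),
    )


# ---------------------------------------------------------------------------
# nearest-gene assignment


class _ChromGenes:
    """Per-chromosome gene arrays with a fast nearest-gene query.

    Genes are sorted by start.  When they are pairwise disjoint (sorted ends
    are then also sorted), the nearest gene for any query interval is one of
    the two genes flanking the insertion point, which gives an O(log G) query;
    otherwise an exact dense scan over all genes is used.  Ties on edge gap
    are broken by the smaller distance to the TSS, then by lexicographic
    gene_id, so assignment is deterministic.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        order = np.argsort([g.span.start for g in genes], kind="stable")
        self.genes = [genes[i] for i in order]
        self.starts = np.array([g.span.start for g in self.genes], dtype=np.int64)
        self.ends = np.array([g.span.end for g in self.genes], dtype=np.int64)
        self.tss = np.array([g.tss for g in self.genes], dtype=np.int64)
        self.sign = np.array(
            [1 if g.strand == "+" else -1 for g in self.genes], dtype=np.int64
        )
        ids = [g.gene_id for g in self.genes]
        self.lex_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
        self.disjoint = bool(np.all(self.ends[:-1] <= self.starts[1:]))

    def _keys(self, cand, pstart, pend):
        """(gap, tss_gap, lex, signed) arrays for candidate gene indices."""
        gs, ge = self.starts[cand], self.ends[cand]
        gap = np.maximum(0, np.maximum(gs - pend, pstart - ge))
        tss = self.tss[cand]
        tss_gap = np.where(
            (tss >= pstart) & (tss < pend),
            0,
            np.minimum(np.abs(tss - pstart), np.abs(tss - (pend - 1))),
        )
        # side: -1 when the peak lies genomically left of the gene
        left_of_gene = pend <= gs
        right_of_gene = pstart >= ge
        side = np.where(left_of_gene, -1, np.where(right_of_gene, 1, 0))
        signed = gap * side * self.sign[cand]
        return gap, tss_gap, self.lex_rank[cand], signed

    def query(self, pstart: np.ndarray, pend: np.ndarray):
        """Nearest gene index and signed distance for each query interval."""
        n = len(pstart)
        if not self.genes:
            return np.full(n, -1), np.zeros(n, dtype=np.int64)
        if self.disjoint:
            # genes overlapping a query form the contiguous index range
            # [i0, j); the nearest gene is one of those or the two flanks
            i0 = np.searchsorted(self.ends, pstart, side="right")
            j = np.searchsorted(self.starts, pend, side="left")
            depth = int(np.max(j - i0)) + 2 if n else 2
            if depth <= 16:
                cands = np.stack(
                    [
                        np.clip(i0 - 1 + k, 0, len(self.genes) - 1)
                        for k in range(depth)
                    ]
                )
            else:  # unusually wide queries: fall back to the dense scan
                cands = np.broadcast_to(
                    np.arange(len(self.genes))[:, None], (len(self.genes), n)
                )
        else:
            cands = np.broadcast_to(
                np.arange(len(self.genes))[:, None], (len(self.genes), n)
            )
        big = np.iinfo(np.int64).max
        best_key = None
        best_idx = np.zeros(n, dtype=np.int64)
        best_signed = np.zeros(n, dtype=np.int64)
        for row in cands:
            gap, tss_gap, lex, signed = self._keys(row, pstart, pend)
            key = (gap.astype(np.int64), tss_gap.astype(np.int64), lex.astype(np.int64))
            if best_key is None:
                best_key = key
                best_idx, best_signed = row.copy(), signed
                continue
            better = (
                (key[0] < best_key[0])
                | ((key[0] == best_key[0]) & (key[1] < best_key[1]))
                | ((key[0] == best_key[0]) & (key[1] == best_key[1]) & (key[2] < best_key[2]))
            )
            for a, b in zip(best_key, key):
                np.copyto(a, b, where=better)
            np.copyto(best_idx, row, where=better)
            np.copyto(best_signed, signed, where=better)
        return best_idx, best_signed


def _genes_by_chrom(genes: Sequence[GeneModel]) -> Dict[str, _ChromGenes]:
    by: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by.setdefault(g.chrom, []).append(g)
    return {c: _ChromGenes(gs) for c, gs in by.items()}


def assign_nearest_gene(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    _index: Optional[Dict[str, _ChromGenes]] = None,
) -> pd.DataFrame:
    """Assign each peak to its closest gene.

    A peak overlapping a gene span gets that gene at signed distance 0;
    otherwise the gene minimizing the edge-to-edge gap wins, the distance
    signed negative upstream of the gene and positive downstream (relative to
    gene strand).  Peaks on chromosomes without genes are flagged with a
    missing gene_id.
    """
    index = _index if _index is not None else _genes_by_chrom(genes)
    rows = []
    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, ps in by_chrom.items():
        idx = index.get(chrom)
        if idx is None or not idx.genes:
            warnings.warn(f"no genes on chromosome {chrom!r}; peaks left unassigned")
            for p in ps:
                rows.append((p.peak_id, None, np.nan, True))
            continue
        pstart = np.array([p.start for p in ps], dtype=np.int64)
        pend = np.array([p.end for p in ps], dtype=np.int64)
        gi, signed = idx.query(pstart, pend)
        for p, g, d in zip(ps, gi, signed):
            rows.append((p.peak_id, idx.genes[g].gene_id, int(d), False))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "signed_distance", "unassigned"])


# ---------------------------------------------------------------------------
# peaks per gene and its Monte Carlo null


@dataclass(frozen=True)
class PeaksPerGene:
    histogram: Dict[int, int]
    mean: float
    fraction_multi: float  # associated genes with >= 2 peaks
    n_genes: int
    n_peaks: int


def peaks_per_gene(assignments: pd.DataFrame) -> PeaksPerGene:
    """Histogram and mean of peaks per associated gene (genes with >= 1 peak)."""
    assigned = assignments.dropna(subset=["gene_id"])
    counts = assigned.groupby("gene_id").size()
    if counts.empty:
        return PeaksPerGene({}, float("nan"), float("nan"), 0, 0)
    hist = counts.value_counts().sort_index()
    return PeaksPerGene(
        histogram={int(k): int(v) for k, v in hist.items()},
        mean=float(counts.mean()),
        fraction_multi=float((counts >= 2).mean()),
        n_genes=int(len(counts)),
        n_peaks=int(counts.sum()),
    )


@dataclass(frozen=True)
class PeaksPerGeneNull:
    observed_mean: float
    null_means: np.ndarray
    empirical_p: float
    iterations: int
    seed: int


def _place_random(
    widths: np.ndarray,
    chrom_names: List[str],
    chrom_lengths: np.ndarray,
    rng: np.random.Generator,
    exclude: Optional[Mapping[str, np.ndarray]] = None,
    max_tries: int = 100,
):
    """Place intervals of the given widths uniformly; chromosome chosen with
    probability proportional to its length; overlaps among placed intervals
    are allowed."""
    probs = chrom_lengths / chrom_lengths.sum()
    ci = rng.choice(len(chrom_names), size=len(widths), p=probs)
    fits = chrom_lengths[ci] >= widths
    for _ in range(max_tries):
        if fits.all():
            break
        redo = ~fits
        ci[redo] = rng.choice(len(chrom_names), size=int(redo.sum()), p=probs)
        fits = chrom_lengths[ci] >= widths
    if not fits.all():
        raise ValueError("some interval widths exceed every chromosome length")
    starts = rng.integers(0, chrom_lengths[ci] - widths + 1)
    if exclude:
        for _ in range(max_tries):
            bad = np.zeros(len(widths), dtype=bool)
            for k, c in enumerate(chrom_names):
                mask = ci == k
                if not mask.any() or c not in exclude:
                    continue
                ex = exclude[c]  # (n, 2) array of start, end
                s = starts[mask]
                e = s + widths[mask]
                hit = ((s[:, None] < ex[:, 1]) & (ex[:, 0] < e[:, None])).any(axis=1)
                bad[np.flatnonzero(mask)[hit]] = True
            if not bad.any():
                break
            starts[bad] = rng.integers(
                0, chrom_lengths[ci[bad]] - widths[bad] + 1
            )
    return ci, starts


def peaks_per_gene_null(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    iterations: int = 1000,
    seed: int = 0,
    exclude: Optional[Mapping[str, np.ndarray]] = None,
) -> PeaksPerGeneNull:
    """Monte Carlo null for peaks per associated gene.

    Each iteration places the same number of intervals with the observed width
    multiset uniformly at random (overlaps allowed; chromosome drawn with
    probability proportional to length), reassigns them to nearest genes, and
    records the mean peaks per associated gene.  The add-one estimator
    ``(count(null >= observed) + 1) / (iterations + 1)`` never reports zero.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if iterations < 20:
        warnings.warn(f"{iterations} iterations give an uninformative p-value")
    for p in peaks:
        if p.chrom not in chrom_sizes:
            raise ValueError(f"peak {p.peak_id} on chromosome absent from sizes")
        if p.end > chrom_sizes[p.chrom]:
            raise ValueError(f"peak {p.peak_id} extends beyond its chromosome")

    index = _genes_by_chrom(genes)
    observed = peaks_per_gene(assign_nearest_gene(peaks, genes, _index=index)).mean
    widths = np.array([p.width for p in peaks], dtype=np.int64)
    chrom_names = list(chrom_sizes)
    chrom_lengths = np.array([chrom_sizes[c] for c in chrom_names], dtype=np.int64)

    null_means = np.empty(iterations, dtype=float)
    for it in range(iterations):
        rng = stream(seed, "peaks_per_gene_null", it)
        ci, starts = _place_random(
            widths, chrom_names, chrom_lengths, rng, exclude=exclude
        )
        n_peaks_assigned = 0
        gene_hits = set()
        for k, chrom in enumerate(chrom_names):
            mask = ci == k
            if not mask.any():
                continue
            idx = index.get(chrom)
            if idx is None or not idx.genes:
                continue
            s = starts[mask]
            gi, _ = idx.query(s, s + widths[mask])
            n_peaks_assigned += int(mask.sum())
            gene_hits.update((chrom, int(g)) for g in gi)
        null_means[it] = n_peaks_assigned / len(gene_hits) if gene_hits else np.nan
    valid = null_means[~np.isnan(null_means)]
    p = (np.count_nonzero(valid >= observed) + 1) / (len(valid) + 1)
    return PeaksPerGeneNull(
        observed_mean=observed,
        null_means=null_means,
        empirical_p=float(p),
        iterations=iterations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# feature annotation


def annotate_feature(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_window: int = 500,
) -> pd.DataFrame:
    """Classify each peak as promoter, exon, intron, or intergenic.

    Precedence: promoter (overlap with [TSS - w, TSS + w) of any gene) >
    exon (overlap with any exonic base) > intron (overlap with a gene span
    but nothing above) > intergenic.  Exactly one category per peak.
    """
    if promoter_window <= 0:
        raise ValueError("promoter_window must be positive")
    proms: Dict[str, List[Tuple[int, int]]] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for g in genes:
        proms.setdefault(g.chrom, []).append(
            (max(0, g.tss - promoter_window), g.tss + promoter_window)
        )
        spans.setdefault(g.chrom, []).append((g.span.start, g.span.end))
        for ex in g.exons:
            exons.setdefault(g.chrom, []).append((ex.start, ex.end))

    def as_arr(d: Dict[str, List[Tuple[int, int]]]) -> Dict[str, np.ndarray]:
        return {c: np.array(v, dtype=np.int64) for c, v in d.items()}

    proms_a, exons_a, spans_a = as_arr(proms), as_arr(exons), as_arr(spans)

    def hits(arr: Optional[np.ndarray], s: int, e: int) -> bool:
        if arr is None or arr.size == 0:
            return False
        return bool(((s < arr[:, 1]) & (arr[:, 0] < e)).any())

    rows = []
    for p in peaks:
        s, e = p.start, p.end
        if hits(proms_a.get(p.chrom), s, e):
            cat = "promoter"
        elif hits(exons_a.get(p.chrom), s, e):
            cat = "exon"
        elif hits(spans_a.get(p.chrom), s, e):
            cat = "intron"
        else:
            cat = "intergenic"
        rows.append((p.peak_id, cat))
    return pd.DataFrame(rows, columns=["peak_id", "category"])


# ---------------------------------------------------------------------------
# distance profiles and width summaries


@dataclass(frozen=True)
class TSSDistanceProfile:
    distances: np.ndarray  # signed bp, one per peak with a TSS on its chromosome
    counts: np.ndarray
    bin_edges: np.ndarray


def tss_distance_profile(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    bin: int = 250,
    range_bp: int = 5000,
) -> TSSDistanceProfile:
    """Histogram of signed peak-center-to-nearest-TSS distances.

    The peak center is ``start + width // 2``; distance to the closest TSS on
    the same chromosome, signed by that gene's strand (negative = upstream of
    the TSS).  Ties between equidistant TSSs break by lexicographic gene_id.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_arr = {}
    for c, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.gene_id)
        tss_arr[c] = (
            np.array([g.tss for g in gs], dtype=np.int64),
            np.array([1 if g.strand == "+" else -1 for g in gs], dtype=np.int64),
        )
    dists = []
    for p in peaks:
        if p.chrom not in tss_arr:
            continue
        tss, sign = tss_arr[p.chrom]
        center = p.start + p.width // 2
        delta = center - tss
        best = np.flatnonzero(np.abs(delta) == np.abs(delta).min())[0]  # lex tie-break
        dists.append(int(delta[best] * sign[best]))
    d = np.array(dists, dtype=np.int64)
    edges = np.arange(-range_bp, range_bp + bin, bin)
    counts, _ = np.histogram(d, bins=edges)
    return TSSDistanceProfile(distances=d, counts=counts, bin_edges=edges)


def width_summary(peaks: Sequence[Peak]) -> Dict[str, float]:
    """Median and quartiles of peak widths."""
    w = np.array([p.width for p in peaks], dtype=float)
    if w.size == 0:
        return {"n": 0, "median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.percentile(w, [25, 50, 75])
    return {"n": int(w.size), "median": float(med), "q1": float(q1), "q3": float(q3)}
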