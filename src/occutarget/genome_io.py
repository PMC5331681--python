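"""Genomic file I/O and the coordinate conventions shared by the whole pipeline.

All in-memory coordinates are **0-based, half-open** (BED convention): an
interval ``[start, end)`` covers ``end - start`` basepairs.  GTF input, which
is 1-based and fully closed, is converted at parse time and converted back on
write.  The transcription start site (TSS) of a plus-strand gene is
``span.start``; for a minus-strand gene it is ``span.end - 1`` (the biological
5' base).

Chromosome names are taken verbatim from the input files; an optional alias
map can be applied by callers that need to reconcile naming schemes.

Every downstream module consumes only the validated types defined here —
nothing else in the package re-parses text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GenomeIOError",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CoverageTrack",
    "StrandedCoverage",
    "DERecord",
    "read_chrom_sizes",
    "read_peaks",
    "write_peaks",
    "read_genes",
    "write_genes_gtf",
    "write_genes_bed12",
    "read_de_table",
    "write_de_table",
    "read_coverage",
    "write_bedgraph",
    "write_tsv",
]

STRANDS = ("+", "-", ".")


class GenomeIOError(ValueError):
    """Raised for malformed genomic input (bad coordinates, broken invariants)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise GenomeIOError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared basepairs (0 if on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return self.overlap_bp(other) >= min_overlap


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq peak call: the atomic unit of binding evidence."""

    interval: GenomicInterval
    peak_id: str
    timepoint: str = "t1"
    replicate: str = "r1"
    enrichment: Optional[float] = None

    def __post_init__(self) -> None:
        if self.enrichment is not None and self.enrichment < 0:
            raise GenomeIOError(f"peak {self.peak_id}: negative enrichment")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand, derived TSS, and optional exon structure.

    ``exons`` is a base-level union: exons are pairwise non-overlapping,
    ordered by start, and contained in ``span``.
    """

    gene_id: str
    span: GenomicInterval
    exons: Tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.start < self.span.start or ex.end > self.span.end:
                raise GenomeIOError(
                    f"gene {self.gene_id}: exon {ex.chrom}:{ex.start}-{ex.end} "
                    "outside gene span"
                )
            if prev_end is not None and ex.start < prev_end:
                raise GenomeIOError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based position)."""
        return self.span.start if self.span.strand == "+" else self.span.end - 1

    @property
    def length(self) -> int:
        return self.span.width

    @property
    def exonic_bases(self) -> int:
        return sum(ex.width for ex in self.exons)


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-expression table (consumed, never produced)."""

    gene_id: str
    log2fc: float
    padj: Optional[float] = None

    def __post_init__(self) -> None:
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise GenomeIOError(f"{self.gene_id}: padj {self.padj} outside [0, 1]")


class CoverageTrack:
    """Per-chromosome read-density vectors (reads per basepair).

    Values are stored densely, one float per base.  Slices beyond the stored
    chromosome length read as zero, so genes near contig ends never raise.
    """

    def __init__(self, values: Mapping[str, np.ndarray], strand: Optional[str] = None):
        self._values: Dict[str, np.ndarray] = {}
        for chrom, arr in values.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 1:
                raise GenomeIOError(f"{chrom}: coverage vector must be 1-D")
            if np.any(a < 0):
                raise GenomeIOError(f"{chrom}: negative coverage values")
            self._values[chrom] = a
        if strand is not None and strand not in ("+", "-"):
            raise GenomeIOError(f"invalid track strand {strand!r}")
        self.strand = strand

    @property
    def chroms(self) -> List[str]:
        return list(self._values)

    def chrom_length(self, chrom: str) -> int:
        return len(self._values.get(chrom, ()))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base density over ``[start, end)``, zero-padded."""
        if start < 0 or end <= start:
            raise GenomeIOError(f"bad slice [{start}, {end})")
        arr = self._values.get(chrom)
        out = np.zeros(end - start, dtype=float)
        if arr is None:
            return out
        lo, hi = start, min(end, len(arr))
        if hi > lo:
            out[: hi - lo] = arr[lo:hi]
        return out

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Total reads (density integrated over bases) in ``[start, end)``."""
        return float(self.values(chrom, start, end).sum())

    def total(self) -> float:
        return float(sum(a.sum() for a in self._values.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        if factor < 0:
            raise GenomeIOError("scale factor must be nonnegative")
        return CoverageTrack(
            {c: a * factor for c, a in self._values.items()}, strand=self.strand
        )


@dataclass(frozen=True)
class StrandedCoverage:
    """A plus/minus pair of coverage tracks for strand-specific protocols."""

    plus: CoverageTrack
    minus: CoverageTrack

    def for_strand(self, strand: str) -> CoverageTrack:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise GenomeIOError(f"cannot pick a track for strand {strand!r}")


def coverage_for_strand(coverage, strand: str) -> CoverageTrack:
    """Resolve a CoverageTrack or StrandedCoverage to the track for ``strand``."""
    if isinstance(coverage, StrandedCoverage):
        return coverage.for_strand(strand)
    return coverage


# ---------------------------------------------------------------------------
# chrom sizes


def read_chrom_sizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise GenomeIOError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
        chrom, size = fields[0], int(fields[1])
        if size <= 0:
            raise GenomeIOError(f"{path}:{lineno}: nonpositive size for {chrom}")
        if chrom in sizes:
            raise GenomeIOError(f"{path}:{lineno}: duplicate chromosome {chrom}")
        sizes[chrom] = size
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# peaks (BED6 / ENCODE narrowPeak)

_SKIP_PREFIXES = ("#", "track", "browser")


def _check_chrom(chrom, end, chrom_sizes, path, lineno, warned: set) -> None:
    if chrom_sizes is None:
        return
    if chrom not in chrom_sizes:
        raise GenomeIOError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
    if end > chrom_sizes[chrom]:
        raise GenomeIOError(
            f"{path}:{lineno}: interval end {end} beyond {chrom} length "
            f"{chrom_sizes[chrom]}"
        )


def read_peaks(
    path,
    format: str = "bed6",
    timepoint: str = "t1",
    replicate: str = "r1",
    chrom_sizes: Optional[Mapping[str, int]] = None,
    known_chroms: Optional[Iterable[str]] = None,
) -> List[Peak]:
    """Read peak calls from a BED6 or ENCODE narrowPeak file.

    With ``chrom_sizes`` supplied, a peak on an unknown chromosome (or beyond
    the chromosome end) is a hard error; with only ``known_chroms`` it warns.
    Malformed coordinates always raise, naming the offending line.
    Input order is preserved.
    """
    if format not in ("bed6", "narrowPeak"):
        raise GenomeIOError(f"unknown peak format {format!r}")
    known = set(known_chroms) if known_chroms is not None else None
    peaks: List[Peak] = []
    seen_ids: set = set()
    warned: set = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(_SKIP_PREFIXES):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 3:
            raise GenomeIOError(f"{path}:{lineno}: fewer than 3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise GenomeIOError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise GenomeIOError(
                f"{path}:{lineno}: invalid coordinates {chrom}:{start}-{end}"
            )
        _check_chrom(chrom, end, chrom_sizes, path, lineno, warned)
        if known is not None and chrom not in known and chrom not in warned:
            warnings.warn(f"{path}:{lineno}: chromosome {chrom!r} not in known set")
            warned.add(chrom)
        name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else f"peak_{lineno}"
        strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
        enrichment = None
        if format == "narrowPeak":
            if len(fields) < 7:
                raise GenomeIOError(f"{path}:{lineno}: narrowPeak needs >= 7 columns")
            enrichment = float(fields[6])
        if name in seen_ids:
            raise GenomeIOError(
                f"{path}:{lineno}: duplicate peak_id {name!r} within "
                f"({timepoint}, {replicate})"
            )
        seen_ids.add(name)
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, end, strand),
                peak_id=name,
                timepoint=timepoint,
                replicate=replicate,
                enrichment=enrichment,
            )
        )
    return peaks


def write_peaks(peaks: Sequence[Peak], path, format: str = "bed6") -> None:
    if format not in ("bed6", "narrowPeak"):
        raise GenomeIOError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for pk in peaks:
            iv = pk.interval
            base = f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.peak_id}\t0\t{iv.strand}"
            if format == "bed6":
                fh.write(base + "\n")
            else:
                enr = pk.enrichment if pk.enrichment is not None else 0.0
                fh.write(base + f"\t{enr:g}\t-1\t-1\t-1\n")


# ---------------------------------------------------------------------------
# gene models (GTF / BED12)


def _merge_intervals(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Base-level union of (start, end) pairs."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_genes(path, format: str = "gtf") -> List[GeneModel]:
    """Read gene models from GTF or BED12; one GeneModel per unique gene_id.

    Exons repeated across transcripts are collapsed to their base-level union.
    A gene whose exons fall outside its span is a hard error.
    """
    if format == "gtf":
        return _read_genes_gtf(path)
    if format == "bed12":
        return _read_genes_bed12(path)
    raise GenomeIOError(f"unknown gene format {format!r}")


def _read_genes_gtf(path) -> List[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: List[GeneModel] = []
    gene_features = list(db.features_of_type("gene"))
    if gene_features:
        for g in gene_features:
            gid = g.attributes.get("gene_id", [g.id])[0]
            span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
            exon_ivs = _merge_intervals(
                [(ex.start - 1, ex.end) for ex in db.children(g, featuretype="exon")]
            )
            exons = tuple(
                GenomicInterval(g.seqid, s, e, g.strand) for s, e in exon_ivs
            )
            genes.append(GeneModel(gid, span, exons))
    else:
        # dialect without explicit gene features: derive spans from exons
        by_gene: Dict[str, List] = {}
        for ex in db.features_of_type("exon"):
            gid = ex.attributes.get("gene_id", [None])[0]
            if gid is None:
                raise GenomeIOError(f"{path}: exon without gene_id")
            by_gene.setdefault(gid, []).append(ex)
        for gid, exs in by_gene.items():
            chrom, strand = exs[0].seqid, exs[0].strand
            ivs = _merge_intervals([(e.start - 1, e.end) for e in exs])
            span = GenomicInterval(chrom, ivs[0][0], ivs[-1][1], strand)
            genes.append(
                GeneModel(
                    gid,
                    span,
                    tuple(GenomicInterval(chrom, s, e, strand) for s, e in ivs),
                )
            )
    return genes


def _read_genes_bed12(path) -> List[GeneModel]:
    rows: Dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(_SKIP_PREFIXES):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise GenomeIOError(f"{path}:{lineno}: BED12 needs 12 columns")
        chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
        if start < 0 or start >= end:
            raise GenomeIOError(f"{path}:{lineno}: invalid coordinates")
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise GenomeIOError(f"{path}:{lineno}: blockCount mismatch")
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        if any(e > end for _, e in exons):
            raise GenomeIOError(f"{path}:{lineno}: block extends past chromEnd")
        rec = rows.setdefault(
            name, {"chrom": chrom, "strand": strand, "start": start, "end": end, "exons": []}
        )
        if rec["chrom"] != chrom or rec["strand"] != strand:
            raise GenomeIOError(
                f"{path}:{lineno}: gene {name!r} repeated on a different "
                "chromosome or strand"
            )
        rec["start"] = min(rec["start"], start)
        rec["end"] = max(rec["end"], end)
        rec["exons"].extend(exons)
    genes = []
    for gid, rec in rows.items():
        ivs = _merge_intervals(rec["exons"])
        span = GenomicInterval(rec["chrom"], rec["start"], rec["end"], rec["strand"])
        genes.append(
            GeneModel(
                gid,
                span,
                tuple(GenomicInterval(rec["chrom"], s, e, rec["strand"]) for s, e in ivs),
            )
        )
    return genes


def write_genes_gtf(genes: Sequence[GeneModel], path, source: str = "occutarget") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def write_genes_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or (g.span,)
            sizes = ",".join(str(ex.width) for ex in exons) + ","
            offsets = ",".join(str(ex.start - g.span.start) for ex in exons) + ","
            fh.write(
                f"{g.chrom}\t{g.span.start}\t{g.span.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.span.start}\t{g.span.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# differential-expression tables


def read_de_table(path) -> pd.DataFrame:
    """Read a DE table (TSV with header) into columns gene_id, log2fc, padj.

    Accepts either ``log2fc`` or DESeq2's ``log2FoldChange`` column name.
    Missing padj ('.' or empty) becomes NaN.  Duplicate gene_ids are an error.
    """
    df = pd.read_csv(path, sep="\t", na_values=[".", ""], dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols:
        raise GenomeIOError(f"{path}: no gene_id column")
    lfc_col = cols.get("log2fc") or cols.get("log2foldchange")
    if lfc_col is None:
        raise GenomeIOError(f"{path}: no log2fc / log2FoldChange column")
    if "padj" not in cols:
        raise GenomeIOError(f"{path}: no padj column")
    out = pd.DataFrame(
        {
            "gene_id": df[cols["gene_id"]].astype(str),
            "log2fc": pd.to_numeric(df[lfc_col]),
            "padj": pd.to_numeric(df[cols["padj"]]),
        }
    )
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise GenomeIOError(f"{path}: duplicate gene_id {dup!r}")
    if out["log2fc"].isna().any():
        raise GenomeIOError(f"{path}: missing log2fc values")
    bad = out["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise GenomeIOError(f"{path}: padj outside [0, 1]")
    return out


def write_de_table(df: pd.DataFrame, path) -> None:
    write_tsv(df, path)


# ---------------------------------------------------------------------------
# bedGraph coverage


def read_coverage(
    path,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    strand: Optional[str] = None,
) -> CoverageTrack:
    """Read a bedGraph into a dense per-base CoverageTrack.

    Overlapping bedGraph intervals are a hard error; gaps read as zero.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(_SKIP_PREFIXES):
            continue
        f = line.split()
        if len(f) < 4:
            raise GenomeIOError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        if start < 0 or start >= end:
            raise GenomeIOError(f"{path}:{lineno}: invalid coordinates")
        if value < 0:
            raise GenomeIOError(f"{path}:{lineno}: negative coverage")
        rows.append((chrom, start, end, value))
    by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    for chrom, start, end, value in rows:
        by_chrom.setdefault(chrom, []).append((start, end, value))
    values: Dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise GenomeIOError(
                    f"{path}: overlapping bedGraph intervals on {chrom} at {s2}"
                )
        length = chrom_sizes[chrom] if chrom_sizes else ivs[-1][1]
        if ivs[-1][1] > length:
            raise GenomeIOError(
                f"{path}: coverage on {chrom} beyond stated length {length}"
            )
        arr = np.zeros(length, dtype=float)
        for s, e, v in ivs:
            arr[s:e] = v
        values[chrom] = arr
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            values.setdefault(chrom, np.zeros(size, dtype=float))
    return CoverageTrack(values, strand=strand)


def write_bedgraph(track: CoverageTrack, path, decimals: int = 6) -> None:
    """Write a CoverageTrack as bedGraph, run-length collapsing equal values.

    Zero runs are omitted (bedGraph gaps read back as zero).
    """
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = np.round(track.values(chrom, 0, track.chrom_length(chrom)), decimals)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# generic TSV


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV with header, '.' for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep=".")
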