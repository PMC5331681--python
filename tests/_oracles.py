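"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written the slow, obviously-correct way (all-pairs scans,
per-base loops, exact tail enumeration) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Set, Tuple


def components_bruteforce(
    records: Sequence[Tuple[str, int, int, int]], min_overlap: int
) -> List[List[Tuple[str, int, int, int]]]:
    """Connected components under pairwise overlap >= min_overlap (union-find)."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        ci, si, ei, _ = records[i]
        for j in range(i + 1, n):
            cj, sj, ej, _ = records[j]
            if ci == cj and min(ei, ej) - max(si, sj) >= min_overlap:
                union(i, j)
    comps: Dict[int, List] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(records[i])
    return list(comps.values())


def intersect_bruteforce(
    rep_a: Sequence[Tuple[str, int, int]],
    rep_b: Sequence[Tuple[str, int, int]],
    min_overlap: int = 1,
) -> Set[Tuple[str, int, int]]:
    """Reproducible merged spans via the all-pairs component scan."""
    records = [(c, s, e, 0) for c, s, e in rep_a] + [(c, s, e, 1) for c, s, e in rep_b]
    out = set()
    for comp in components_bruteforce(records, min_overlap):
        if {tag for *_, tag in comp} == {0, 1}:
            out.add(
                (comp[0][0], min(r[1] for r in comp), max(r[2] for r in comp))
            )
    return out


def nearest_gene_bruteforce(
    peak: Tuple[str, int, int],
    genes: Sequence[Tuple[str, str, int, int, str]],  # (gene_id, chrom, start, end, strand)
) -> Optional[Tuple[str, int]]:
    """(gene_id, signed_distance) by exhaustive scan; None if no gene on chrom."""
    pc, ps, pe = peak
    best = None
    for gid, gc, gs, ge, strand in genes:
        if gc != pc:
            continue
        gap = max(0, gs - pe, ps - ge)
        tss = gs if strand == "+" else ge - 1
        tss_gap = 0 if ps <= tss < pe else min(abs(tss - ps), abs(tss - (pe - 1)))
        key = (gap, tss_gap, gid)
        if best is None or key < best[0]:
            if pe <= gs:
                side = -1
            elif ps >= ge:
                side = 1
            else:
                side = 0
            sign = 1 if strand == "+" else -1
            best = (key, gid, gap * side * sign)
    return None if best is None else (best[1], best[2])


def annotate_bruteforce(
    peak: Tuple[str, int, int],
    genes: Sequence[Tuple[str, str, int, int, str, List[Tuple[int, int]]]],
    promoter_window: int,
) -> str:
    """Feature category by scanning every gene and exon."""
    pc, ps, pe = peak

    def overlaps(s, e):
        return ps < e and s < pe

    is_prom = is_exon = is_intron = False
    for gid, gc, gs, ge, strand, exons in genes:
        if gc != pc:
            continue
        tss = gs if strand == "+" else ge - 1
        if overlaps(max(0, tss - promoter_window), tss + promoter_window):
            is_prom = True
        if any(overlaps(s, e) for s, e in exons):
            is_exon = True
        if overlaps(gs, ge):
            is_intron = True
    if is_prom:
        return "promoter"
    if is_exon:
        return "exon"
    if is_intron:
        return "intron"
    return "intergenic"


def peak_score_bruteforce(
    peak: Tuple[int, int],
    gene: Tuple[int, int],
    steepness: float = 5e-4,
    offset: float = 15.0,
    overlap_score: float = 1.0,
    d0: int = 1,
) -> float:
    """Mean per-base score by looping over every base of the peak."""
    p0, p1 = peak
    g0, g1 = gene
    total = 0.0
    for x in range(p0, p1):
        if g0 <= x < g1:
            total += overlap_score
        else:
            if x < g0:
                d = g0 - x - (1 - d0)
            else:
                d = x - g1 + d0
            total += 1.0 / (1.0 + math.exp(steepness * (d - offset)))
    return total / (p1 - p0)


def response_curve_bruteforce(
    scores: Dict[str, float], de_set: Set[str], thresholds: Sequence[float]
) -> List[Tuple[int, int]]:
    """(n_above, n_de_above) per cutoff via a double loop."""
    out = []
    for c in thresholds:
        n_above = sum(1 for v in scores.values() if v >= c)
        n_de = sum(1 for g, v in scores.items() if v >= c and g in de_set)
        out.append((n_above, n_de))
    return out


def hypergeom_tail_bruteforce(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric draw, by direct enumeration."""
    total = 0.0
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / denom
    return total
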