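"""Call high-confidence direct targets by integrating occupancy scores with
differential expression.

For each timepoint, genes are ranked by occupancy score and, under a
progressively relaxing score cutoff, the number of differentially expressed
genes among those above the cutoff is traced out (the *response curve*).
The same curve computed on random gene sets of matched size — averaged over
repetitions — gives the baseline expected by chance.  Where the experimental
curve shows a clear change of slope (detected with a continuous two-segment
piecewise-linear fit) and stands well clear of the baseline, the cutoff at
the breakpoint defines the high-confidence target set: genes above the
threshold that are also differentially expressed in the stated direction.
The default direction is down-regulation under corepressor overexpression,
the signal with usable dynamic range; up-regulated and loss-of-function
curves typically do not separate from their baselines and yield
"none detected".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._rng import stream

__all__ = [
    "DEThresholds",
    "ResponseCurve",
    "TargetCallResult",
    "CallTargetsResult",
    "classify_de",
    "response_curve",
    "randomized_baseline",
    "build_response_curve",
    "detect_inflection",
    "call_targets",
]


@dataclass(frozen=True)
class DEThresholds:
    """Differential-expression call thresholds.

    ``min_abs_log2fc`` is inclusive (a magnitude of exactly 0.5 qualifies);
    ``alpha`` is strict (padj must be < alpha).
    """

    min_abs_log2fc: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def classify_de(
    de: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> Dict[str, Set[str]]:
    """Split a DE table into down- and up-regulated gene sets.

    Genes with missing padj (unexpressed / independent-filtering casualties)
    are excluded from both sets.
    """
    ok = de["padj"].notna() & (de["padj"] < thresholds.alpha)
    down = ok & (de["log2fc"] <= -thresholds.min_abs_log2fc)
    up = ok & (de["log2fc"] >= thresholds.min_abs_log2fc)
    return {
        "down": set(de.loc[down, "gene_id"]),
        "up": set(de.loc[up, "gene_id"]),
    }


@dataclass
class ResponseCurve:
    """Experimental and randomized-baseline response curves.

    ``thresholds`` are descending score cutoffs; at cutoff ``c``, ``n_above``
    counts genes with score >= c and ``n_de_above`` those that are also DE in
    ``direction``.  ``baseline_mean``/``baseline_sd`` are per-cutoff
    statistics of ``n_de_above`` over ``n_baseline_reps`` random gene sets of
    the same size as the DE set.
    """

    thresholds: np.ndarray
    n_above: np.ndarray
    n_de_above: np.ndarray
    direction: str = "down"
    baseline_mean: Optional[np.ndarray] = None
    baseline_sd: Optional[np.ndarray] = None
    n_baseline_reps: int = 0
    n_universe: int = 0
    set_size: int = 0

    def to_frame(self) -> pd.DataFrame:
        data = {
            "threshold": self.thresholds,
            "n_above": self.n_above,
            "n_de_above": self.n_de_above,
        }
        if self.baseline_mean is not None:
            data["baseline_mean"] = self.baseline_mean
            data["baseline_sd"] = self.baseline_sd
        return pd.DataFrame(data)


def _score_map(scores: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    return scores["score"].to_numpy(dtype=float), list(scores["gene_id"])


def _curve_thresholds(score_values: np.ndarray, grid) -> np.ndarray:
    if grid is not None:
        thr = np.asarray(sorted(set(float(g) for g in grid), reverse=True), dtype=float)
        if thr.size == 0:
            raise ValueError("empty cutoff grid")
        return thr
    pos = np.unique(score_values[score_values > 0])
    return pos[::-1].astype(float)


def _counts_at_thresholds(values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """count(values >= c) for each descending cutoff c."""
    s = np.sort(values)
    return len(values) - np.searchsorted(s, thresholds, side="left")


def response_curve(
    scores: pd.DataFrame,
    de_set: Set[str],
    grid=None,
    direction: str = "down",
) -> ResponseCurve:
    """Experimental arm: DE genes among genes above each score cutoff.

    By default the cutoff grid is every distinct positive score, so the curve
    is exact; an explicit grid may be passed instead.
    """
    values, gene_ids = _score_map(scores)
    thresholds = _curve_thresholds(values, grid)
    if not de_set:
        warnings.warn("empty DE set: response curve is identically zero")
    de_mask = np.fromiter((g in de_set for g in gene_ids), dtype=bool, count=len(gene_ids))
    return ResponseCurve(
        thresholds=thresholds,
        n_above=_counts_at_thresholds(values, thresholds),
        n_de_above=_counts_at_thresholds(values[de_mask], thresholds),
        direction=direction,
        n_universe=len(gene_ids),
        set_size=int(de_mask.sum()),
    )


def randomized_baseline(
    scores: pd.DataFrame,
    set_size: int,
    n_reps: int = 100,
    seed: int = 0,
    grid=None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline arm: per-cutoff mean and sd of n_de_above over random sets.

    Each repetition samples ``set_size`` genes uniformly without replacement
    from the scored universe and recomputes the curve.  Returns
    (thresholds, mean, sd).
    """
    values, gene_ids = _score_map(scores)
    n = len(gene_ids)
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds scored universe {n}")
    thresholds = _curve_thresholds(values, grid)
    acc = np.zeros(thresholds.size)
    acc2 = np.zeros(thresholds.size)
    for rep in range(n_reps):
        rng = stream(seed, "randomized_baseline", rep)
        pick = rng.choice(n, size=set_size, replace=False)
        c = _counts_at_thresholds(values[pick], thresholds)
        acc += c
        acc2 += c.astype(float) ** 2
    mean = acc / n_reps
    var = np.maximum(acc2 / n_reps - mean**2, 0.0)
    return thresholds, mean, np.sqrt(var)


def build_response_curve(
    scores: pd.DataFrame,
    de_set: Set[str],
    n_reps: int = 100,
    seed: int = 0,
    grid=None,
    direction: str = "down",
) -> ResponseCurve:
    """Experimental curve plus its matched randomized baseline."""
    curve = response_curve(scores, de_set, grid=grid, direction=direction)
    if curve.set_size > 0 and curve.thresholds.size > 0:
        _, mean, sd = randomized_baseline(
            scores, curve.set_size, n_reps=n_reps, seed=seed, grid=curve.thresholds
        )
        curve.baseline_mean, curve.baseline_sd = mean, sd
        curve.n_baseline_reps = n_reps
    return curve


@dataclass
class TargetCallResult:
    """Outcome of inflection detection on one response curve.

    ``threshold_score`` is None when no clear change of slope was detected
    (the curve is indistinguishable from a single line, or does not separate
    from the baseline).
    """

    threshold_score: Optional[float]
    breakpoint_index: int = -1
    fit_sse: float = float("nan")
    single_line_sse: float = float("nan")
    separation: float = float("nan")
    targets: Set[str] = field(default_factory=set)

    @property
    def detected(self) -> bool:
        return self.threshold_score is not None


def _two_segment_fit(y: np.ndarray, min_segment_points: int):
    """Continuous two-segment piecewise-linear least squares on (index, y).

    Exhaustive breakpoint search; the model is y = a + b*x + c*max(0, x - k).
    Returns (best_k, best_sse, single_sse).
    """
    m = y.size
    x = np.arange(m, dtype=float)
    A1 = np.column_stack([np.ones(m), x])
    coef1 = np.linalg.lstsq(A1, y, rcond=None)[0]
    single_sse = float(np.sum((y - A1 @ coef1) ** 2))
    best_k, best_sse = -1, np.inf
    for k in range(min_segment_points - 1, m - min_segment_points + 1):
        A = np.column_stack([np.ones(m), x, np.maximum(0.0, x - k)])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((y - A @ coef) ** 2))
        if sse < best_sse:
            best_k, best_sse = k, sse
    return best_k, best_sse, single_sse


def detect_inflection(
    curve: ResponseCurve,
    min_separation: float = 2.0,
    min_sse_improvement: float = 0.2,
    min_segment_points: int = 3,
) -> TargetCallResult:
    """Locate the change of slope in a response curve, if clearly evident.

    The curve is fit in rank space (cutoff rank index vs n_de_above) with a
    continuous two-segment piecewise-linear model by exhaustive breakpoint
    search.  A threshold is declared only when (a) the two-segment fit
    improves on a single line by at least ``min_sse_improvement`` (fraction
    of SSE) and (b) the experimental count at the breakpoint is at least
    ``min_separation`` times the randomized-baseline mean there.  Otherwise
    the result is "none detected".
    """
    y = np.asarray(curve.n_de_above, dtype=float)
    if y.size < 2 * min_segment_points + 2:
        raise ValueError(
            f"curve has {y.size} cutoffs; need >= {2 * min_segment_points + 2}"
        )
    k, sse, single_sse = _two_segment_fit(y, min_segment_points)
    result = TargetCallResult(
        threshold_score=None,
        breakpoint_index=k,
        fit_sse=sse,
        single_line_sse=single_sse,
    )
    # flat or (numerically) perfectly linear curve: nothing to detect
    if single_sse <= 1e-9 * max(1.0, float(np.sum(y**2))):
        return result
    if sse > (1.0 - min_sse_improvement) * single_sse:
        return result
    if curve.baseline_mean is not None:
        base = float(curve.baseline_mean[k])
        sep = y[k] / base if base > 0 else np.inf
        result.separation = sep
        if sep < min_separation:
            return result
    result.threshold_score = float(curve.thresholds[k])
    return result


def _targets_at_threshold(
    scores: pd.DataFrame, de_set: Set[str], threshold: float
) -> Set[str]:
    above = set(scores.loc[scores["score"] >= threshold, "gene_id"])
    return above & de_set


@dataclass
class CallTargetsResult:
    """Per-timepoint curves/thresholds and the union target set."""

    per_timepoint: Dict[str, Tuple[ResponseCurve, TargetCallResult]]
    union: Set[str]
    table: pd.DataFrame  # gene_id, timepoints, score, log2fc, padj


def call_targets(
    scores_by_tp: Mapping[str, pd.DataFrame],
    de_by_tp: Mapping[str, pd.DataFrame],
    direction: str = "down",
    thresholds: DEThresholds = DEThresholds(),
    n_reps: int = 100,
    seed: int = 0,
    min_separation: float = 2.0,
) -> CallTargetsResult:
    """Full target call across timepoints.

    Per timepoint: classify DE, build the response curve with its randomized
    baseline, detect the inflection, and collect genes above the threshold
    that are DE in ``direction``.  The final set is the union over
    timepoints; a timepoint with "none detected" contributes nothing.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    per_tp: Dict[str, Tuple[ResponseCurve, TargetCallResult]] = {}
    union: Set[str] = set()
    rows = []
    for tp in scores_by_tp:
        scores = scores_by_tp[tp]
        de = de_by_tp[tp]
        de_set = classify_de(de, thresholds)[direction]
        curve = build_response_curve(
            scores, de_set, n_reps=n_reps, seed=seed, direction=direction
        )
        if curve.thresholds.size >= 8:
            call = detect_inflection(curve, min_separation=min_separation)
        else:
            call = TargetCallResult(threshold_score=None)
        if call.detected:
            call.targets = _targets_at_threshold(scores, de_set, call.threshold_score)
            union |= call.targets
            de_idx = de.set_index("gene_id")
            smap = dict(zip(scores["gene_id"], scores["score"]))
            for g in sorted(call.targets):
                rows.append(
                    {
                        "gene_id": g,
                        "timepoint": tp,
                        "score": smap.get(g, np.nan),
                        "log2fc": de_idx.loc[g, "log2fc"],
                        "padj": de_idx.loc[g, "padj"],
                    }
                )
        per_tp[tp] = (curve, call)
    if rows:
        long = pd.DataFrame(rows)
        table = (
            long.groupby("gene_id")
            .agg(
                timepoints=("timepoint", lambda s: ",".join(sorted(s))),
                score=("score", "max"),
                log2fc=("log2fc", "mean"),
                padj=("padj", "min"),
            )
            .reset_index()
        )
    else:
        table = pd.DataFrame(columns=["gene_id", "timepoints", "score", "log2fc", "padj"])
    return CallTargetsResult(per_timepoint=per_tp, union=union, table=table)
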