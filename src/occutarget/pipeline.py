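"""Convenience workflow helpers chaining the pipeline stages.

These are thin compositions of the per-module operations, used by the CLI,
the examples, and anyone who wants the standard peaks -> reproducible sets ->
occupancy scores -> target call flow in one call.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence, Tuple

import pandas as pd

from .genome_io import GeneModel, Peak
from .occupancy_scoring import DEFAULT_PARAMS, ScoringParameters, score_all_genes
from .peak_analysis import ReproduciblePeakSet, intersect_replicates
from .synthetic_data import REPLICATES, TIMEPOINTS, SyntheticDataset
from .target_calling import CallTargetsResult, DEThresholds, call_targets

__all__ = ["reproducible_sets", "score_timepoints", "call_targets_from_dataset"]


def reproducible_sets(
    peaks: Mapping[Tuple[str, str], Sequence[Peak]],
    min_overlap: int = 1,
) -> Dict[str, ReproduciblePeakSet]:
    """Replicate-intersect each timepoint's two replicates."""
    out = {}
    for tp in TIMEPOINTS:
        out[tp] = intersect_replicates(
            list(peaks[(tp, REPLICATES[0])]),
            list(peaks[(tp, REPLICATES[1])]),
            min_overlap=min_overlap,
        )
    return out


def score_timepoints(
    genes: Sequence[GeneModel],
    sets: Mapping[str, ReproduciblePeakSet],
    params: ScoringParameters = DEFAULT_PARAMS,
) -> Dict[str, pd.DataFrame]:
    """Occupancy-score every gene against each timepoint's reproducible set."""
    return {tp: score_all_genes(genes, s, params, timepoint=tp) for tp, s in sets.items()}


def call_targets_from_dataset(
    ds: SyntheticDataset,
    params: ScoringParameters = DEFAULT_PARAMS,
    thresholds: DEThresholds = DEThresholds(),
    direction: str = "down",
    n_reps: int = 100,
    seed: int = 0,
    min_separation: float = 2.0,
) -> Tuple[Dict[str, pd.DataFrame], CallTargetsResult]:
    """Run the full binding+expression integration on a synthetic dataset."""
    sets = reproducible_sets(ds.peaks)
    scores = score_timepoints(ds.genes, sets, params)
    result = call_targets(
        scores,
        ds.de,
        direction=direction,
        thresholds=thresholds,
        n_reps=n_reps,
        seed=seed,
        min_separation=min_separation,
    )
    return scores, result
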