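"""Experiment harness: parameter sweeps, headline scenarios, error reports.

Mirrors the simulation study design: a noiseless reference database is
built once per charge-filter setting; noisy reads are then generated for a
query set (a random subset for sweeps, every protein for headline runs) and
classified against the full database; accuracy and per-length breakdowns
are reported, with replicate spread for sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentParams, FusionDirection, GapVariant
from .classification import ClassificationResult, classify_batch, evaluate_accuracy
from .digestion import FingerprintDB, SimParams, build_database, digest

__all__ = [
    "LOW_NOISE",
    "HIGH_NOISE",
    "SweepSpec",
    "run_condition",
    "run_sweep",
    "summarize_sweep",
    "run_headline",
    "misclassification_report",
]

#: Close-to-ideal measuring circumstances.
LOW_NOISE = SimParams(e_p=0.99, C=0.99, r=5.0)
#: Resolution twice as coarse as attainable, 10% of sites and fragments lost.
HIGH_NOISE = SimParams(e_p=0.90, C=0.90, r=10.0)


def _alignment_params(
    params: SimParams,
    gap_variant: GapVariant = "squared",
    fusion_direction: FusionDirection = "both",
) -> AlignmentParams:
    return AlignmentParams.from_resolution(
        params.r, L=params.lower_limit,
        gap_variant=gap_variant, fusion_direction=fusion_direction,
    )


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter-at-a-time noise sweep with replicates."""

    varied_parameter: Literal["r", "C", "e_p"]
    values: tuple[float, ...]
    fixed_params: SimParams = LOW_NOISE
    n_replicates: int = 5
    n_queries: int = 200
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for v in self.values:
            if self.varied_parameter in ("C", "e_p") and not 0 <= v <= 1:
                raise ValueError(f"{self.varied_parameter} values must be in [0, 1]")
            if self.varied_parameter == "r" and v < 0:
                raise ValueError("r values must be non-negative")

    def conditions(self) -> list[SimParams]:
        return [replace(self.fixed_params, **{self.varied_parameter: v}) for v in self.values]


def run_condition(
    proteome: Sequence[tuple[str, str]],
    query_ids: Sequence[str],
    params: SimParams,
    db: FingerprintDB,
    replicate_seeds: Sequence[int],
    gap_variant: GapVariant = "squared",
    fusion_direction: FusionDirection = "both",
) -> tuple[list[float], list[list[ClassificationResult]]]:
    """Noisy reads of the chosen queries, classified; one pass per replicate.

    Returns per-replicate accuracies and the full classification results.
    Identity of a query is its own protein id, so ``correct`` is recorded
    directly on each result.
    """
    seqs = dict(proteome)
    missing = [q for q in query_ids if q not in seqs]
    if missing:
        raise KeyError(f"query ids not in proteome: {missing[:5]}")
    aln = _alignment_params(params, gap_variant, fusion_direction)
    truths = {q: q for q in query_ids}
    accuracies: list[float] = []
    all_results: list[list[ClassificationResult]] = []
    for rep, seed in enumerate(replicate_seeds):
        rep_params = replace(params, seed=int(seed))
        queries = [digest(q, seqs[q], rep_params, replicate=rep) for q in query_ids]
        results = classify_batch(queries, db, aln, truths=truths)
        acc, _ = evaluate_accuracy(results, truths)
        accuracies.append(acc)
        all_results.append(results)
    return accuracies, all_results


def run_sweep(
    proteome: Sequence[tuple[str, str]],
    spec: SweepSpec,
    db: FingerprintDB | None = None,
    gap_variant: GapVariant = "squared",
    fusion_direction: FusionDirection = "both",
) -> pd.DataFrame:
    """Accuracy per condition and replicate, long format.

    The query subset is drawn once with the base seed and reused across all
    conditions; replicate seeds are derived from the base seed. Columns:
    parameter, value, replicate, accuracy.
    """
    if db is None:
        db = build_database(proteome, spec.fixed_params)
    rng = np.random.default_rng(spec.base_seed)
    ids = [pid for pid, _ in proteome]
    n_q = min(spec.n_queries, len(ids))
    query_ids = [ids[i] for i in rng.choice(len(ids), size=n_q, replace=False)]
    replicate_seeds = rng.integers(0, 2**31 - 1, size=spec.n_replicates)
    rows = []
    for value, params in zip(spec.values, spec.conditions()):
        accs, _ = run_condition(
            proteome, query_ids, params, db, replicate_seeds,
            gap_variant, fusion_direction,
        )
        for rep, acc in enumerate(accs):
            rows.append(
                {
                    "parameter": spec.varied_parameter,
                    "value": value,
                    "replicate": rep,
                    "accuracy": acc,
                }
            )
    return pd.DataFrame(rows)


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd accuracy per condition (replicate spread)."""
    return (
        sweep.groupby(["parameter", "value"])["accuracy"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "accuracy_mean", "std": "accuracy_sd"})
    )


def run_headline(
    proteome: Sequence[tuple[str, str]],
    scenario: Literal["low", "high"] | SimParams = "low",
    charge_filter: bool = False,
    seed: int = 0,
    gap_variant: GapVariant = "squared",
    fusion_direction: FusionDirection = "both",
    bin_width: int = 250,
) -> tuple[float, pd.DataFrame, list[ClassificationResult]]:
    """One noisy read per proteome constituent against the full noiseless DB.

    Returns (accuracy, per-length histogram table, classification results).
    """
    if isinstance(scenario, SimParams):
        params = scenario
    else:
        params = {"low": LOW_NOISE, "high": HIGH_NOISE}[scenario]
    params = replace(params, charge_filter=charge_filter, seed=seed)
    db = build_database(proteome, params)
    aln = _alignment_params(params, gap_variant, fusion_direction)
    truths = {pid: pid for pid, _ in proteome}
    lengths = {pid: len(seq) for pid, seq in proteome}
    queries = [digest(pid, seq, params) for pid, seq in proteome]
    results = classify_batch(queries, db, aln, truths=truths)
    accuracy, hist = evaluate_accuracy(results, truths, lengths, bin_width=bin_width)
    return accuracy, hist, results


def misclassification_report(
    results: Sequence[ClassificationResult],
    lengths: Mapping[str, int],
    length_threshold: int = 250,
) -> tuple[pd.DataFrame, float | None]:
    """Misclassified queries with their lengths, and the short-query share.

    Returns the table (query_id, predicted_id, query_length) and the
    fraction of misclassifications shorter than ``length_threshold``
    residues (None when there are no misclassifications).
    """
    rows = [
        {
            "query_id": res.query_id,
            "predicted_id": res.predicted_id,
            "query_length": lengths[res.query_id],
        }
        for res in results
        if res.correct is False
    ]
    table = pd.DataFrame(rows, columns=["query_id", "predicted_id", "query_length"])
    if len(table) == 0:
        return table, None
    frac = float((table["query_length"] < length_threshold).mean())
    return table, frac
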