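"""Nearest-fingerprint identification against a noiseless reference database."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentParams, align_matrix
from .digestion import Fingerprint, FingerprintDB

__all__ = [
    "UNCLASSIFIED",
    "ClassificationResult",
    "classify",
    "classify_batch",
    "evaluate_accuracy",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    predicted_id: str
    distance: float
    n_ties: int
    correct: bool | None = None

    @property
    def classified(self) -> bool:
        return self.predicted_id != UNCLASSIFIED


def _from_distances(
    query_id: str, distances: np.ndarray, db_ids: Sequence[str], truth: str | None
) -> ClassificationResult:
    finite = np.isfinite(distances)
    if not finite.any():
        return ClassificationResult(
            query_id, UNCLASSIFIED, np.inf, 0,
            correct=None if truth is None else False,
        )
    best = distances[finite].min()
    tied = np.flatnonzero(distances == best)
    predicted = db_ids[tied[0]]  # ties broken by database order
    return ClassificationResult(
        query_id,
        predicted,
        float(best),
        int(len(tied)),
        correct=None if truth is None else predicted == truth,
    )


def classify(
    query: Fingerprint,
    db: FingerprintDB,
    params: AlignmentParams,
    truth: str | None = None,
) -> ClassificationResult:
    """Assign ``query`` the identity of the nearest database fingerprint.

    An empty query, or one infeasible against every entry, comes back as
    ``unclassified`` (counted as incorrect by :func:`evaluate_accuracy`).
    Ties on the minimal distance are broken by database order and reported
    in ``n_ties``.
    """
    if len(db) == 0:
        raise ValueError("database is empty")
    distances = align_matrix([query], db, params)[0]
    return _from_distances(query.protein_id, distances, db.ids, truth)


def classify_batch(
    queries: Sequence[Fingerprint],
    db: FingerprintDB,
    params: AlignmentParams,
    truths: Mapping[str, str] | None = None,
) -> list[ClassificationResult]:
    """Classify many queries; identical to per-query :func:`classify` calls."""
    if len(db) == 0:
        raise ValueError("database is empty")
    distances = align_matrix(queries, db, params)
    db_ids = db.ids
    out = []
    for q, row in zip(queries, distances):
        truth = truths.get(q.protein_id) if truths is not None else None
        out.append(_from_distances(q.protein_id, row, db_ids, truth))
    return out


def evaluate_accuracy(
    results: Sequence[ClassificationResult],
    truths: Mapping[str, str],
    lengths: Mapping[str, int] | None = None,
    bin_width: int = 250,
) -> tuple[float, pd.DataFrame]:
    """Fraction of correct identifications, plus a per-length breakdown.

    ``truths`` maps query id to true protein id; unclassified queries count
    as incorrect. When ``lengths`` (query id -> sequence length in residues)
    is given, the returned table bins correct/incorrect/unclassified counts
    into ``bin_width``-residue sequence-length bins; otherwise it has a
    single row covering all queries.
    """
    if not results:
        raise ValueError("no results to evaluate")
    rows = []
    for res in results:
        if res.query_id not in truths:
            raise KeyError(f"missing truth label for query {res.query_id!r}")
        correct = res.classified and res.predicted_id == truths[res.query_id]
        rows.append(
            {
                "query_id": res.query_id,
                "correct": correct,
                "unclassified": not res.classified,
                "length": lengths[res.query_id] if lengths is not None else 0,
            }
        )
    df = pd.DataFrame(rows)
    accuracy = float(df["correct"].mean())
    df["length_bin"] = (df["length"] // bin_width) * bin_width
    hist = (
        df.groupby("length_bin")
        .agg(
            n=("correct", "size"),
            correct=("correct", "sum"),
            unclassified=("unclassified", "sum"),
        )
        .reset_index()
    )
    hist["incorrect"] = hist["n"] - hist["correct"]
    return accuracy, hist
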