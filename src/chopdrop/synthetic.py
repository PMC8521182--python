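"""Synthetic proteomes and small alignment fixtures.

Stands in for a real proteome so every stage of the pipeline is testable
without downloads. Sequence lengths are drawn log-uniformly (a proteome's
length distribution is strongly right-skewed); residue usage is uniform by
default, since fingerprint statistics depend mainly on the density of
cleavage targets (K/R), which callers can tune via ``residue_frequencies``.
A configurable fraction of entries are near-duplicate "paralogs" — copies
of another entry with independent point substitutions — to exercise the
misclassification behavior real paralogous families cause.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .chemistry import CANONICAL_RESIDUES

__all__ = [
    "ProteomeSpec",
    "generate_proteome",
    "generate_distinct_fingerprint_proteome",
    "worked_fixtures",
]

_ALPHABET = sorted(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class ProteomeSpec:
    n_proteins: int = 500
    length_range: tuple[int, int] = (50, 2000)
    residue_frequencies: Mapping[str, float] | None = None  # default uniform
    paralog_fraction: float = 0.0
    paralog_identity: float = 0.9  # per-residue survival probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length_range")
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ValueError("paralog_fraction must be in [0, 1]")
        if not 0.0 <= self.paralog_identity <= 1.0:
            raise ValueError("paralog_identity must be in [0, 1]")
        if self.residue_frequencies is not None:
            if set(self.residue_frequencies) != CANONICAL_RESIDUES:
                raise ValueError("frequencies must cover exactly the 20 residues")
            if not np.isclose(sum(self.residue_frequencies.values()), 1.0):
                raise ValueError("frequencies must sum to 1")


def _random_sequence(rng: np.random.Generator, length: int, p: np.ndarray) -> str:
    return "".join(rng.choice(_ALPHABET, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Independent point substitutions with survival probability ``identity``."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) >= identity)
    for i in hits:
        choices = [aa for aa in _ALPHABET if aa != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_proteome(spec: ProteomeSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Deterministic synthetic proteome plus its truth table.

    Returns ``(records, truth)`` where records are (id, sequence) pairs and
    the truth table has columns id, length, paralog_of (empty string for
    base sequences).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.residue_frequencies is None:
        p = np.full(20, 0.05)
    else:
        p = np.array([spec.residue_frequencies[aa] for aa in _ALPHABET])
        p = p / p.sum()

    n_paralogs = int(round(spec.n_proteins * spec.paralog_fraction))
    n_base = spec.n_proteins - n_paralogs
    if n_base < 1:
        raise ValueError("paralog_fraction leaves no base sequences")

    lo, hi = spec.length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_base)).astype(int)
    lengths = np.clip(lengths, lo, hi)

    records: list[tuple[str, str]] = []
    truth_rows = []
    for k, length in enumerate(lengths):
        pid = f"SYN{k:05d}"
        seq = _random_sequence(rng, int(length), p)
        records.append((pid, seq))
        truth_rows.append({"id": pid, "length": len(seq), "paralog_of": ""})

    for k in range(n_paralogs):
        src_idx = int(rng.integers(n_base))
        src_id, src_seq = records[src_idx]
        pid = f"PAR{k:05d}"
        seq = _mutate(rng, src_seq, spec.paralog_identity)
        records.append((pid, seq))
        truth_rows.append({"id": pid, "length": len(seq), "paralog_of": src_id})

    return records, pd.DataFrame(truth_rows)


def generate_distinct_fingerprint_proteome(
    spec: ProteomeSpec, oversample: float = 2.0
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Synthetic proteome whose noiseless fingerprints are pairwise distinct.

    Self-classification studies condition on a proteome with unique,
    non-empty reference fingerprints. Random proteomes occasionally violate
    this: very short proteins can lose every fragment to the detection
    floor (empty fingerprint), and cleavage-free proteins heavier than the
    saturation cap all collapse to the single weight 1.6 kDa. This
    oversamples from ``spec`` and keeps the first ``spec.n_proteins``
    entries with unique non-empty noiseless fingerprints.
    """
    from .digestion import NOISELESS, digest

    big = dataclasses.replace(spec, n_proteins=max(int(spec.n_proteins * oversample), spec.n_proteins + 20))
    records, truth = generate_proteome(big)
    seen: set[tuple[float, ...]] = set()
    kept: list[tuple[str, str]] = []
    for pid, seq in records:
        fp = digest(pid, seq, NOISELESS).weights
        if len(fp) == 0 or fp in seen:
            continue
        seen.add(fp)
        kept.append((pid, seq))
        if len(kept) == spec.n_proteins:
            break
    if len(kept) < spec.n_proteins:
        raise ValueError(
            "could not assemble enough distinct-fingerprint proteins; "
            "increase oversample"
        )
    ids = {pid for pid, _ in kept}
    truth = truth[truth["id"].isin(ids)].reset_index(drop=True)
    return kept, truth


def worked_fixtures() -> dict[str, dict]:
    """Small fingerprint pairs with known alignment outcomes.

    Keys: ``identity`` (equal fingerprints, distance 0), ``fusion`` (two
    query fragments matching one reference fragment exactly, distance 0),
    ``skip`` (one interior extra fragment, distance = gap penalty G),
    ``leading_double_skip`` (two unmatched leading fragments, which the
    global edge conditions make unreachable: infeasible).
    """
    return {
        "identity": {"x": [600.0, 900.0], "y": [600.0, 900.0], "distance": 0.0},
        "fusion": {"x": [600.0, 700.0], "y": [1300.0], "distance": 0.0},
        "skip": {"x": [600.0, 800.0, 900.0], "y": [600.0, 900.0], "distance": "G"},
        "leading_double_skip": {
            "x": [550.0, 650.0, 600.0],
            "y": [600.0],
            "distance": float("inf"),
        },
    }
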