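"""In-silico chop-n-drop digestion: cleave, filter, capture, add noise.

A protein threaded through the proteasome-nanopore construct is cleaved
C-terminally of the trypsin-like target residues (K, R); each realized
fragment's weight is then observed subject to the measurement model:

1. each target site is cleaved with probability ``e_p`` (missed sites fuse
   neighboring fragments, which appear as the sum of their weights);
2. optional charge filter: fragments with net charge below −1 e at pH 4
   cannot enter the pore against the electrophoretic force and are dropped;
3. fragments lighter than the lower detection limit ``L`` (500 Da) escape
   detection; weights above the 1.6 kDa saturation cap are clipped to it;
4. each surviving fragment is captured with probability ``C``;
5. Gaussian noise with standard deviation sigma_r = r / PHI^-1(0.75) is
   added to each observed weight, so that half of all measurements deviate
   at most ``r`` (the resolution) from the true weight.

Filters act on the true physical mass by default — they model physics, not
readout — with ``filter_on_noisy`` available to apply the detection floor to
the noisy weight instead.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.stats import norm

from .chemistry import (
    CANONICAL_RESIDUES,
    ChargeModel,
    MassTable,
    peptide_charge,
    peptide_mass,
)

__all__ = [
    "SimParams",
    "Fragment",
    "Fingerprint",
    "FingerprintDB",
    "cleavage_sites",
    "sigma_from_resolution",
    "fragment_protein",
    "digest",
    "build_database",
    "NOISELESS",
]


def sigma_from_resolution(r: float) -> float:
    """Noise standard deviation enforcing resolution ``r``.

    Chosen so that P(|n| <= r) = 0.5 for n ~ N(0, sigma_r):
    sigma_r = -r / PHI^-1(0.25) = r / PHI^-1(0.75) ~= 1.4826 r.
    """
    if r < 0:
        raise ValueError(f"resolution must be non-negative, got {r}")
    if r == 0:
        return 0.0
    return -r / norm.ppf(0.25)


@dataclass(frozen=True)
class SimParams:
    """All noise/physics knobs of one simulated measurement."""

    e_p: float = 1.0  # proteasome cleaving efficiency (per-site probability)
    C: float = 1.0  # capture rate (per-fragment probability)
    r: float = 0.0  # resolution (Da)
    lower_limit: float = 500.0  # L: lower detection limit (Da)
    upper_cap: float = 1600.0  # saturation cap (Da)
    cleave_after: frozenset[str] = frozenset({"K", "R"})
    charge_filter: bool = False
    charge_cutoff: float = -1.0  # drop iff charge < cutoff (strict)
    pH: float = 4.0
    filter_on_noisy: bool = False  # apply the detection floor to noisy weights
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_p <= 1.0:
            raise ValueError(f"e_p must be in [0, 1], got {self.e_p}")
        if not 0.0 <= self.C <= 1.0:
            raise ValueError(f"C must be in [0, 1], got {self.C}")
        if self.r < 0:
            raise ValueError(f"r must be non-negative, got {self.r}")
        if not 0 < self.lower_limit < self.upper_cap:
            raise ValueError("require 0 < lower_limit < upper_cap")
        if not self.cleave_after <= CANONICAL_RESIDUES:
            raise ValueError("cleave_after must be canonical residues")

    @property
    def sigma(self) -> float:
        return sigma_from_resolution(self.r)


#: Parameter template for database construction: every site cleaved, every
#: fragment captured, no measurement noise.
NOISELESS = SimParams(e_p=1.0, C=1.0, r=0.0)


@dataclass(frozen=True)
class Fragment:
    """One realized (possibly fused) digestion product."""

    sequence: str
    true_mass: float
    charge: float
    start: int  # 0-based, half-open coordinates in the parent
    end: int


@dataclass(frozen=True)
class Fingerprint:
    """Ordered observed fragment weights (Da), N- to C-terminal."""

    protein_id: str
    weights: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)


def cleavage_sites(sequence: str, cleave_after: Iterable[str] = ("K", "R")) -> list[int]:
    """0-based positions after which the protease cuts.

    A cut after the final residue is never emitted (it creates no boundary).
    """
    targets = set(cleave_after)
    return [i for i, aa in enumerate(sequence[:-1]) if aa in targets]


def _protein_rng(seed: int, protein_id: str, replicate: int = 0) -> np.random.Generator:
    """Independent per-protein substream, stable across run order."""
    id_hash = zlib.crc32(protein_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, replicate, id_hash]))


def fragment_protein(
    sequence: str,
    cut_positions: Sequence[int],
    mass_table: MassTable | None = None,
    charge_model: ChargeModel | None = None,
    pH: float = 4.0,
) -> list[Fragment]:
    """Split ``sequence`` at the realized cut positions into Fragments."""
    bounds = [0] + [p + 1 for p in cut_positions] + [len(sequence)]
    frags = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        sub = sequence[start:end]
        frags.append(
            Fragment(
                sequence=sub,
                true_mass=peptide_mass(sub, mass_table),
                charge=peptide_charge(sub, charge_model, pH=pH),
                start=start,
                end=end,
            )
        )
    return frags


def digest(
    protein_id: str,
    sequence: str,
    params: SimParams,
    rng: np.random.Generator | None = None,
    replicate: int = 0,
) -> Fingerprint:
    """Simulate one chop-n-drop read of ``sequence`` under ``params``.

    Deterministic given (sequence, params.seed, protein_id, replicate) when
    ``rng`` is not supplied.
    """
    if rng is None:
        rng = _protein_rng(params.seed, protein_id, replicate)

    sites = cleavage_sites(sequence, params.cleave_after)
    if params.e_p >= 1.0:
        realized = sites
    elif params.e_p <= 0.0:
        realized = []
    else:
        keep = rng.random(len(sites)) < params.e_p
        realized = [s for s, k in zip(sites, keep) if k]

    fragments = fragment_protein(sequence, realized, pH=params.pH)

    if params.charge_filter:
        fragments = [f for f in fragments if not f.charge < params.charge_cutoff]

    if not params.filter_on_noisy:
        fragments = [f for f in fragments if f.true_mass >= params.lower_limit]
    weights = np.array(
        [min(f.true_mass, params.upper_cap) for f in fragments], dtype=np.float64
    )

    if params.C < 1.0 and len(weights):
        captured = rng.random(len(weights)) < params.C
        weights = weights[captured]

    if params.r > 0 and len(weights):
        weights = weights + rng.normal(0.0, params.sigma, size=len(weights))

    if params.filter_on_noisy:
        weights = weights[weights >= params.lower_limit]

    return Fingerprint(protein_id=protein_id, weights=tuple(weights.tolist()))


@dataclass
class FingerprintDB:
    """Identified collection of noiseless reference fingerprints."""

    entries: list[tuple[str, Fingerprint]]
    params_used: SimParams

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, Fingerprint]]:
        return iter(self.entries)

    @property
    def ids(self) -> list[str]:
        return [pid for pid, _ in self.entries]

    def empty_entries(self) -> list[str]:
        """Proteins whose noiseless fingerprint retained zero fragments."""
        return [pid for pid, fp in self.entries if len(fp) == 0]


def build_database(
    proteome: Iterable[tuple[str, str]],
    params: SimParams | None = None,
) -> FingerprintDB:
    """Noiseless in-silico digestion of every protein in ``proteome``.

    ``params`` supplies the filter configuration (charge filter, detection
    limits); its noise knobs are overridden to the noiseless setting
    C = 1, e_p = 1, r = 0. Duplicate identifiers are rejected.
    """
    base = params if params is not None else NOISELESS
    db_params = replace(base, e_p=1.0, C=1.0, r=0.0)
    entries: list[tuple[str, Fingerprint]] = []
    seen: set[str] = set()
    for pid, seq in proteome:
        if pid in seen:
            raise ValueError(f"duplicate protein identifier: {pid!r}")
        seen.add(pid)
        entries.append((pid, digest(pid, seq, db_params)))
    if not entries:
        raise ValueError("proteome is empty")
    return FingerprintDB(entries=entries, params_used=db_params)
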