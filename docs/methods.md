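# Methods

## The measurement being simulated

A proteasome–FraC nanopore construct processes an unfolded protein
N- to C-terminally: the proteasome (engineered to retain only its
trypsin-like activity) cleaves after lysine and arginine, and each released
fragment translocates the pore, where the residual-current blockade reports
its molecular weight. The ordered list of observed weights is the protein's
*fingerprint*. The simulator reproduces this observation process at the
sequence level; it does not model the current trace itself, proteasome
kinetics, or proteoforms (splice variants, PTMs).

## Chemistry

**Masses.** Fragment weights are *average* masses — the measured quantity
is the effective weight of a heterogeneous isotopic population. The residue
table is the Expasy/IUPAC average set (values below, Da); a peptide's mass
is the sum of its residue masses plus one water (18.0153 Da), so hydrolysis
mass gain is modelled: each cleavage adds one water across the two
products.

```
A 71.0779   C 103.1429  D 115.0874  E 129.1140  F 147.1738
G 57.0513   H 137.1393  I 113.1576  K 128.1723  L 113.1576
M 131.1960  N 114.1026  P 97.1152   Q 128.1292  R 156.1857
S 87.0773   T 101.1039  V 99.1311   W 186.2099  Y 163.1732
```

**Charge.** Net charge at pH 4.0 (the FraC operating point) is the
concentration-ratio (Henderson–Hasselbalch) sum over one N-terminal amine,
one C-terminal carboxyl and the ionizable side chains, with the Bjellqvist
pKa set:

```
positive: N-term 7.5, K 10.0, R 12.0, H 5.98
negative: C-term 3.55, D 4.05, E 4.45, C 9.0, Y 10.0
```

This matches biopython's `IsoelectricPoint.charge_at_pH` except that
biopython additionally applies residue-specific *terminal* pKas for a few
residues; we keep a single terminal pKa each, as the model defines. The
difference is a few hundredths of a charge and only matters within ~0.05 e
of the −1 e filter cutoff. Note that with any standard pKa table, free
lysine at pH 4 carries about +1.26 e (not +2): the C-terminal carboxyl
(pKa ≈ 3.55) is already mostly deprotonated at pH 4.

Sequences with non-canonical residues (X, B, Z, U, O occur in UniProt) are
rejected at the chemistry layer; `screen_canonical` excludes such proteins
from both database and query sets and reports their ids, so the realized n
of a proteome run is visible.

## Noise model

Three knobs represent the experimental noise sources, applied in this
order (each fused run of uncut fragments is one fragment throughout):

1. **Proteasome efficiency e_p** — per-site Bernoulli cut; a missed site
   leaves the two neighbors represented by their summed weight.
2. **Charge filter** (off by default) — drop fragments with charge
   strictly below −1 e.
3. **Detection limits** — drop fragments with *true* mass < L = 500 Da;
   clip true masses at 1600 Da.
4. **Capture rate C** — per-fragment Bernoulli retention.
5. **Resolution r** — add Gaussian noise, σ_r = r / Φ⁻¹(0.75) ≈ 1.4826 r,
   chosen so that P(|noise| ≤ r) = 0.5: half of all measurements deviate at
   most the resolution from the truth.

Design choice: the detectability filters act on the **true** physical mass
— they model physics (a light fragment escapes detection regardless of how
its weight would have been read), not the readout. A capped fragment
therefore reports 1600 Da *plus* noise, and noisy weights below L are not
re-filtered. The alternative reading (filter on the noisy weight) is
exposed as `SimParams.filter_on_noisy` for sensitivity analysis.

Reproducibility: every protein draws from an independent RNG substream
keyed by `(seed, replicate, crc32(protein_id))`, so per-protein results do
not depend on processing order.

## Alignment

The distance between query X and reference Y is a global dynamic program
over cumulative weight mismatch (see README for the recurrence). Two
deliberately preserved quirks:

- **Edge conditions** make two or more consecutive unmatched fragments at a
  fingerprint's start unreachable (such alignments are infeasible, distance
  ∞), and interior skips come bundled one-per-match. The recurrence is
  implemented exactly as defined, not "fixed".
- **Gap penalty.** The default is G = (1.96 σ_r)² + L (`squared`). The
  alternative reading G = 1.96 σ_r + L (`linear-95`) — under which a gap is
  preferred over a match exactly when the weight difference exceeds the 95%
  band of correct matches — is selectable; both equal L at r = 0. The L
  floor keeps a match preferred when an undetectable (< 500 Da) fragment
  was fused onto a neighbor. Every run records which variant was used.
- **Fusion direction.** As written, the fusion move joins two *query*
  fragments against one reference fragment. A missed cleavage in a noisy
  query physically produces one query fragment matching the sum of two
  *reference* fragments, i.e. the mirrored move. Default
  `fusion_direction="both"` enables both; `"as-printed"` restricts to the
  former for literal reproduction.

Ties in the traceback are broken by fixed move priority
(match > fuse-X > fuse-Y > skip-X > skip-Y); the distance is unaffected.
The distance-only path is a numba-jitted rolling-array kernel
(O(N_X·N_Y) time, O(N_Y) memory, with a pure-Python fallback); the full
table is only built when a trace is requested. The test suite checks the
implementation exactly against an independent exhaustive enumeration of
all legal move sequences on thousands of random pairs.

No length normalization is applied to distances: classification compares
one query against all database entries, so any query-constant scale would
not change the argmin.

## Classification

A query takes the identity of the database entry with the smallest
distance. Ties are broken by database order, with the tie count reported so
callers can compute a pessimistic accuracy. Empty queries (every fragment
lost) and queries infeasible against all entries are "unclassified" and
count as incorrect — a conservative convention. Correctness is exact
identifier match; paralog mix-ups count as errors.

## Synthetic proteomes

`generate_proteome` emulates a proteome: lengths are log-uniform on
50–2000 residues (a right-skewed spread without importing real data),
residue usage is uniform by default (fingerprint statistics depend mainly
on K/R density, tunable via `residue_frequencies`), and a configurable
fraction of entries are paralogs — copies of a base entry with independent
point substitutions surviving at rate `paralog_identity`.

What this generator does **not** reproduce about real proteomes, and hence
what passing tests do not show: real amino-acid frequencies (uniform usage
overweights heavy residues, so fragments are heavier and a larger share of
reference weights sit exactly at the 1600 Da cap, which weakens
discrimination between long fingerprints), real length distributions
(log-uniform on 50–2000 puts nearly half the proteome below 250 residues,
the regime where few-fragment fingerprints are least distinctive), domain
structure, and paralogous families beyond simple point mutation. Absolute
accuracies on these synthetic proteomes are therefore conservative
relative to a run on a real proteome under the same noise, especially in
the high-noise scenario; the supported conclusions are about the
*mechanism* (exactness of the alignment, calibration of the noise model,
graceful and monotone degradation with each noise parameter, errors
concentrating on short proteins). `run_headline` runs unchanged on any
real proteome FASTA for absolute numbers.

`generate_distinct_fingerprint_proteome` additionally guarantees pairwise
distinct, non-empty noiseless fingerprints (random proteomes occasionally
collide: very short proteins lose every fragment to the detection floor,
and cleavage-free heavy proteins all read as the single weight 1600 Da) —
the precondition of self-classification studies.

## Study scales and numerical choices

- Accuracy studies use a 500-protein synthetic proteome; sweeps classify a
  200-query random subset (drawn once per sweep) against the full database,
  5 replicates per condition — the same design as a proteome-scale study,
  at a size where a full run takes seconds.
- Scenario presets: low noise e_p = 0.99, C = 0.99, r = 5 Da; high noise
  e_p = 0.90, C = 0.90, r = 10 Da.
- Length histograms default to 250-residue bins; the misclassification
  report's short-protein threshold defaults to 250 residues.
- ∞ is `numpy.inf`, which propagates correctly through `min` and addition.
- The charge-filter cutoff is strict: drop iff charge < −1.0 exactly.
- Degenerate inputs: e_p = 0 yields the whole protein as one fragment
  (capped at 1600 Da if heavier); two empty fingerprints align at distance
  0; exactly one empty fingerprint is infeasible.

## Known limitations

- Capture probability is constant; in reality it likely depends on
  fragment size and charge.
- The current–weight relation above 1.6 kDa is unknown, so all heavier
  fragments are indistinguishable at 1600 Da.
- Proteoforms are not modelled; highly similar paralogs are frequently
  confused at realistic resolutions, and the classifier makes no attempt
  to group them.
- The alignment's edge-condition quirks (no two leading skips) mean a
  query missing its first two detectable fragments cannot be aligned
  feasibly to its true reference.
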