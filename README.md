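# chopdrop

Simulation and identification of **chop-n-drop protein fingerprints** — the
single-molecule scheme in which a proteasome mounted on a FraC nanopore
cleaves an unfolded protein at trypsin-like sites (after K and R) and the
weight of each released fragment is read from the ionic-current blockade it
causes. The ordered sequence of fragment weights is the protein's
fingerprint. `chopdrop` answers the question: *is that weight sequence
characteristic enough to identify a protein in a complex mixture, and how
robust is the identification to experimental noise?*

Intended users: nanopore proteomics groups exploring fingerprinting
designs, and anyone needing a reference implementation of the
fingerprint-alignment classifier.

## Model

An in-silico digestion of a protein sequence applies, in order:

1. **Cleavage** — each K/R site is cut with probability *e_p* (proteasome
   efficiency); missed sites fuse adjacent fragments into one with summed
   weight.
2. **Charge filter** (optional) — fragments with net charge < −1 e at
   pH 4.0 (Henderson–Hasselbalch sum, Bjellqvist pKa set) cannot enter the
   pore against the electrophoretic force and are dropped.
3. **Detection limits** — fragments lighter than *L* = 500 Da escape
   detection; weights above 1.6 kDa read as 1.6 kDa (the current–weight
   relation is only established up to there).
4. **Capture** — each fragment is measured with probability *C*.
5. **Resolution** — Gaussian noise with σ_r = r / Φ⁻¹(0.75) ≈ 1.4826 r is
   added to each weight, so half of all measurements deviate ≤ *r* from
   the true weight.

A query fingerprint X is identified by aligning it to every noiseless
database fingerprint Y and taking the minimum distance, where

    S(0,0) = 0,  S(i,0) = S(0,j) = ∞  (i, j ≥ 1)
    S(i,j) = min ( |X_i − Y_j| + S(i−1, j−1),            match
                   |X_i + X_{i−1} − Y_j| + S(i−2, j−1),  fusion
                   |X_i − Y_j| + G + S(i−2, j−1),        skip X_{i−1}
                   |X_i − Y_j| + G + S(i−1, j−2) )       skip Y_{j−1}

with gap penalty G = (1.96 σ_r)² + L. Fusion moves (a missed cleavage)
carry no gap cost; by default the mirrored fusion |X_i − Y_j − Y_{j−1}| is
also enabled (`fusion_direction="both"`), since a missed cleavage in the
query physically matches the *sum of two database* fragments. See
`docs/methods.md` for the variants and their rationale.

## Worked example

```python
from chopdrop import ProteomeSpec, generate_proteome, run_headline

records, truth = generate_proteome(ProteomeSpec(n_proteins=150, seed=42))
accuracy, hist, results = run_headline(records, "low", seed=7)
print(f"accuracy: {accuracy:.3f}")
```

prints (`python examples/03_classify_noisy_reads.py`):

```
low-noise scenario (e_p=0.99, C=0.99, r=5 Da), 150 proteins
accuracy: 0.980

correct / total by sequence-length bin (residues):
      0-249     58 / 61
    250-499     34 / 34
    500-749     21 / 21
    ...
3 misclassified; fraction under 250 residues: 1.00
```

98% of the 150 synthetic proteins are recovered from a single noisy read;
all three failures are short proteins, whose few-fragment fingerprints are
the least distinctive. The other scripts in `examples/` walk through
digestion (`01`), the alignment moves (`02`) and noise-parameter sweeps
(`04`).

A thin CLI wraps the same functions:

```
chopdrop synth --n 500 --seed 7 --out proteome.fasta
chopdrop build-db --fasta proteome.fasta --out db.tsv
chopdrop simulate --fasta proteome.fasta --resolution 5 --seed 1 --out reads.tsv
chopdrop classify --query reads.tsv --db db.tsv --resolution 5 --out calls.csv
```

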