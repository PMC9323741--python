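# dnaspectra

Spectral analysis of DNA sequences with **adaptive, per-sequence numeric
mappings** derived from the spectral envelope, for detecting the three-base
periodicity (TBP) of protein-coding DNA and discriminating coding from
non-coding sequences.

## The problem

Protein-coding DNA carries a period-3 statistical structure — the codon
length — visible as a peak at normalised frequency *f* = 1/3 in the energy
spectrum of a suitably mapped sequence. But DNA is symbolic: before any DFT,
each base must be assigned a number, and a fixed assignment (Voss binary
indicators, EIIP pseudopotentials, QPSK constellation points) can hide the
spectral structure particular to one sequence. This package computes the
mapping *from* the sequence.

## The method

For a sequence of length *N* with binary indicator signals
x_A, x_C, x_G, x_T and their DFTs X_b[k], a mapping is a weight vector
**w** = (a, c, g, t) ∈ ℂ⁴ and the mapped signal's energy spectrum is

    S[k] = |a·X_A[k] + c·X_C[k] + g·X_G[k] + t·X_T[k]|² = |w · X_k|².

The **spectral envelope** at bin *k* is the maximum of S[k] over unit-norm
**w** — the largest eigenvalue of the rank-1 Hermitian matrix
X_kᵀ conj(X_k), with closed form

    λ_k = ‖X_k‖²,   w ∝ conj(X_k),

phase-fixed so the first nonzero weight (A, C, G, T order) is real positive.
Each maximiser is a candidate mapping; two selection rules are provided:

* **SNR-SE** — scan bins k = 0..⌊N/2⌋ and keep the candidate whose folded
  one-sided spectrum maximises the SNR (largest non-DC line vs the remaining
  non-DC energy);
* **TBP-SE** — solve the envelope at the codon bin k = ⌊N/3⌋, guaranteeing
  no unit-norm mapping puts more energy at *f* = 1/3.

A sequence is then called *coding* when the largest non-DC line of its
one-sided spectrum lies within 1/3 ± 0.02 cycles/sample. A sliding-window
profile of the energy at the TBP bin (default W = 351, step 5, mapping
re-fitted per window) localises exons inside long genomic regions. The
classical fixed mappings (Voss, EIIP, QPSK) and an entropy-minimising
baseline are included as comparators, plus seeded generators for
coding-like/non-coding synthetic sequences.

## Worked example

```python
import numpy as np
from dnaspectra import (coding_like_sequence, default_coding_model,
                        to_indicators, tbp_se, voss_spectrum,
                        classify_coding, spectral_entropy)
from dnaspectra.adaptive import spectrum_snr

seq = coding_like_sequence(default_coding_model(0.6), n_codons=100, seed=7)
ind = to_indicators(seq)
r = tbp_se(ind)
print("N:", seq.n, "k:", r.k, "lambda: %.2f" % r.score)
print("w:", np.round(r.mapping.weights, 3))
print("peak f: %.4f" % r.spectrum.peak_frequency(),
      "SNR: %.3f" % spectrum_snr(r.spectrum),
      "H: %.3f" % spectral_entropy(r.spectrum))
print("call:", classify_coding(r.spectrum))
v = voss_spectrum(ind)
print("voss peak f: %.4f" % v.peak_frequency(), "voss SNR: %.3f" % spectrum_snr(v))
```

prints

```
N: 300 k: 100 lambda: 4687.00
w: [ 0.578-0.j    -0.257+0.452j -0.331-0.529j  0.01 +0.077j]
peak f: 0.3333 SNR: 0.237 H: 4.341
call: coding
voss peak f: 0.3333 voss SNR: 0.164
```

A 300-nt sequence with moderate codon bias (ε = 0.6): the TBP-SE mapping is
the unit vector that maximises energy at bin 100 (*f* = 1/3; λ = 4687 is
that maximal energy). Its spectrum peaks exactly at 1/3, so the sequence is
called coding, and the adaptive mapping gives a cleaner peak (SNR 0.237)
than the mapping-free Voss spectrum of the same sequence (0.164).

The same analyses are available from the shell:

```sh
dnaspectra simulate dataset --n-coding 10 --n-noncoding 10 --seed 1 --out demo.fa
dnaspectra classify demo.fa --method tbp-se --labels demo.labels.tsv --out demo
dnaspectra windows gene.fa --method tbp-se -W 351 --step 5 --out gene
```

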