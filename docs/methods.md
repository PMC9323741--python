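# Methods

## Model and conventions

A DNA sequence s of length N over {A, C, G, T} is represented by four binary
indicator signals x_b (1 where the sequence reads base b). IUPAC ambiguity
codes are tolerated: an ambiguous position gives an all-zero indicator
column, so it preserves the length and phase of the signal while adding no
energy to any spectrum; the count of such positions is recorded and warned
about. Input is case-insensitive. User-facing coordinates are 1-based
inclusive (GenBank convention); internal arrays are 0-indexed. BED exports
convert to 0-based half-open.

All DFTs use the negative-exponent convention X[k] = Σ_n x[n]·e^(−j2πnk/N)
(numpy's forward transform). The convention is load-bearing: the phases of
envelope-derived mapping weights flip under the opposite sign. Frequencies
are reported as normalised f = k/N in cycles/sample on [0, 1/2].

A mapping w = (a, c, g, t) ∈ ℂ⁴ produces the signal
x = a·x_A + c·x_C + g·x_G + t·x_T with energy spectrum S[k] = |w·X_k|².
Complex mappings give asymmetric two-sided spectra, so every reported
spectrum is one-sided: bin k ∈ (0, N/2) receives S[k] + S[N−k] (content is
added, not averaged); DC and, for even N, the Nyquist bin are copied. Total
energy is conserved. Spectra are stored unnormalised; division by the
maximum is a presentation option only.

## Spectral envelope

The envelope at bin k is λ_k = max S[k] over unit-norm w — the top
eigenvalue of the rank-1 Hermitian matrix X_kᵀ·conj(X_k). The
implementation uses the closed form λ_k = ‖X_k‖², w ∝ conj(X_k) and is
property-tested against a dense 4×4 Hermitian eigensolver. Eigenvector
phase is fixed by rotating w so its first nonzero component in A, C, G, T
order is real positive; this makes the mapping unique (no ties are possible
once the phase is fixed) and reproduces the conventional presentation in
which the A weight is real.

The maximisation is applied to the raw indicators — no mean-centering, no
variance normalisation of the kind used for stationary categorical time
series. A documented consequence: the envelope curve coincides bin-by-bin
with the two-sided Voss spectrum (trace of a rank-1 matrix = its nonzero
eigenvalue). An optional `center` flag subtracts indicator means, which
only zeroes the DC bin.

Degenerate bins (X_k = 0) return λ = 0 with a `None` mapping rather than an
arbitrary vector. Numerically, "zero" means λ ≤ (N·10⁻¹²)²: FFT round-off
leaves O((N·ε_machine)²) dust on bins that are analytically zero (e.g.
non-harmonic bins of a purely periodic sequence), and letting that dust
define a unit-norm mapping would hand the SNR-SE scan spurious
infinite-SNR candidates.

## Adaptive mapping selection

Spectrum SNR: signal = the largest non-DC bin of the one-sided spectrum;
noise = the sum of the other non-DC bins; DC is excluded from both. SNR is
+∞ when a single line carries all non-DC energy and 0 when there is none.
Both edge cases use a relative floor of 10⁻¹² (vs the largest bin, and vs
the signal respectively) to absorb FFT dust.

SNR-SE iterates k over [0, ⌊N/2⌋] — including k = 0, whose candidate's SNR
is still computed DC-excluded — and keeps the candidate with the strictly
largest SNR, so the lowest qualifying bin wins among ties (including ties
at +∞). If every candidate has zero SNR, the k = 1 candidate is returned
with a warning. TBP-SE solves the envelope once, at k = ⌊N/3⌋, and raises
on a sequence degenerate there. Both algorithms are deterministic:
identical inputs give bit-identical mappings.

The entropy-minimising baseline (`mem_baseline`, off by default elsewhere)
searches real unit-norm mappings for minimal spectral entropy of the folded
spectrum by Nelder–Mead from multiple seeded starts; the normalised EIIP
vector is always one start, so the result is never worse than EIIP. It is a
criterion-level reconstruction of the minimum-entropy-mapping idea, kept as
a comparator; it does not reproduce any particular published optimiser, and
its sign is fixed (first nonzero weight positive) for reproducibility.

## Entropy, classification, evaluation

Spectral entropy is the Shannon entropy (nats) of the one-sided spectrum
normalised to a probability vector, DC included, with 0·ln 0 ≡ 0; it ranges
from 0 (single line) to ln(⌊N/2⌋+1) (flat) and is permutation-invariant —
which is also why entropy alone is a weak selection criterion, and why the
SNR rule is the primary one. The deliberate asymmetry — entropy includes
DC, SNR excludes it — follows each measure's standard form.

Classification: coding iff the largest non-DC bin (ties to the lowest bin;
Nyquist included) has frequency in the closed interval [1/3 − tol, 1/3 +
tol], tol defaulting to 0.02. A spectrum with no non-DC energy is called
non-coding with a warning. Evaluation yields TP/FP/TN/FN with coding as the
positive class, accuracy = (TP+TN)/total, TPR = TP/(TP+FN),
TNR = TN/(TN+FP), FPR = 1 − TNR; a rate with an empty denominator is
reported as missing, not 0. The classifier is binary without a score
threshold, so it yields a single ROC point rather than a curve.

## Window profiling

The energy at bin ⌊W/3⌋ of each length-W window (start positions 1, 1+step,
…; trailing partial windows dropped) is recorded and normalised by the
profile maximum. W defaults to 351 — the classical choice for this
protocol, divisible by 3 so the TBP bin sits exactly at f = 1/3 — with step
5. Adaptive methods re-fit their mapping inside every window: per-window
adaptation is the only reading consistent with the mappings being adaptive,
and a global mapping would fix one bin's maximiser for all windows.
Profile values are attached to both window start and centre. A window that
is degenerate for its method (e.g. a homopolymer stretch under TBP-SE)
contributes zero energy rather than failing the profile.

Exon-like regions are maximal runs of windows with normalised energy ≥
threshold (default 0.5, an explicit user parameter), reported as the union
of the windows' spans, 1-based inclusive. Raising the threshold never
enlarges a region.

## Synthetic data

The generators emulate, at desk scale, the two sequence classes the method
discriminates. Coding-like sequences draw position j mod 3 from row j of a
3×4 positional base-frequency matrix; a single effect-size knob ε ∈ [0, 1]
interpolates between uniform i.i.d. (ε = 0) and the full bias (ε = 1). The
default matrix favours a distinct base per codon position at probability
0.7 — strong enough to make the TBP unambiguous at ε = 1 — chosen as a
minimal one-knob parameterisation of codon bias rather than a realistic
codon-usage table. Non-coding sequences are i.i.d. draws from a base
composition (uniform by default). The labelled-dataset generator uses
300-nt sequences, 200 per class in the power-curve test, honouring the
200-bp minimum-length rule used when preparing real datasets; the mosaic
gene fixture reuses the exon coordinates of the classic five-exon benchmark
region (7990 bp) with synthetic content.

What passing synthetic tests does *not* show: real coding sequences carry
codon-usage, GC-isochore and higher-order correlation structure absent
here, and some real genes lack a detectable TBP altogether, so synthetic
TPR/FPR values do not transfer to real genomes; the synthetic power curve
only demonstrates that the pipeline responds monotonically to the strength
of period-3 structure and attains its design sensitivity under the stated
conditions. All generators are pure functions of (parameters, seed).

## Numerical choices and limitations

- Envelope degeneracy threshold (N·10⁻¹²)² and SNR dust floor 10⁻¹²,
  as above; both are far below any energy a real single-base difference can
  produce and far above double-precision FFT round-off for any N this
  package targets.
- Peak searches always exclude DC and include Nyquist; the classification
  interval is closed on both ends; argmax ties break to the lowest bin.
- The power-curve test tolerates a 0.05 one-sided dip between adjacent ε
  grid points — binomial noise at 200 sequences per class — while requiring
  TPR ≥ 0.95 at ε = 1 and TPR ≈ FPR (±0.10) at ε = 0.
- SNR-SE is O(N²) in the scan (N/2 candidates × O(N) spectrum each, after
  one O(N log N) FFT); TBP-SE is O(N log N). For window profiling both are
  applied to W-sized subproblems, so cost scales with the number of
  windows.
- Sequences shorter than ~200 bp carry too few period-3 cycles for a stable
  peak; the dataset filter defaults to 200 bp minimum and keeps exactly
  200.
- The envelope equals the Voss curve here by construction; methods that
  variance-normalise the envelope for stationary categorical series would
  differ and are out of scope.
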