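"""Adaptive DNA mappings derived from the spectral envelope.

A fixed mapping (EIIP, QPSK, ...) applied to every sequence can hide the
spectral structure particular to one sequence.  The envelope maximisers form
a per-sequence search space of candidate mappings — one per frequency bin —
and the two algorithms here pick one:

``snr_se``
    scans all one-sided bins and keeps the candidate whose mapped one-sided
    spectrum has the highest SNR (largest non-DC line against the remaining
    non-DC background);

``tbp_se``
    exploits prior knowledge of the three-base periodicity of protein-coding
    DNA and solves the envelope only at bin ``⌊N/3⌋`` (normalised frequency
    nearest 1/3), guaranteeing that no unit-norm mapping places more energy
    at the codon frequency than the returned one.

``mem_baseline`` is an optional comparator: a real unit-norm mapping chosen
by minimising the spectral entropy of the folded spectrum.  It is a
criterion-level reconstruction of the minimum-entropy-mapping idea by
multi-start local optimisation, not the published MEM algorithm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .metrics import spectral_entropy
from .sequence import IndicatorSet
from .spectral import (
    Mapping,
    OneSidedSpectrum,
    TwoSidedSpectrum,
    fold_one_sided,
    indicator_dft,
)
from .envelope import _envelope_from_xk

__all__ = [
    "AdaptiveResult",
    "spectrum_snr",
    "tbp_se",
    "snr_se",
    "mem_baseline",
]


@dataclass(frozen=True)
class AdaptiveResult:
    """Outcome of an adaptive-mapping algorithm.

    Attributes
    ----------
    mapping : Mapping
        The selected unit-norm mapping.
    spectrum : OneSidedSpectrum
        Folded energy spectrum of the mapped signal.
    k : int
        Frequency bin whose envelope solution was selected.
    score : float
        Selection score — envelope eigenvalue λ_k for ``tbp_se``, the spectrum
        SNR for ``snr_se``, the spectral entropy for ``mem_baseline``.
    method : str
        Algorithm label.
    """

    mapping: Mapping
    spectrum: OneSidedSpectrum
    k: int
    score: float
    method: str

    def to_dict(self) -> dict:
        w = self.mapping.weights
        return {
            "method": self.method,
            **{b: [c.real, c.imag] for b, c in zip("acgt", w)},
            "chosen_k": self.k,
            "lambda_or_snr": self.score,
        }


def spectrum_snr(spec: OneSidedSpectrum) -> float:
    """SNR of a one-sided spectrum: largest non-DC line over the rest.

    Signal power is the maximum energy over bins ``k ≥ 1``; noise power is the
    sum of the remaining non-DC bins (DC reflects base composition only and is
    excluded from both).  Returns ``inf`` when a single line carries all
    non-DC energy, and 0.0 when no non-DC bin has energy.
    """
    if spec.n_bins < 3:
        raise ValueError("SNR undefined for spectra with fewer than 3 bins")
    tail = spec.values[1:]
    signal = float(tail.max())
    # non-DC content at the FFT round-off floor (relative to the largest
    # bin, DC included) counts as zero: no real spectral line is there
    if signal <= float(spec.values.max()) * 1e-12:
        return 0.0
    noise = float(tail.sum()) - signal
    if noise <= signal * 1e-12:  # noise at the round-off floor
        return math.inf
    return signal / noise


def _mapped_one_sided(dft: np.ndarray, w: np.ndarray, n: int) -> OneSidedSpectrum:
    two = TwoSidedSpectrum(values=np.abs(w @ dft) ** 2, n=n)
    return fold_one_sided(two)


def tbp_se(ind: IndicatorSet) -> AdaptiveResult:
    """TBP-SE: spectral-envelope mapping at the codon-frequency bin ``⌊N/3⌋``.

    Raises if the sequence is degenerate at that bin (λ = 0, e.g. a
    homopolymer), since no mapping can expose period-3 structure there.
    """
    n = ind.n
    if n < 3:
        raise ValueError("TBP-SE requires N >= 3")
    k = n // 3
    dft = indicator_dft(ind)
    lam, mapping = _envelope_from_xk(dft[:, k], n, k)
    if mapping is None:
        raise ValueError(
            f"degenerate sequence: spectral envelope is 0 at bin {k} (f=1/3)"
        )
    spectrum = _mapped_one_sided(dft, mapping.weights, n)
    return AdaptiveResult(
        mapping=mapping, spectrum=spectrum, k=k, score=lam, method="tbp_se"
    )


def snr_se(ind: IndicatorSet) -> AdaptiveResult:
    """SNR-SE: the envelope candidate whose mapped spectrum maximises SNR.

    Scans bins ``k = 0..⌊N/2⌋``; strict improvement only, so among ties the
    lowest bin wins (infinite-SNR candidates included).  If every candidate
    has zero SNR the ``k = 1`` candidate is returned with a warning.
    """
    n = ind.n
    if n < 3:
        raise ValueError("SNR-SE requires N >= 3")
    dft = indicator_dft(ind)
    best: AdaptiveResult | None = None
    best_snr = -math.inf
    for k in range(n // 2 + 1):
        lam, mapping = _envelope_from_xk(dft[:, k], n, k)
        if mapping is None:  # degenerate bin: no candidate mapping
            continue
        spectrum = _mapped_one_sided(dft, mapping.weights, n)
        snr = spectrum_snr(spectrum)
        if snr > best_snr:
            best_snr = snr
            best = AdaptiveResult(
                mapping=mapping, spectrum=spectrum, k=k, score=snr, method="snr_se"
            )
    assert best is not None  # k=0 always has lam > 0 for nonempty sequences
    if best_snr == 0.0:
        warnings.warn(
            "all SNR-SE candidates have zero SNR; returning the k=1 candidate",
            stacklevel=2,
        )
        lam, mapping = _envelope_from_xk(dft[:, 1], n, 1)
        if mapping is not None:
            spectrum = _mapped_one_sided(dft, mapping.weights, n)
            best = AdaptiveResult(
                mapping=mapping, spectrum=spectrum, k=1, score=0.0, method="snr_se"
            )
    return best


def mem_baseline(
    ind: IndicatorSet, restarts: int = 8, seed: int = 0
) -> AdaptiveResult:
    """Entropy-minimising real mapping (criterion-level MEM reconstruction).

    Searches real unit-norm weight vectors for the one whose folded spectrum
    has minimal spectral entropy, by Nelder–Mead from ``restarts`` seeded
    starting points.  The normalised EIIP weights are always included as a
    start, so the result's entropy never exceeds EIIP's.  This reproduces the
    *criterion* of the minimum-entropy-mapping spectrum, not its published
    optimiser.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    n = ind.n
    dft = indicator_dft(ind)
    rng = np.random.default_rng(seed)

    def entropy_of(w4: np.ndarray) -> float:
        norm = np.linalg.norm(w4)
        if norm == 0 or not np.isfinite(norm):
            return math.inf
        spec = _mapped_one_sided(dft, w4 / norm, n)
        if spec.total_energy() == 0:
            return math.inf
        return spectral_entropy(spec)

    eiip = np.array([0.126, 0.134, 0.0806, 0.1335])
    starts = [eiip / np.linalg.norm(eiip)]
    starts += [rng.standard_normal(4) for _ in range(restarts - 1)]

    best_w: np.ndarray | None = None
    best_h = math.inf
    for w0 in starts:
        res = optimize.minimize(entropy_of, w0, method="Nelder-Mead")
        if np.isfinite(res.fun) and res.fun < best_h:
            best_h = float(res.fun)
            best_w = np.asarray(res.x) / np.linalg.norm(res.x)
    if best_w is None:
        raise RuntimeError("entropy minimisation failed from every start")
    # sign convention: first nonzero component positive, mirroring the envelope
    for comp in best_w:
        if comp != 0:
            if comp < 0:
                best_w = -best_w
            break
    mapping = Mapping(
        a=complex(best_w[0]), c=complex(best_w[1]),
        g=complex(best_w[2]), t=complex(best_w[3]),
        name="mem_baseline",
    )
    spectrum = _mapped_one_sided(dft, best_w.astype(complex), n)
    return AdaptiveResult(
        mapping=mapping, spectrum=spectrum, k=spectrum.peak_bin(), score=best_h,
        method="mem_baseline",
    )
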