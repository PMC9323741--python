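"""Spectral envelope of a symbolic DNA sequence.

At frequency bin ``k`` the spectral envelope is the maximum energy
``λ_k = max |w · X_k|²`` over unit-norm complex weight vectors ``w``, i.e. the
largest eigenvalue of the 4×4 Hermitian matrix ``X_kᵀ conj(X_k)`` built from
the indicator DFT coefficients.  That matrix is rank one, so the problem has
a closed form:

    λ_k = ‖X_k‖²       and       w ∝ conj(X_k),

(Cauchy–Schwarz: ``|w·X_k| ≤ ‖w‖·‖X_k‖`` with equality at ``w = conj(X_k)``
up to a phase).  The returned eigenvector phase is fixed by rotating ``w`` so
its first nonzero component, in A, C, G, T order, is real and positive —
making the mapping unique and reproducible.

Each maximiser is itself a candidate DNA mapping; the adaptive algorithms in
:mod:`dnaspectra.adaptive` select among them.

No centering or variance normalisation of the indicators is applied: the
envelope is the literal maximum of the energy quadratic form.  A documented
consequence is that the envelope curve coincides bin-by-bin with the
(two-sided) Voss spectrum, since the trace of a rank-1 Hermitian matrix
equals its single nonzero eigenvalue.  An optional mean-centering flag is
provided for exploration; all published behaviour of this package uses the
uncentered form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import IndicatorSet
from .spectral import Mapping, indicator_dft

__all__ = ["EnvelopeResult", "spectral_envelope_at", "envelope_curve"]

#: Unit-norm tolerance guaranteed for envelope-derived mappings.
NORM_TOL = 1e-9


@dataclass(frozen=True)
class EnvelopeResult:
    """Per-bin spectral envelope: eigenvalues and maximising unit mappings.

    ``mappings[i]`` is ``None`` where ``lambdas[i] == 0`` (degenerate bin:
    no direction carries energy, the maximiser is undefined).
    """

    bins: np.ndarray
    lambdas: np.ndarray
    mappings: tuple
    n: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.bins / self.n

    def to_table(self) -> str:
        """Tab-separated export: bin, frequency, lambda, weights as re/im pairs."""
        header = (
            "bin\tnormalized_frequency\tlambda\t"
            "a_re\ta_im\tc_re\tc_im\tg_re\tg_im\tt_re\tt_im"
        )
        lines = [header]
        for k, lam, m in zip(self.bins, self.lambdas, self.mappings):
            if m is None:
                wcols = "\t".join(["nan"] * 8)
            else:
                w = m.weights
                wcols = "\t".join(f"{v:.8g}" for pair in zip(w.real, w.imag) for v in pair)
            lines.append(f"{k}\t{k / self.n:.8g}\t{lam:.10g}\t{wcols}")
        return "\n".join(lines) + "\n"


def _phase_normalize(w: np.ndarray) -> np.ndarray:
    """Rotate so the first nonzero component (A,C,G,T order) is real positive."""
    for comp in w:
        if abs(comp) > 0:
            return w * (comp.conjugate() / abs(comp))
    return w


def _envelope_from_xk(xk: np.ndarray, n: int, k: int) -> tuple[float, Mapping | None]:
    lam = float(np.vdot(xk, xk).real)
    # FFT round-off leaves O((N*eps)^2) dust on bins that are analytically
    # zero (e.g. non-harmonic bins of a periodic sequence); treat those as
    # degenerate rather than letting noise define a mapping
    if lam <= (n * 1e-12) ** 2:
        return 0.0, None
    w = _phase_normalize(xk.conj() / np.sqrt(lam))
    mapping = Mapping(
        a=complex(w[0]), c=complex(w[1]), g=complex(w[2]), t=complex(w[3]),
        name=f"envelope(k={k}, f={k / n:.4g})",
    )
    return lam, mapping


def _dft(ind: IndicatorSet, center: bool) -> np.ndarray:
    if not center:
        return indicator_dft(ind)
    centered = ind.indicators - ind.indicators.mean(axis=1, keepdims=True)
    # centering each indicator changes only the k=0 DFT coefficient
    return np.fft.fft(centered, axis=1)


def spectral_envelope_at(
    ind: IndicatorSet, k: int, center: bool = False
) -> tuple[float, Mapping | None]:
    """Solve the spectral envelope at one frequency bin.

    Returns ``(λ_k, w)`` where ``λ_k = ‖X_k‖²`` is the maximal energy any
    unit-norm mapping can place at bin ``k`` and ``w`` the maximising mapping
    under the first-nonzero-real-positive phase convention.  A degenerate bin
    (``X_k = 0``) yields ``(0.0, None)``.

    Matches a dense Hermitian eigensolver on ``X_kᵀ conj(X_k)`` to high
    relative accuracy (property-tested).
    """
    n = ind.n
    if not 0 <= k <= n - 1:
        raise ValueError(f"bin k={k} outside [0, {n - 1}]")
    xk = _dft(ind, center)[:, k]
    return _envelope_from_xk(xk, n, k)


def envelope_curve(ind: IndicatorSet, center: bool = False) -> EnvelopeResult:
    """Spectral envelope over the one-sided bin range ``k = 0..⌊N/2⌋``."""
    n = ind.n
    dft = _dft(ind, center)
    bins = np.arange(n // 2 + 1)
    lambdas = np.empty(bins.size)
    mappings = []
    for k in bins:
        lam, m = _envelope_from_xk(dft[:, k], n, int(k))
        lambdas[k] = lam
        mappings.append(m)
    return EnvelopeResult(bins=bins, lambdas=lambdas, mappings=tuple(mappings), n=n)
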