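"""Energy spectra of numerically mapped DNA sequences.

A mapping assigns one complex weight to each base, ``w = (a, c, g, t)``, and
turns the indicator signals into the numeric signal

    x[n] = a·x_A[n] + c·x_C[n] + g·x_G[n] + t·x_T[n].

The energy spectrum is ``S[k] = |a·X_A[k] + c·X_C[k] + g·X_G[k] + t·X_T[k]|²``
where ``X_b[k]`` is the DFT of indicator ``x_b`` with the negative-exponent
convention ``X[k] = Σ_n x[n]·exp(−j2πnk/N)`` (the numpy forward transform).
The sign convention is fixed package-wide: the phases of envelope-derived
mapping weights depend on it.

Complex weights generally give an asymmetric two-sided spectrum, so all
reported spectra are one-sided: the content of each negative-frequency bin is
*added* to its positive counterpart over bins ``k = 0..⌊N/2⌋`` with normalised
frequencies ``f = k/N`` in cycles/sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import IndicatorSet

__all__ = [
    "Mapping",
    "TwoSidedSpectrum",
    "OneSidedSpectrum",
    "indicator_dft",
    "map_to_signal",
    "energy_spectrum",
    "fold_one_sided",
    "voss_spectrum",
    "qpsk_mapping",
    "eiip_mapping",
    "uniform_mapping",
]


@dataclass(frozen=True)
class Mapping:
    """The weight vector ``w = (a, c, g, t)`` of a base-to-number mapping."""

    a: complex
    c: complex
    g: complex
    t: complex
    name: str = ""

    @property
    def weights(self) -> np.ndarray:
        """Weights as a length-4 complex vector in A, C, G, T order."""
        return np.array([self.a, self.c, self.g, self.t], dtype=complex)

    @property
    def is_real(self) -> bool:
        return bool(np.all(self.weights.imag == 0.0))

    def norm(self) -> float:
        return float(np.linalg.norm(self.weights))

    def to_dict(self) -> dict:
        """JSON-friendly form: each weight as a [re, im] pair."""
        return {
            "name": self.name,
            **{
                base: [w.real, w.imag]
                for base, w in zip("acgt", self.weights)
            },
        }


@dataclass(frozen=True)
class TwoSidedSpectrum:
    """Energy spectrum on all bins ``k = 0..N−1`` (each a squared modulus)."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.n,):
            raise ValueError("two-sided spectrum must have N values")
        object.__setattr__(self, "values", vals)

    def total_energy(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class OneSidedSpectrum:
    """Folded spectrum on bins ``k = 0..⌊N/2⌋``; frequencies ``f = k/N``."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.n // 2 + 1,):
            raise ValueError("one-sided spectrum must have floor(N/2)+1 values")
        object.__setattr__(self, "values", vals)

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def frequencies(self) -> np.ndarray:
        """Normalised frequency grid f_k = k/N in cycles/sample on [0, 1/2]."""
        return np.arange(self.n_bins) / self.n

    def bin_nearest(self, frequency: float) -> int:
        """Index of the bin whose normalised frequency is nearest ``frequency``."""
        return int(np.argmin(np.abs(self.frequencies - frequency)))

    def peak_bin(self, exclude_dc: bool = True) -> int:
        """Bin of the largest energy; ties go to the lowest bin.

        The DC bin only reflects base composition, so peak searches skip it
        by default; the Nyquist bin is included.
        """
        start = 1 if exclude_dc else 0
        return start + int(np.argmax(self.values[start:]))

    def peak_frequency(self, exclude_dc: bool = True) -> float:
        return self.peak_bin(exclude_dc) / self.n

    def total_energy(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> np.ndarray:
        """Values divided by their maximum (presentation only); zeros if flat-zero."""
        m = self.values.max()
        return self.values / m if m > 0 else np.zeros_like(self.values)

    def to_table(self) -> str:
        """Tab-separated export: bin, normalized_frequency, energy."""
        lines = ["bin\tnormalized_frequency\tenergy"]
        for k, (f, e) in enumerate(zip(self.frequencies, self.values)):
            lines.append(f"{k}\t{f:.8g}\t{e:.10g}")
        return "\n".join(lines) + "\n"


def qpsk_mapping() -> Mapping:
    """Fixed complex mapping on the four QPSK constellation points."""
    return Mapping(a=1 + 1j, c=-1 - 1j, g=-1 + 1j, t=1 - 1j, name="qpsk")


def eiip_mapping() -> Mapping:
    """Fixed real mapping on electron-ion interaction pseudopotentials."""
    return Mapping(a=0.126, c=0.134, g=0.0806, t=0.1335, name="eiip")


def uniform_mapping() -> Mapping:
    """All-ones mapping (useful as a degenerate reference: signal is constant)."""
    return Mapping(a=1, c=1, g=1, t=1, name="uniform")


def indicator_dft(ind: IndicatorSet) -> np.ndarray:
    """DFT of the four indicator signals.

    Returns a ``(4, N)`` complex array, rows in A, C, G, T order; column ``k``
    is the 4-dimensional frequency vector ``X_k``.  ``X_b[0]`` is the count of
    base ``b``.
    """
    return np.fft.fft(ind.indicators, axis=1)


def map_to_signal(ind: IndicatorSet, mapping: Mapping) -> np.ndarray:
    """Numeric signal ``x[n] = a·x_A[n] + c·x_C[n] + g·x_G[n] + t·x_T[n]``."""
    return mapping.weights @ ind.indicators


def energy_spectrum(ind: IndicatorSet, mapping: Mapping) -> TwoSidedSpectrum:
    """Two-sided energy spectrum of the mapped signal.

    ``S[k] = |w · X_k|²`` — identical to the quadratic form
    ``w (X_kᵀ conj(X_k)) w^H`` on the rank-1 Hermitian matrix built from the
    indicator DFT coefficients.
    """
    mapped = mapping.weights @ indicator_dft(ind)
    return TwoSidedSpectrum(values=np.abs(mapped) ** 2, n=ind.n)


def fold_one_sided(spec: TwoSidedSpectrum) -> OneSidedSpectrum:
    """Fold a two-sided spectrum to one-sided bins ``0..⌊N/2⌋``.

    Negative-frequency content is *added* to (not averaged with) the positive
    counterpart: ``out[k] = S[k] + S[N−k]`` for ``0 < k < N/2``; DC and (for
    even N) the Nyquist bin are copied.  Total energy is conserved.
    """
    n = spec.n
    half = n // 2
    out = np.empty(half + 1)
    out[0] = spec.values[0]
    if half >= 1:
        upper = n - np.arange(1, half + 1)
        out[1:] = spec.values[1 : half + 1] + spec.values[upper]
        if n % 2 == 0:
            out[half] = spec.values[half]  # Nyquist bin is its own mirror
    return OneSidedSpectrum(values=out, n=n)


def voss_spectrum(ind: IndicatorSet) -> OneSidedSpectrum:
    """Mapping-free spectrum: sum of the four indicator DFT energies, folded.

    The two-sided Voss value at each bin equals the spectral envelope there
    (trace of the rank-1 matrix ``X_kᵀ conj(X_k)`` = its only nonzero
    eigenvalue), so this is also the envelope curve.
    """
    dft = indicator_dft(ind)
    two_sided = TwoSidedSpectrum(values=(np.abs(dft) ** 2).sum(axis=0), n=ind.n)
    return fold_one_sided(two_sided)


def mapped_one_sided(ind: IndicatorSet, mapping: Mapping) -> OneSidedSpectrum:
    """Convenience: one-sided spectrum of the mapped signal."""
    return fold_one_sided(energy_spectrum(ind, mapping))
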