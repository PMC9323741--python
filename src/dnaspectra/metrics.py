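"""Spectral entropy, the TBP classification rule and classifier evaluation.

Protein-coding DNA carries a three-base periodicity (TBP) from the codon
structure, visible as a spectral line at normalised frequency 1/3.  The
classifier here is the peak test: a sequence is called coding when the
largest non-DC line of its one-sided spectrum falls within ±tol of 1/3
(default tol = 0.02 cycles/sample).  Evaluation against known labels yields
a confusion table and the usual accuracy / sensitivity / specificity, i.e. a
single point in ROC space (the rule has no score threshold to sweep).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectral import OneSidedSpectrum

__all__ = [
    "CODING",
    "NONCODING",
    "ConfusionCounts",
    "ClassificationMetrics",
    "spectral_entropy",
    "classify_coding",
    "evaluate_classifier",
]

CODING = "coding"
NONCODING = "noncoding"

#: Codon frequency: one cycle per three bases.
TBP_FREQUENCY = 1.0 / 3.0


def spectral_entropy(spec: OneSidedSpectrum) -> float:
    """Shannon entropy (nats) of the normalised one-sided spectrum.

    ``H = −Σ p[k]·ln p[k]`` with ``p[k] = S[k]/ΣS`` over all bins including
    DC; ``0·ln 0 ≡ 0``.  Ranges from 0 (single line) to ``ln(⌊N/2⌋+1)``
    (flat spectrum).  Note the asymmetry with :func:`~dnaspectra.adaptive.
    spectrum_snr`, which excludes DC — both follow their standard forms.
    """
    total = spec.total_energy()
    if total <= 0:
        raise ValueError("spectral entropy undefined for a zero-total spectrum")
    p = spec.values / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def classify_coding(spec: OneSidedSpectrum, tol: float = 0.02) -> str:
    """Call a sequence coding iff its spectral peak sits at the codon frequency.

    The largest non-DC bin (ties to the lowest bin, Nyquist included) must
    have normalised frequency inside the closed interval
    ``[1/3 − tol, 1/3 + tol]``.  An all-zero non-DC spectrum is called
    non-coding with a warning.
    """
    if spec.n_bins < 2:
        raise ValueError("classification needs at least 2 bins")
    if spec.values[1:].max() == 0.0:
        warnings.warn("no non-DC energy; calling noncoding", stacklevel=2)
        return NONCODING
    f = spec.peak_frequency(exclude_dc=True)
    return CODING if TBP_FREQUENCY - tol <= f <= TBP_FREQUENCY + tol else NONCODING


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion table for the coding/non-coding test."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, sensitivity (TPR), specificity (TNR) and FPR = 1 − TNR.

    A rate whose denominator is empty (e.g. TPR with no coding sequences) is
    ``None`` — reported as missing rather than coerced to 0.
    """

    accuracy: float
    tpr: float | None
    tnr: float | None

    @property
    def fpr(self) -> float | None:
        return None if self.tnr is None else 1.0 - self.tnr

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "TPR": self.tpr,
            "TNR": self.tnr,
            "FPR": self.fpr,
        }


def evaluate_classifier(
    predictions: Sequence[str], labels: Sequence[str]
) -> tuple[ConfusionCounts, ClassificationMetrics]:
    """Score coding/non-coding calls against ground-truth labels.

    ``accuracy = (TP+TN)/total``, ``TPR = TP/(TP+FN)``, ``TNR = TN/(TN+FP)``.
    Positives are coding sequences.
    """
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    if not labels:
        raise ValueError("cannot evaluate an empty set")
    valid = {CODING, NONCODING}
    for v in (*predictions, *labels):
        if v not in valid:
            raise ValueError(f"invalid class label {v!r}")
    tp = sum(p == CODING and y == CODING for p, y in zip(predictions, labels))
    fn = sum(p == NONCODING and y == CODING for p, y in zip(predictions, labels))
    tn = sum(p == NONCODING and y == NONCODING for p, y in zip(predictions, labels))
    fp = sum(p == CODING and y == NONCODING for p, y in zip(predictions, labels))
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    metrics = ClassificationMetrics(
        accuracy=(tp + tn) / counts.total,
        tpr=tp / (tp + fn) if (tp + fn) else None,
        tnr=tn / (tn + fp) if (tn + fp) else None,
    )
    return counts, metrics
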