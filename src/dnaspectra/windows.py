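"""Sliding-window TBP profiling for exon localisation.

The energy at the codon frequency (bin ``⌊W/3⌋`` of a length-``W`` window,
normalised frequency ~1/3) is evaluated window by window along a genomic
region; exon-bearing stretches stand out as high-energy runs.  The classical
window length for this protocol is W = 351 (divisible by 3, so the TBP bin
sits exactly at f = 1/3) with a step of 5.

Adaptive methods (snr_se, tbp_se, mem) recompute their mapping inside every
window — the mapping is per-window, not global, which is what makes them
adaptive in the sliding setting.  Trailing partial windows are dropped: the
fixed-W DFT grid requires full windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adaptive import mem_baseline, snr_se, tbp_se
from .sequence import DnaSequence, IndicatorSet, to_indicators
from .spectral import (
    OneSidedSpectrum,
    eiip_mapping,
    mapped_one_sided,
    qpsk_mapping,
    voss_spectrum,
)

__all__ = ["WindowProfile", "tbp_window_profile", "call_regions", "METHODS"]


def _one_sided_for(method: str, ind: IndicatorSet) -> OneSidedSpectrum:
    if method == "voss":
        return voss_spectrum(ind)
    if method == "eiip":
        return mapped_one_sided(ind, eiip_mapping())
    if method == "qpsk":
        return mapped_one_sided(ind, qpsk_mapping())
    if method == "tbp_se":
        return tbp_se(ind).spectrum
    if method == "snr_se":
        return snr_se(ind).spectrum
    if method == "mem":
        return mem_baseline(ind).spectrum
    raise ValueError(f"unknown method {method!r}")


#: Spectrum methods accepted anywhere a ``method`` argument appears.
METHODS = ("voss", "eiip", "qpsk", "mem", "snr_se", "tbp_se")


@dataclass(frozen=True)
class WindowProfile:
    """Per-window energy at the TBP bin along a sequence.

    Positions are 1-based; ``starts[i]`` is the first base of window ``i`` and
    ``centers[i]`` its middle base.  ``normalized`` is ``raw / max(raw)``,
    or all zeros (with ``all_zero=True``) when no window carries energy.
    """

    window: int
    step: int
    starts: np.ndarray
    raw: np.ndarray
    method: str
    sequence_id: str = ""
    all_zero: bool = False

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.window // 2

    @property
    def normalized(self) -> np.ndarray:
        m = self.raw.max() if self.raw.size else 0.0
        return self.raw / m if m > 0 else np.zeros_like(self.raw)

    @property
    def tbp_bin(self) -> int:
        return self.window // 3

    def to_table(self) -> str:
        """Tab-separated export: start, center, raw, normalized."""
        lines = ["start\tcenter\traw\tnormalized"]
        for s, c, r, z in zip(self.starts, self.centers, self.raw, self.normalized):
            lines.append(f"{s}\t{c}\t{r:.10g}\t{z:.8g}")
        return "\n".join(lines) + "\n"


def tbp_window_profile(
    seq: DnaSequence,
    method: str = "tbp_se",
    window: int = 351,
    step: int = 5,
) -> WindowProfile:
    """Slide a rectangular window and record the energy at its TBP bin.

    For each full window starting at positions 1, 1+step, ... the method's
    one-sided spectrum of the subsequence is computed (adaptive methods refit
    their mapping per window) and the energy at bin ``⌊window/3⌋`` recorded.
    The profile has exactly ``⌊(N − window)/step⌋ + 1`` entries.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if window < 3:
        raise ValueError("window must be >= 3")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = seq.n
    if n < window:
        raise ValueError(
            f"sequence {seq.id!r} has N={n} < window={window}; use a smaller window"
        )
    ind_full = to_indicators(seq).indicators
    k = window // 3
    starts0 = np.arange(0, n - window + 1, step)
    raw = np.empty(starts0.size)
    for i, p in enumerate(starts0):
        sub = IndicatorSet(
            indicators=ind_full[:, p : p + window], source_id=seq.id
        )
        try:
            spec = _one_sided_for(method, sub)
            raw[i] = spec.values[k]
        except ValueError:
            # degenerate window (e.g. homopolymer for tbp_se): no TBP energy
            raw[i] = 0.0
    return WindowProfile(
        window=window,
        step=step,
        starts=starts0 + 1,
        raw=raw,
        method=method,
        sequence_id=seq.id,
        all_zero=bool(raw.max() == 0.0) if raw.size else True,
    )


def call_regions(
    profile: WindowProfile, threshold: float = 0.5
) -> list[tuple[int, int]]:
    """Call putative exon intervals from a window profile.

    Maximal runs of windows with normalised energy ≥ ``threshold`` are merged
    into the union of their ``[start, start + window − 1]`` spans, returned as
    1-based inclusive intervals.  Raising the threshold never enlarges a
    region.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if profile.starts.size == 0 or profile.all_zero:
        return []
    hot = profile.normalized >= threshold
    regions: list[tuple[int, int]] = []
    w = profile.window
    for s, flag in zip(profile.starts, hot):
        if not flag:
            continue
        start, end = int(s), int(s) + w - 1
        if regions and start <= regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], max(regions[-1][1], end))
        else:
            regions.append((start, end))
    return regions


def regions_to_bed(
    regions: list[tuple[int, int]], chrom: str, name: str
) -> str:
    """Serialise called regions as BED (0-based half-open) lines."""
    lines = [f"{chrom}\t{s - 1}\t{e}\t{name}" for s, e in regions]
    return "\n".join(lines) + ("\n" if lines else "")
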