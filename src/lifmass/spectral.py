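"""Averaged power spectra of potential traces and their χ² comparison.

One whole-trace periodogram per realization (mean removed, Hamming
window), averaged across realizations; no segment averaging, since
repetitions provide the ensemble.  Spectra entering the χ² statistic are
first rescaled to a common histogram scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import PotentialTrace

__all__ = [
    "SpectrumEstimate",
    "estimate_spectrum",
    "median_frequency",
    "chi2_spectra",
    "chi2_significance",
]

DEFAULT_BAND = (0.5, 500.0)


@dataclass
class SpectrumEstimate:
    """Realization-averaged discrete power spectrum."""

    power: np.ndarray
    freqs: np.ndarray
    n_realizations: int
    median_freq: float

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.power.shape != self.freqs.shape:
            raise ValueError("power and freqs must have equal length")
        if self.power.size and self.power.min() < 0:
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.power.size


def estimate_spectrum(
    traces: list[PotentialTrace],
    t_transient: float | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> SpectrumEstimate:
    """Hamming-windowed periodogram averaged over realizations.

    Parameters
    ----------
    traces
        Realizations sharing ``dt`` and length; the transient stretch of
        each is discarded before windowing.
    t_transient
        Override for the per-trace transient (ms).
    band
        (low, high) frequency bounds in Hz retained in the estimate;
        removes DC and ultra-slow leakage by default.
    """
    if not traces:
        raise ValueError("estimate_spectrum requires at least one trace")
    dt = traces[0].dt
    n = traces[0].values.size
    for tr in traces:
        if abs(tr.dt - dt) > 1e-12 or tr.values.size != n:
            raise ValueError("all traces must share dt and length")

    segments = []
    for tr in traces:
        if t_transient is not None:
            k0 = int(np.ceil(t_transient / dt - 1e-9))
            seg = tr.values[k0:]
        else:
            seg = tr.post_transient()
        segments.append(seg)
    n_seg = segments[0].size
    if any(s.size != n_seg for s in segments):
        raise ValueError("post-transient segments differ in length")

    window = np.hamming(n_seg)
    freqs = np.fft.rfftfreq(n_seg, d=dt / 1e3)  # Hz
    power = np.zeros(freqs.size)
    for seg in segments:
        x = (seg - seg.mean()) * window
        power += np.abs(np.fft.rfft(x)) ** 2
    power /= len(segments)

    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("frequency band is empty for this trace length")
    freqs, power = freqs[keep], power[keep]
    est = SpectrumEstimate(
        power=power, freqs=freqs, n_realizations=len(traces), median_freq=np.nan
    )
    est.median_freq = median_frequency(est)
    return est


def median_frequency(spectrum: SpectrumEstimate) -> float:
    """Smallest frequency where cumulative power reaches half the total."""
    total = spectrum.power.sum()
    if total <= 0:
        raise ValueError("median frequency undefined for a zero spectrum")
    cum = np.cumsum(spectrum.power)
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(spectrum.freqs[idx])


def _as_histograms(
    p: SpectrumEstimate, q: SpectrumEstimate, scale: float | None
) -> tuple[np.ndarray, np.ndarray]:
    if p.n_bins != q.n_bins:
        raise ValueError("spectra differ in bin count")
    if not np.allclose(p.freqs, q.freqs):
        raise ValueError("spectra are on different frequency grids")
    if scale is None:
        scale = float(p.n_bins)
    ps, qs = p.power.sum(), q.power.sum()
    if ps <= 0 or qs <= 0:
        raise ValueError("cannot normalize a zero spectrum")
    return p.power / ps * scale, q.power / qs * scale


def chi2_spectra(
    p: SpectrumEstimate, q: SpectrumEstimate, scale: float | None = None
) -> float:
    """χ² distance between two spectra on a common histogram scale.

    Both spectra are normalized to unit sum and multiplied by ``scale``
    (default: the number of bins), then
    ``chi2 = sum_l (P_l - Q_l)^2 / (P_l + Q_l)`` with empty bins
    skipped.  The statistic scales linearly with ``scale``.
    """
    ph, qh = _as_histograms(p, q, scale)
    denom = ph + qh
    mask = denom > 0
    return float(((ph[mask] - qh[mask]) ** 2 / denom[mask]).sum())


def chi2_significance(stat: float, n_bins: int, alpha: float = 0.01) -> bool:
    """True iff the spectra are indistinguishable at level ``alpha``.

    Compares the statistic against the (1 - alpha) quantile of the χ²
    distribution with ``n_bins - 1`` degrees of freedom (unit-sum
    constraint removes one).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    return bool(stat <= stats.chi2.ppf(1.0 - alpha, df=n_bins - 1))
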