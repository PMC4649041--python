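"""Wavelet-band functional connectivity from region-averaged BOLD series.

Each subject's regional time series are decomposed into dyadic frequency
bands with an undecimated (maximal-overlap) discrete wavelet transform; the
proximity between two regions is the Pearson correlation of their
coefficients at the analysis scale (scale 2 by default), with negative
correlations excluded — they are treated as very large distances, i.e.
absent edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .graph import GraphValidationError, ProximityGraph

__all__ = [
    "RegionTimeSeriesSet",
    "WaveletCoefficients",
    "wavelet_band_decompose",
    "scale_band_hz",
    "correlation_adjacency",
    "nonnegative_proximity",
    "DEFAULT_WAVELET",
    "DEFAULT_SCALE",
]

#: Daubechies-4 undecimated transform — the established choice for
#: resting-state wavelet correlation analysis.
DEFAULT_WAVELET = "db4"
#: analysis scale whose band carries the canonical resting-state signal
DEFAULT_SCALE = 2


@dataclass(frozen=True)
class RegionTimeSeriesSet:
    """Region-averaged BOLD time series: regions x time points, plus TR."""

    series: np.ndarray
    tr_seconds: float
    node_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        s = np.asarray(self.series, dtype=float)
        if s.ndim != 2:
            raise GraphValidationError("series must be a 2-D regions x time matrix")
        if not np.isfinite(s).all():
            raise GraphValidationError("series contains missing/non-finite values")
        if self.tr_seconds <= 0:
            raise GraphValidationError("tr_seconds must be positive")
        s = s.copy()
        s.setflags(write=False)
        object.__setattr__(self, "series", s)
        ids = self.node_ids
        ids = tuple(f"n{i}" for i in range(s.shape[0])) if ids is None else tuple(ids)
        if len(ids) != s.shape[0] or len(set(ids)) != len(ids):
            raise GraphValidationError("node_ids must be unique, one per region")
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_regions(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass(frozen=True)
class WaveletCoefficients:
    """Detail coefficients of one dyadic scale (length-preserving transform)."""

    scale: int
    band_hz: tuple[float, float]
    coeffs: np.ndarray
    node_ids: tuple[str, ...]
    tr_seconds: float


def scale_band_hz(scale: int, tr_seconds: float) -> tuple[float, float]:
    """Nominal frequency band (low, high) of a dyadic wavelet scale.

    Scale j covers (Nyquist / 2^j, Nyquist / 2^(j-1)) with
    Nyquist = 1 / (2 TR).
    """
    nyquist = 1.0 / (2.0 * tr_seconds)
    return (nyquist / 2**scale, nyquist / 2 ** (scale - 1))


def wavelet_band_decompose(
    ts: RegionTimeSeriesSet,
    n_scales: int = 4,
    wavelet: str = DEFAULT_WAVELET,
) -> list[WaveletCoefficients]:
    """Undecimated wavelet decomposition into ``n_scales`` detail bands.

    Uses the stationary (maximal-overlap) discrete wavelet transform with
    periodic boundary handling, in its energy-preserving normalization, so
    every scale retains ``n_timepoints`` coefficients and the energy of the
    detail scales plus the final approximation equals the input energy.

    Requires ``n_scales <= floor(log2(n_timepoints)) - 2`` and
    ``n_timepoints`` divisible by ``2**n_scales``.
    """
    t = ts.n_timepoints
    max_depth = int(np.floor(np.log2(t))) - 2
    if n_scales < 1:
        raise GraphValidationError("n_scales must be >= 1")
    if n_scales > max_depth:
        raise GraphValidationError(
            f"series of length {t} supports at most {max_depth} scales, "
            f"requested {n_scales}"
        )
    if t % 2**n_scales:
        raise GraphValidationError(
            f"n_timepoints ({t}) must be divisible by 2**n_scales ({2**n_scales})"
        )
    # returns [approx_n, detail_n, ..., detail_1]
    out = pywt.swt(ts.series, wavelet, level=n_scales, norm=True,
                   trim_approx=True, axis=-1)
    result = []
    for scale in range(1, n_scales + 1):
        result.append(
            WaveletCoefficients(
                scale=scale,
                band_hz=scale_band_hz(scale, ts.tr_seconds),
                coeffs=out[-scale],
                node_ids=ts.node_ids,
                tr_seconds=ts.tr_seconds,
            )
        )
    return result


def wavelet_approximation(
    ts: RegionTimeSeriesSet, n_scales: int = 4, wavelet: str = DEFAULT_WAVELET
) -> np.ndarray:
    """Final smooth (approximation) coefficients of the same decomposition."""
    out = pywt.swt(ts.series, wavelet, level=n_scales, norm=True,
                   trim_approx=True, axis=-1)
    return out[0]


def correlation_adjacency(wc: WaveletCoefficients) -> np.ndarray:
    """Pearson correlation matrix of per-region wavelet coefficients."""
    coeffs = wc.coeffs
    if coeffs.shape[1] < 3:
        raise GraphValidationError("need at least 3 coefficients per region")
    sd = coeffs.std(axis=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = ", ".join(wc.node_ids[i] for i in dead[:5])
        raise GraphValidationError(f"zero-variance region(s): {names}")
    corr = np.corrcoef(coeffs)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.T)


def nonnegative_proximity(
    corr: np.ndarray, node_ids: tuple[str, ...] | None = None
) -> tuple[ProximityGraph, int]:
    """Truncate negative correlations to zero (absent) and count them.

    Returns the proximity graph plus the number of strictly negative
    unordered off-diagonal pairs, which the group analysis compares between
    groups.
    """
    corr = np.asarray(corr, dtype=float)
    tri = np.triu_indices(corr.shape[0], k=1)
    n_negative = int((corr[tri] < 0).sum())
    weights = np.clip(corr, 0.0, 1.0)
    np.fill_diagonal(weights, 0.0)
    return ProximityGraph(weights=weights, node_ids=node_ids), n_negative


def timeseries_to_proximity(
    ts: RegionTimeSeriesSet,
    scale: int = DEFAULT_SCALE,
    n_scales: int = 4,
    wavelet: str = DEFAULT_WAVELET,
) -> tuple[ProximityGraph, np.ndarray, int]:
    """Full per-subject connectivity stage: series -> (proximity, raw R, #neg)."""
    bands = wavelet_band_decompose(ts, n_scales=n_scales, wavelet=wavelet)
    corr = correlation_adjacency(bands[scale - 1])
    prox, n_neg = nonnegative_proximity(corr, ts.node_ids)
    return prox, corr, n_neg
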