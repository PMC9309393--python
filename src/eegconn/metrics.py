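"""Pairwise functional-connectivity estimators and the all-pairs matrix.

Three base metrics are provided:

* ``pcc`` -- Pearson correlation coefficient, the covariance of two series
  normalized by the product of their standard deviations; range [-1, 1].
  The sign is kept: anticorrelated channels are meaningful and are styled
  distinctly downstream.
* ``coherence`` -- magnitude-squared spectral coherence
  |p_xy(f)|^2 / (p_xx(f) p_yy(f)) from Welch auto-/cross-spectra, averaged
  over the frequency bins inside a band; range [0, 1].
* ``plv`` -- phase-locking value, the modulus of the time-averaged unit
  phasor of the instantaneous phase difference; range [0, 1]. Phases come
  from the analytic signal (Hilbert transform) of band-limited inputs, or
  may be supplied directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional

import numpy as np
import scipy.signal

from .errors import DomainError, EstimationError
from .preprocess import BANDS, BandSpec, Recording

METRICS = ("pcc", "coherence", "plv", "comprehensive")

#: Self-connectivity of each base metric (matrix diagonal).
SELF_VALUE = {"pcc": 1.0, "coherence": 1.0, "plv": 1.0, "comprehensive": 0.0}


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel weights for one metric, band, condition."""

    weights: np.ndarray
    metric: str
    labels: tuple[str, ...]
    band: str = "broadband"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise DomainError(
                f"weights {self.weights.shape} inconsistent with {n} labels")
        if self.metric not in METRICS:
            raise DomainError(f"unknown metric {self.metric!r}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.weights[self.labels.index(a), self.labels.index(b)])

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle (unordered-pair) weights as a flat vector."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.weights[iu]

    def reorder(self, labels: tuple[str, ...] | list[str]) -> "ConnectivityMatrix":
        """Explicitly permute channels into the given label order."""
        if set(labels) != set(self.labels):
            raise DomainError("reorder requires the same label set")
        idx = [self.labels.index(l) for l in labels]
        return ConnectivityMatrix(
            weights=self.weights[np.ix_(idx, idx)], metric=self.metric,
            labels=tuple(labels), band=self.band, meta=dict(self.meta))


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length series.

    r = sum((x_i - xbar)(y_i - ybar)) / sqrt(sum((x_i - xbar)^2) sum((y_i - ybar)^2))
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DomainError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise DomainError("pcc needs at least 2 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        raise DomainError("correlation undefined for a constant series")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def _welch_params(n: int, seg: Optional[int], overlap: float) -> tuple[int, int]:
    if seg is None:
        seg = min(256, 2 ** int(np.log2(n)))
    if seg > n:
        raise DomainError(f"segment length {seg} exceeds series length {n}")
    nover = int(round(overlap * seg))
    step = seg - nover
    n_segments = 1 + (n - seg) // step
    if n_segments < 2:
        raise EstimationError(
            f"only {n_segments} Welch segment(s); per-bin coherence would be "
            "identically 1 -- use a shorter segment or more data")
    return seg, nover


def band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: BandSpec | str = "alpha",
    seg: Optional[int] = None,
    overlap: float = 0.5,
) -> float:
    """Magnitude-squared coherence averaged over a frequency band.

    Welch auto- and cross-spectra on Hann-windowed segments (default 50%
    overlap); per-bin coherence |p_xy|^2 / (p_xx p_yy); the returned scalar
    is the mean over bins inside [band.lo, band.hi].
    """
    if isinstance(band, str):
        band = BANDS[band]
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DomainError(f"length mismatch: {x.size} vs {y.size}")
    if band.hi > fs / 2:
        raise DomainError(f"band [{band.lo}, {band.hi}] exceeds Nyquist {fs / 2}")
    seg, nover = _welch_params(x.size, seg, overlap)
    kw = dict(fs=fs, window="hann", nperseg=seg, noverlap=nover, detrend="constant")
    f, pxy = scipy.signal.csd(x, y, **kw)
    _, pxx = scipy.signal.welch(x, **kw)
    _, pyy = scipy.signal.welch(y, **kw)
    mask = (f >= band.lo) & (f <= band.hi)
    if not mask.any():
        raise DomainError(f"no spectral bins inside [{band.lo}, {band.hi}] Hz")
    coh = np.abs(pxy[mask]) ** 2 / (pxx[mask] * pyy[mask])
    return float(np.clip(coh.mean(), 0.0, 1.0))


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of a band-limited series via the analytic signal."""
    return np.angle(scipy.signal.hilbert(np.asarray(x, dtype=float).ravel()))


def plv(x: np.ndarray, y: np.ndarray, phase_input: bool = False) -> float:
    """Phase-locking value |1/n sum_t exp(i(phi_xt - phi_yt))|.

    With ``phase_input=True`` the arguments are taken as phase series in
    radians; otherwise phases are extracted from the analytic signal.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise DomainError("plv of a zero-length series is undefined")
    if x.size != y.size:
        raise DomainError(f"length mismatch: {x.size} vs {y.size}")
    if phase_input:
        px, py = x, y
    else:
        px, py = instantaneous_phase(x), instantaneous_phase(y)
    return float(np.clip(np.abs(np.mean(np.exp(1j * (px - py)))), 0.0, 1.0))


def _pairwise(rec: Recording, fn: Callable[[np.ndarray, np.ndarray], float],
              metric: str, meta: dict[str, Any]) -> ConnectivityMatrix:
    n = rec.n_channels
    w = np.full((n, n), SELF_VALUE[metric])
    for a in range(n):
        for b in range(a + 1, n):
            try:
                v = fn(rec.data[a], rec.data[b])
            except Exception as exc:
                raise type(exc)(
                    f"pair ({rec.labels[a]}, {rec.labels[b]}): {exc}") from exc
            w[a, b] = w[b, a] = v
    return ConnectivityMatrix(weights=w, metric=metric, labels=rec.labels,
                              band=rec.band, meta=meta)


def connectivity_matrix(
    rec: Recording,
    metric: str = "pcc",
    band: Optional[BandSpec | str] = None,
    seg: Optional[int] = None,
    overlap: float = 0.5,
) -> ConnectivityMatrix:
    """All-pairs connectivity of a recording under one base metric.

    Every unordered channel pair is evaluated once and mirrored; the
    diagonal is the metric's self-value (1 for pcc/coherence/plv).
    """
    if rec.n_channels < 2:
        raise DomainError("connectivity needs at least 2 channels")
    if metric == "pcc":
        return _pairwise(rec, pcc, "pcc", {})
    if metric == "plv":
        # hilbert is per-channel, so precomputing phases equals the
        # per-pair evaluation exactly
        phases = np.angle(scipy.signal.hilbert(rec.data, axis=1))
        n = rec.n_channels
        w = np.ones((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                w[a, b] = w[b, a] = plv(phases[a], phases[b], phase_input=True)
        return ConnectivityMatrix(weights=w, metric="plv", labels=rec.labels,
                                  band=rec.band, meta={})
    if metric == "coherence":
        if band is None:
            band = BANDS[rec.band] if rec.band in BANDS else "alpha"
        bspec = BANDS[band] if isinstance(band, str) else band
        meta = {"band": bspec.name, "seg": seg, "overlap": overlap}
        return _pairwise(
            rec,
            lambda x, y: band_coherence(x, y, rec.fs, bspec, seg, overlap),
            "coherence", meta)
    raise DomainError(f"unknown base metric {metric!r}")
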