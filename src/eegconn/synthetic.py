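"""Synthetic multichannel signals with analytically known connectivity.

Every estimator in the package can be validated without any EEG dataset:

* correlated Gaussian pairs ``y = rho x + sqrt(1 - rho^2) eps`` have
  expected Pearson correlation exactly rho;
* phase-coupled oscillator pairs with i.i.d. von Mises(0, kappa) phase
  jitter have asymptotic phase-locking value I1(kappa)/I0(kappa)
  (the Bessel ratio, i.e. the mean resultant length of the jitter);
* block-structured recordings mix a global source, per-block sources and
  channel noise so that the expected correlation is rho_hi within a block
  and rho_lo across blocks -- the planted structure that fractional
  thresholding should recover.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.signal
import scipy.special

from .errors import DomainError
from .montage import load_montage
from .preprocess import BANDS, BandSpec, Recording


def expected_plv(kappa: float) -> float:
    """Asymptotic PLV of von Mises(0, kappa) phase jitter: I1(k)/I0(k)."""
    if kappa < 0:
        raise DomainError("concentration kappa must be >= 0")
    if np.isinf(kappa):
        return 1.0
    return float(scipy.special.i1(kappa) / scipy.special.i0(kappa))


def gen_correlated_pair(rho: float, n: int, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-Gaussian series with planted correlation rho."""
    if not -1.0 <= rho <= 1.0:
        raise DomainError(f"correlation target {rho} outside [-1, 1]")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    y = rho * x + np.sqrt(1.0 - rho**2) * eps
    return x, y


def gen_phase_coupled(kappa: float, f0: float, fs: float, n: int,
                      seed: int = 0, return_phases: bool = False):
    """Two cosine carriers whose phase difference is von Mises jitter.

    Channel 1 is cos(2 pi f0 t + phi_t) with a slowly wandering common
    phase phi_t; channel 2 adds i.i.d. von Mises(0, kappa) jitter eta_t.
    ``kappa=inf`` means rigid locking (eta identically 0); ``kappa=0`` is
    uniform jitter (no locking). With ``return_phases=True`` the
    instantaneous phase series of both channels are returned instead of
    the signals, for direct PLV evaluation.
    """
    if not 0 < f0 < fs / 2:
        raise DomainError(f"carrier {f0} Hz outside (0, {fs / 2}) Hz")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    # slow phase wander keeps the carrier realistic without touching the
    # phase-difference statistics
    phi = np.cumsum(rng.standard_normal(n) * 0.02)
    if np.isinf(kappa):
        eta = np.zeros(n)
    elif kappa == 0:
        eta = rng.uniform(-np.pi, np.pi, n)
    else:
        eta = rng.vonmises(0.0, kappa, n)
    px = 2 * np.pi * f0 * t + phi
    py = px + eta
    if return_phases:
        return px, py
    return np.cos(px), np.cos(py)


@dataclass(frozen=True)
class CouplingSpec:
    """Recipe for a block-structured recording with planted correlations."""

    n_channels: int = 8
    fs: float = 200.0
    duration: float = 50.0
    seed: int = 0
    rho_hi: float = 0.8
    rho_lo: float = 0.1
    blocks: Optional[tuple[tuple[int, ...], ...]] = None
    carrier: BandSpec = field(default_factory=lambda: BANDS["alpha"])

    def block_assignment(self) -> tuple[tuple[int, ...], ...]:
        if self.blocks is not None:
            return self.blocks
        half = self.n_channels // 2
        return (tuple(range(half)), tuple(range(half, self.n_channels)))

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_lo <= self.rho_hi <= 1.0:
            raise DomainError("need 0 <= rho_lo <= rho_hi <= 1")
        blocks = self.block_assignment()
        members = sorted(i for b in blocks for i in b)
        if members != list(range(self.n_channels)):
            raise DomainError("blocks must partition the channel set")


def _bandpass(data: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    """Zero-phase Butterworth band-pass applied identically per channel.

    One linear filter shared by every channel preserves all planted
    zero-lag correlations between white-noise sources.
    """
    sos = scipy.signal.butter(4, [band.lo, band.hi], btype="bandpass",
                              fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def gen_structured_recording(spec: CouplingSpec) -> Recording:
    """Band-limited recording with intra-/inter-block planted correlations.

    Channel c in block k mixes a global source g, a block source u_k and
    private noise: with a = sqrt(rho_lo), b = sqrt(rho_hi - rho_lo),
    c = sqrt(1 - rho_hi),
    ``x = a g + b u_k + c e``, giving expected correlation rho_hi within a
    block and rho_lo across blocks. Labels come from the packaged montage
    so region/hemisphere stages are exercised directly.
    """
    montage = load_montage()
    regioned = [e.label for e in montage.electrodes if e.region is not None]
    if spec.n_channels > len(regioned):
        raise DomainError(
            f"{spec.n_channels} channels requested but montage offers "
            f"{len(regioned)} regioned labels")
    labels = tuple(regioned[:spec.n_channels])
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    blocks = spec.block_assignment()
    g = rng.standard_normal(n)
    sources = {k: rng.standard_normal(n) for k in range(len(blocks))}
    a = np.sqrt(spec.rho_lo)
    b = np.sqrt(spec.rho_hi - spec.rho_lo)
    c = np.sqrt(1.0 - spec.rho_hi)
    data = np.empty((spec.n_channels, n))
    for k, block in enumerate(blocks):
        for ch in block:
            data[ch] = a * g + b * sources[k] + c * rng.standard_normal(n)
    data = _bandpass(data, spec.fs, spec.carrier)
    return Recording(data=data, fs=spec.fs, labels=labels,
                     band=spec.carrier.name if spec.carrier.name in
                     ("delta", "theta", "alpha", "beta") else "broadband")
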