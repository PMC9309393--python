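"""Recording I/O, wavelet-packet band extraction and window slicing.

A :class:`Recording` is the unit every connectivity estimator consumes:
a channels x samples matrix with a sampling rate, ordered channel labels
and an optional band tag. The four canonical EEG rhythms are extracted by
wavelet packet decomposition (WPD): the signal is decomposed into a full
binary wavelet tree of depth ``level``, whose 2**level leaves tile
[0, fs/2] in equal-width frequency strips once they are re-ordered from
natural (tree) order to frequency order; a band is reconstructed from the
leaves whose nominal strip overlaps the band's [lo, hi) interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pywt
import scipy.io

from .errors import ConfigError, DomainError, FormatError

BAND_TAGS = ("delta", "theta", "alpha", "beta", "broadband")


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise DomainError(f"band {self.name}: need 0 < lo < hi, got [{self.lo}, {self.hi}]")


#: Canonical EEG rhythm bands (Hz).
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
}


@dataclass(frozen=True)
class Recording:
    """Multichannel time series: channels x samples, with rate and labels."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    band: str = "broadband"

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.data.ndim != 2:
            raise FormatError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise FormatError(
                f"{self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("channel labels must be unique")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if self.data.shape[1] < 2:
            raise FormatError("recording needs at least 2 samples")
        if self.band not in BAND_TAGS:
            raise ConfigError(f"unknown band tag {self.band!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"ch{i}" for i in range(n))


def load_recording(
    path: str | Path,
    fs: Optional[float] = None,
    labels: Optional[Sequence[str]] = None,
    var_name: Optional[str] = None,
) -> Recording:
    """Load a broadband recording from .mat, delimited text, or .npy.

    ``.mat`` files must hold one 2-D numeric array (or name it with
    *var_name*); delimited text is channels-as-rows. A ``.npy`` array may
    carry a JSON sidecar ``<stem>.json`` with ``{"fs": ..., "labels": ...}``.
    The array is oriented so the longer axis is samples whenever *labels*
    pin the channel count.
    """
    path = Path(path)
    sidecar_fs = sidecar_labels = None
    if path.suffix == ".mat":
        mat = scipy.io.loadmat(path)
        if "fs" in mat:
            sidecar_fs = float(np.asarray(mat["fs"]).ravel()[0])
        if "labels" in mat:
            def unwrap(v):
                while isinstance(v, np.ndarray):
                    v = v.ravel()[0]
                return str(v).strip()
            sidecar_labels = [unwrap(v) for v in np.asarray(mat["labels"]).ravel()]
        arrays = {k: v for k, v in mat.items()
                  if not k.startswith("__") and k not in ("fs", "labels")
                  and isinstance(v, np.ndarray) and v.ndim == 2 and v.dtype.kind in "fiu"}
        if var_name is not None:
            if var_name not in arrays:
                raise FormatError(f"variable {var_name!r} not found in {path.name}")
            data = arrays[var_name]
        elif len(arrays) == 1:
            data = next(iter(arrays.values()))
        else:
            raise FormatError(
                f"{path.name} holds {len(arrays)} 2-D arrays; pass var_name"
            )
    elif path.suffix == ".npy":
        data = np.load(path)
        sc = path.with_suffix(".json")
        if sc.exists():
            meta = json.loads(sc.read_text())
            sidecar_fs = meta.get("fs")
            sidecar_labels = meta.get("labels")
    else:
        rows = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                rows.append([float(v) for v in line.replace(",", " ").split()])
            except ValueError:
                raise FormatError(f"{path.name} line {lineno}: non-numeric value") from None
        if not rows:
            raise FormatError(f"{path.name}: no data rows")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"{path.name}: ragged rows (widths {sorted(widths)})")
        data = np.array(rows)

    data = np.atleast_2d(np.asarray(data, dtype=float))
    fs = fs if fs is not None else sidecar_fs
    if fs is None:
        raise ConfigError(f"no sampling rate for {path.name}: pass fs or provide a sidecar")
    labels = labels if labels is not None else sidecar_labels
    if labels is not None and data.shape[0] != len(labels) and data.shape[1] == len(labels):
        data = data.T  # stored samples x channels; labels fix the orientation
    if labels is None:
        labels = _default_labels(data.shape[0])
    return Recording(data=data, fs=float(fs), labels=tuple(labels))


def save_recording(rec: Recording, path: str | Path, var_name: str = "eeg") -> None:
    """Write a recording to .mat (with fs and labels) or .npy + JSON sidecar."""
    path = Path(path)
    if path.suffix == ".mat":
        scipy.io.savemat(path, {var_name: rec.data, "fs": rec.fs,
                                "labels": np.array(rec.labels, dtype=object)})
    elif path.suffix == ".npy":
        np.save(path, rec.data)
        path.with_suffix(".json").write_text(
            json.dumps({"fs": rec.fs, "labels": list(rec.labels), "band": rec.band}))
    else:
        header = f"# fs={rec.fs} labels={','.join(rec.labels)} band={rec.band}\n"
        body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in rec.data)
        path.write_text(header + body + "\n")


def _leaf_selection(fs: float, level: int, band: BandSpec) -> list[int]:
    """Frequency-ordered leaf indices whose nominal strip overlaps the band."""
    width = fs / 2 ** (level + 1)
    sel = []
    for k in range(2**level):
        leaf_lo, leaf_hi = k * width, (k + 1) * width
        if leaf_lo < band.hi and leaf_hi > band.lo:
            sel.append(k)
    return sel


def wpd_band(
    rec: Recording,
    band: BandSpec | str,
    wavelet: str = "db16",
    level: int = 6,
) -> Recording:
    """Band-limit every channel by wavelet-packet decomposition.

    Each channel is decomposed to a full packet tree of depth *level* and
    reconstructed from the frequency-ordered leaves overlapping
    ``[band.lo, band.hi)``. Frequency ordering (Gray-code reordering of the
    natural tree order) is essential: natural order misassigns strips.
    """
    if isinstance(band, str):
        band = BANDS[band]
    if rec.band != "broadband":
        raise ConfigError(f"recording is already band-limited ({rec.band})")
    nyq = rec.fs / 2
    if band.hi > nyq:
        raise DomainError(f"band {band.name} [{band.lo}, {band.hi}] exceeds Nyquist {nyq} Hz")
    leaf_width = rec.fs / 2 ** (level + 1)
    if leaf_width > (band.hi - band.lo):
        raise ConfigError(
            f"level {level} gives {leaf_width:g} Hz leaves, wider than the "
            f"{band.hi - band.lo:g} Hz band {band.name}; increase level"
        )
    sel = _leaf_selection(rec.fs, level, band)
    n = rec.n_samples
    out = np.empty_like(rec.data)
    for c in range(rec.n_channels):
        wp = pywt.WaveletPacket(rec.data[c], wavelet, mode="symmetric", maxlevel=level)
        leaves = wp.get_level(level, order="freq")
        recon = pywt.WaveletPacket(None, wavelet, mode="symmetric", maxlevel=level)
        for k in sel:
            recon[leaves[k].path] = leaves[k].data
        out[c] = recon.reconstruct(update=False)[:n]
    tag = band.name if band.name in BAND_TAGS else "broadband"
    return replace(rec, data=out, band=tag)


def slice_windows(rec: Recording, win_samples: int, step_samples: int) -> list[Recording]:
    """Cut a recording into equal-length windows starting at 0, step, 2*step...

    Only full-length windows are emitted; each inherits fs, labels and band.
    """
    if not (0 < win_samples <= rec.n_samples):
        raise DomainError(
            f"window of {win_samples} samples does not fit in {rec.n_samples}")
    if step_samples < 1:
        raise DomainError("step must be >= 1 sample")
    out = []
    start = 0
    while start + win_samples <= rec.n_samples:
        out.append(replace(rec, data=rec.data[:, start:start + win_samples]))
        start += step_samples
    return out


def window_offsets(n_samples: int, win_samples: int, step_samples: int) -> list[int]:
    """Start indices of the windows :func:`slice_windows` would emit."""
    return list(range(0, n_samples - win_samples + 1, step_samples))
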