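"""Group-level aggregation, condition differences, and dynamic series.

Channel-level connectivity is rolled up to anatomical groups by summation:
the connectivity between groups z_a and z_b is the sum of the pairwise
channel connectivities C(x_i, y_j) over all x_i in z_a and y_j in z_b.
Within a group, internal connectivity counts each unordered channel pair
once. Group levels are the 12 label-prefix regions, the two hemispheres
(midline electrodes excluded), or their cross (AFL, AFR, ...).

Comparable connectivity is the elementwise difference of two conditions'
matrices (positive = first condition stronger). Dynamic connectivity is a
time-ordered sequence of matrices computed on successive fixed-length
windows of one recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError
from .metrics import ConnectivityMatrix, connectivity_matrix
from .montage import Montage
from .preprocess import BandSpec, Recording, slice_windows, window_offsets

logger = logging.getLogger(__name__)

LEVELS = ("region", "hemisphere", "region-hemisphere")


@dataclass
class GroupMatrix:
    """Aggregated group x group connectivity at one anatomical level."""

    weights: np.ndarray
    groups: tuple[str, ...]
    level: str
    metric: str = "pcc"
    band: str = "broadband"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.groups = tuple(self.groups)
        if self.weights.shape != (len(self.groups),) * 2:
            raise DomainError("weights shape inconsistent with group count")
        if self.level not in LEVELS:
            raise DomainError(f"unknown level {self.level!r}")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.weights[self.groups.index(a), self.groups.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.groups, columns=self.groups)


def _grouping(cm: ConnectivityMatrix, montage: Montage, level: str
              ) -> dict[str, list[int]]:
    """Map group name -> channel indices of cm, dropping unmappable labels."""
    if level not in LEVELS:
        raise DomainError(f"level must be one of {LEVELS}, got {level!r}")
    groups: dict[str, list[int]] = {}
    dropped = []
    for idx, lab in enumerate(cm.labels):
        if lab not in montage:
            dropped.append(lab)
            continue
        e = montage.electrode(lab)
        if level == "region":
            key = e.region
        elif level == "hemisphere":
            key = e.hemisphere if e.hemisphere in ("left", "right") else None
        else:
            key = (e.region + e.hemisphere[0].upper()
                   if e.region is not None and e.hemisphere != "midline" else None)
        if key is None:
            dropped.append(lab)
            continue
        groups.setdefault(key, []).append(idx)
    if dropped:
        logger.warning("dropped %d unmappable channel(s) at level %s: %s",
                       len(dropped), level, ", ".join(dropped))
    if not groups:
        raise DomainError(f"no channel maps to any group at level {level!r}")
    return dict(sorted(groups.items()))


def internal_connectivity(cm: ConnectivityMatrix, montage: Montage,
                          level: str = "region") -> pd.Series:
    """Per-group sum of pairwise weights over unordered within-group pairs.

    A singleton group has no pairs and scores 0. Negative totals are legal
    when the base metric is signed.
    """
    groups = _grouping(cm, montage, level)
    out = {}
    for name, idx in groups.items():
        sub = cm.weights[np.ix_(idx, idx)]
        out[name] = float(np.triu(sub, k=1).sum())
    return pd.Series(out, name=f"internal_{cm.metric}")


def aggregate_groups(cm: ConnectivityMatrix, montage: Montage,
                     level: str = "region") -> GroupMatrix:
    """Sum channel-pair connectivity into a group x group matrix.

    Off-diagonal (z_a, z_b) sums cm[x_i, y_j] over all cross pairs; the
    diagonal holds each group's internal connectivity (unordered pairs).
    """
    groups = _grouping(cm, montage, level)
    names = list(groups)
    m = len(names)
    w = np.zeros((m, m))
    for a in range(m):
        ia = groups[names[a]]
        sub = cm.weights[np.ix_(ia, ia)]
        w[a, a] = np.triu(sub, k=1).sum()
        for b in range(a + 1, m):
            ib = groups[names[b]]
            w[a, b] = w[b, a] = cm.weights[np.ix_(ia, ib)].sum()
    return GroupMatrix(weights=w, groups=tuple(names), level=level,
                       metric=cm.metric, band=cm.band,
                       meta={"n_channels": cm.n_channels})


def comparable_difference(cm_a: ConnectivityMatrix, cm_b: ConnectivityMatrix,
                          condition_a: str = "A", condition_b: str = "B"
                          ) -> ConnectivityMatrix:
    """Elementwise difference of two conditions (positive = A stronger).

    Labels must match in order; use :meth:`ConnectivityMatrix.reorder` to
    align explicitly -- no silent reordering is performed.
    """
    if cm_a.labels != cm_b.labels:
        raise AlignmentError(
            "label mismatch between conditions; reorder explicitly first")
    if cm_a.metric != cm_b.metric or cm_a.band != cm_b.band:
        raise AlignmentError(
            f"cannot compare {cm_a.metric}/{cm_a.band} with {cm_b.metric}/{cm_b.band}")
    return ConnectivityMatrix(
        weights=cm_a.weights - cm_b.weights, metric=cm_a.metric,
        labels=cm_a.labels, band=cm_a.band,
        meta={"comparison": f"{condition_a} - {condition_b}",
              "condition_a": condition_a, "condition_b": condition_b})


@dataclass
class DynamicSeries:
    """Time-ordered connectivity frames from sliding windows."""

    frames: list[ConnectivityMatrix]
    window: int
    step: int
    t0_offsets: list[int]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.t0_offsets):
            raise DomainError("one offset per frame required")
        tags = {(f.labels, f.metric, f.band) for f in self.frames}
        if len(tags) > 1:
            raise DomainError("frames must share labels, metric and band")

    def __len__(self) -> int:
        return len(self.frames)

    def edge_series(self, a: str, b: str) -> np.ndarray:
        """One edge's weight across all frames, in time order."""
        return np.array([f[a, b] for f in self.frames])


def dynamic_series(rec: Recording, metric: str = "pcc",
                   win: Optional[int] = None, step: Optional[int] = None,
                   band: Optional[BandSpec | str] = None,
                   **params: Any) -> DynamicSeries:
    """Connectivity matrix per sliding window, frames in time order.

    Defaults: 2 s non-overlapping windows. The recording should already be
    band-decomposed; windows are cut from it directly so per-window filter
    transients never arise.
    """
    if win is None:
        win = int(round(2.0 * rec.fs))
    if step is None:
        step = win
    wins = slice_windows(rec, win, step)
    frames = [connectivity_matrix(w, metric=metric, band=band, **params)
              for w in wins]
    return DynamicSeries(frames=frames, window=win, step=step,
                         t0_offsets=window_offsets(rec.n_samples, win, step))
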