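"""Scalp electrode geometry and anatomical groupings.

The packaged default montage is an extended 10-20 (10-10) layout with 81
labeled electrodes and template 3D coordinates. Labels encode anatomy:
a region prefix (one of the 12 groups AF, C, CP, F, FC, FP, FT, O, P, PO,
T, TP) and a side suffix -- odd trailing index = left hemisphere, even =
right, a trailing ``z`` (including Nz/Iz) = midline. Nz and Iz fall outside
the 12 region groups but remain renderable nodes.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .errors import DomainError, FormatError, MontageLookupError

#: The 12 anatomical region prefixes, longest first so that prefix
#: matching prefers FC over F, PO over P, etc.
REGIONS: tuple[str, ...] = ("AF", "CP", "FC", "FP", "FT", "PO", "TP", "C", "F", "O", "P", "T")

HEMISPHERES: tuple[str, ...] = ("left", "right", "midline")

_DEFAULT_RESOURCE = "standard_1020_81.txt"


def region_of_label(label: str) -> Optional[str]:
    """Region group of a 10-20 style label by longest-prefix match.

    ``Fp1`` maps to ``FP`` (case-insensitive match); labels whose prefix is
    outside the 12-group set (``Nz``, ``Iz``) map to ``None``.
    """
    stem = re.match(r"[A-Za-z]+", label)
    head = (stem.group(0) if stem else label).upper()
    # strip the midline 'z' marker so "AFZ" matches prefix "AF" not "AFZ"
    if head.endswith("Z") and len(head) > 1:
        head = head[:-1]
    for reg in sorted(REGIONS, key=len, reverse=True):
        if head == reg:
            return reg
    return None


def hemisphere_of(label: str) -> str:
    """Hemisphere of a 10-20 style label.

    Odd trailing index -> ``left``; even -> ``right``; trailing ``z``
    (including Nz and Iz) -> ``midline``.
    """
    m = re.match(r"^[A-Za-z]*?([zZ]|\d+)$", label)
    if not m:
        raise DomainError(f"label {label!r} has neither a digit nor a 'z' suffix")
    tail = m.group(1)
    if tail.lower() == "z":
        return "midline"
    return "left" if int(tail) % 2 == 1 else "right"


@dataclass(frozen=True)
class Electrode:
    """One scalp electrode: label, 3D scene coordinate, anatomical tags."""

    label: str
    coord: np.ndarray
    region: Optional[str]
    hemisphere: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if self.coord.shape != (3,):
            raise FormatError(f"electrode {self.label!r}: coordinate must be a 3-vector")


@dataclass
class Montage:
    """Ordered electrode set with region and hemisphere indices."""

    electrodes: list[Electrode]
    region_index: dict[str, list[str]] = field(init=False)
    hemisphere_index: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.electrodes:
            key = e.label.lower()
            if key in seen:
                raise FormatError(f"duplicate electrode label {e.label!r}")
            seen[key] = e.label
        self.region_index = {}
        self.hemisphere_index = {h: [] for h in HEMISPHERES}
        for e in self.electrodes:
            if e.region is not None:
                self.region_index.setdefault(e.region, []).append(e.label)
            self.hemisphere_index[e.hemisphere].append(e.label)
        self._by_label = {e.label.lower(): e for e in self.electrodes}

    def __len__(self) -> int:
        return len(self.electrodes)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]

    def electrode(self, label: str) -> Electrode:
        try:
            return self._by_label[label.lower()]
        except KeyError:
            raise MontageLookupError(f"label {label!r} not in montage") from None

    def __contains__(self, label: str) -> bool:
        return label.lower() in self._by_label

    def coords(self, labels: Optional[Iterable[str]] = None) -> np.ndarray:
        labs = self.labels if labels is None else list(labels)
        return np.array([self.electrode(l).coord for l in labs])

    def region_hemisphere_index(self) -> dict[str, list[str]]:
        """Region x hemisphere cross groups (``AFL`` = AF and left, ...).

        Derived on demand, never stored; midline electrodes belong to no
        cross group. Only non-empty groups are returned.
        """
        out: dict[str, list[str]] = {}
        for e in self.electrodes:
            if e.region is None or e.hemisphere == "midline":
                continue
            out.setdefault(e.region + e.hemisphere[0].upper(), []).append(e.label)
        return out


def region_of(label: str, montage: Montage) -> Optional[str]:
    """Region of an electrode that must exist in *montage*."""
    return montage.electrode(label).region


def _parse_montage_lines(lines: Iterable[str]) -> list[Electrode]:
    electrodes = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) != 4:
            raise FormatError(f"line {lineno}: expected 'label x y z', got {raw!r}")
        label = parts[0]
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric coordinate in {raw!r}") from None
        electrodes.append(
            Electrode(label=label, coord=np.array(xyz), region=region_of_label(label),
                      hemisphere=hemisphere_of(label))
        )
    return electrodes


def load_montage(source: Optional[str | Path] = None) -> Montage:
    """Load a montage from a text table, or the packaged 81-electrode default.

    The table has one electrode per line, ``label x y z``, whitespace- or
    comma-delimited; ``#`` starts a comment.
    """
    if source is None:
        text = (
            importlib.resources.files("eegconn.data")
            .joinpath(_DEFAULT_RESOURCE)
            .read_text()
        )
        lines = text.splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    return Montage(_parse_montage_lines(lines))
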