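"""The 96-channel single-base-substitution (SBS) mutation-type scheme.

Somatic single-base substitutions are conventionally reported with the
pyrimidine of the mutated base pair as reference, giving six base
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G).  Each class is
refined by the immediate 5' and 3' flanking bases, yielding
6 x 4 x 4 = 96 mutation channels with labels such as ``A[C>A]A``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

BASES: tuple[str, ...] = ("A", "C", "G", "T")
BASE_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_LABEL_RE = re.compile(r"^([ACGT])\[([CT])>([ACGT])\]([ACGT])$")


def canonical_channels() -> tuple[str, ...]:
    """All 96 channel labels, grouped by base class, flanks in A<C<G<T order."""
    return tuple(
        f"{f5}[{cls}]{f3}" for cls in BASE_CLASSES for f5 in BASES for f3 in BASES
    )


def base_class(label: str) -> str:
    """Base substitution class (e.g. ``C>A``) of a channel label."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"not a valid SBS channel label: {label!r}")
    ref, alt = m.group(2), m.group(3)
    if ref == alt:
        raise ValueError(f"reference and alternate base identical in {label!r}")
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class ChannelScheme:
    """An ordered set of 96 SBS channels shared by all matrices of an analysis.

    The default ordering groups the 16 trinucleotide contexts of each base
    class contiguously, classes in the order C>A, C>G, C>T, T>A, T>C, T>G.
    """

    channels: tuple[str, ...] = field(default_factory=canonical_channels)

    def __post_init__(self) -> None:
        if len(self.channels) != 96:
            raise ValueError(f"expected 96 channels, got {len(self.channels)}")
        if len(set(self.channels)) != 96:
            raise ValueError("channel labels must be unique")
        counts: dict[str, int] = {}
        for label in self.channels:
            counts[base_class(label)] = counts.get(base_class(label), 0) + 1
        if any(counts.get(cls, 0) != 16 for cls in BASE_CLASSES):
            raise ValueError("each base class must contribute exactly 16 channels")

    @property
    def base_class_of(self) -> dict[str, str]:
        return {label: base_class(label) for label in self.channels}

    def index_of(self, label: str) -> int:
        return self.channels.index(label)

    def class_indices(self, cls: str) -> np.ndarray:
        """Positions of the 16 channels belonging to one base class."""
        if cls not in BASE_CLASSES:
            raise ValueError(f"unknown base class {cls!r}")
        return np.array(
            [i for i, ch in enumerate(self.channels) if base_class(ch) == cls],
            dtype=np.intp,
        )


#: Module-wide default scheme in canonical order.
CANONICAL_SCHEME = ChannelScheme()
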