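"""Containers and TSV I/O for mutation catalogues, signatures and activities.

All tables are tab-separated with a header row.  Catalogue and signature
tables follow the COSMIC convention: a first column of channel labels
(``MutationType``, ``Type`` and a few other dialect names are accepted)
and one numeric column per sample or signature.  Either orientation
(channels x samples or samples x channels) is accepted on read; matrices
are stored internally as samples x channels in the order of the
:class:`~modsig.channels.ChannelScheme`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CANONICAL_SCHEME, ChannelScheme

_LABEL_COLUMN_NAMES = {"mutationtype", "mutation_type", "type", "mutation types",
                       "mutation type", "channel", "somatic mutation type"}

SIGNATURE_SUM_TOL = 1e-6


@dataclass
class MutationCatalog:
    """Observed mutation counts, one row per sample over the 96 channels."""

    sample_ids: list[str]
    counts: np.ndarray  # (n_samples, 96)
    scheme: ChannelScheme = CANONICAL_SCHEME
    cancer_types: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.scheme.channels):
            raise ValueError(f"counts must be n_samples x 96, got {self.counts.shape}")
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValueError("sample_ids length does not match counts")
        if np.any(self.counts < 0):
            raise ValueError("mutation counts must be non-negative")
        if self.cancer_types is not None and len(self.cancer_types) != len(self.sample_ids):
            raise ValueError("cancer_types length does not match sample_ids")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def total_mutations(self) -> float:
        return float(self.counts.sum())


@dataclass
class SignatureSet:
    """Additive signature profiles; each row a probability distribution."""

    signature_ids: list[str]
    profiles: np.ndarray  # (n_signatures, 96)
    scheme: ChannelScheme = CANONICAL_SCHEME

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[1] != len(self.scheme.channels):
            raise ValueError(f"profiles must be n_signatures x 96, got {self.profiles.shape}")
        if len(self.signature_ids) != self.profiles.shape[0]:
            raise ValueError("signature_ids length does not match profiles")
        if np.any(self.profiles < 0):
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=1)
        off = np.abs(sums - 1.0)
        if np.any(off > SIGNATURE_SUM_TOL):
            bad = self.signature_ids[int(np.argmax(off))]
            raise ValueError(
                f"signature {bad!r} sums to {sums[int(np.argmax(off))]:.6g}, not 1"
            )
        # renormalise away rounding error so downstream maths sees exact simplices
        self.profiles = self.profiles / sums[:, None]

    @property
    def n_signatures(self) -> int:
        return self.profiles.shape[0]


@dataclass
class ActivityMatrix:
    """Non-negative additive activities a[k, i] of signature i in sample k."""

    sample_ids: list[str]
    signature_ids: list[str]
    activities: np.ndarray  # (n_samples, n_signatures)

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.shape != (len(self.sample_ids), len(self.signature_ids)):
            raise ValueError("activities shape does not match id lists")
        if np.any(self.activities < 0):
            raise ValueError("activities must be non-negative")


def _read_labelled_matrix(
    path: str | Path, scheme: ChannelScheme
) -> tuple[list[str], np.ndarray]:
    """Read a channel-labelled TSV in either orientation.

    Returns (entity_ids, values) with values oriented entities x channels
    and channels permuted into scheme order.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    channel_set = set(scheme.channels)
    first_col = df.columns[0]
    row_labels = df[first_col].astype(str).tolist()

    if set(row_labels) & channel_set or first_col.strip().lower() in _LABEL_COLUMN_NAMES:
        # channels x entities
        seen: set[str] = set()
        for lab in row_labels:
            if lab in seen:
                raise ValueError(f"{path}: duplicate channel label {lab!r}")
            seen.add(lab)
        unknown = [lab for lab in row_labels if lab not in channel_set]
        if unknown:
            raise ValueError(f"{path}: unknown channel label {unknown[0]!r}")
        missing = [ch for ch in scheme.channels if ch not in seen]
        if missing:
            raise ValueError(f"{path}: missing channel {missing[0]!r}")
        sub = df.set_index(first_col)
        sub = sub.loc[list(scheme.channels)]
        return [str(c) for c in sub.columns], sub.to_numpy(dtype=float).T

    if channel_set.issubset(set(map(str, df.columns[1:]))):
        # entities x channels, first column entity ids
        extra = [c for c in df.columns[1:] if str(c) not in channel_set]
        if extra:
            raise ValueError(f"{path}: unknown channel label {extra[0]!r}")
        values = df[list(scheme.channels)].to_numpy(dtype=float)
        return row_labels, values

    raise ValueError(
        f"{path}: could not locate the 96 channel labels in the first column "
        "or in the header"
    )


def read_catalog(
    path: str | Path,
    scheme: ChannelScheme = CANONICAL_SCHEME,
    cancer_types: list[str] | None = None,
) -> MutationCatalog:
    """Read a mutation-count catalogue TSV (COSMIC-style channel labels)."""
    ids, values = _read_labelled_matrix(path, scheme)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative mutation counts")
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: mutation counts must be integers")
    return MutationCatalog(ids, np.round(values), scheme, cancer_types)


def read_signatures(
    path: str | Path, scheme: ChannelScheme = CANONICAL_SCHEME
) -> SignatureSet:
    """Read a signature-profile TSV; rows must sum to 1 within 1e-6."""
    ids, values = _read_labelled_matrix(path, scheme)
    return SignatureSet(ids, values, scheme)


def read_activities(path: str | Path) -> ActivityMatrix:
    """Read an activity TSV: sample rows, signature columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
    )


def write_catalog(catalog: MutationCatalog, path: str | Path) -> None:
    """Write a catalogue as channels x samples with a MutationType column."""
    df = pd.DataFrame(
        catalog.counts.T, index=list(catalog.scheme.channels), columns=catalog.sample_ids
    )
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t")


def write_signatures(signatures: SignatureSet, path: str | Path) -> None:
    df = pd.DataFrame(
        signatures.profiles.T,
        index=list(signatures.scheme.channels),
        columns=signatures.signature_ids,
    )
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t")


def write_activities(activities: ActivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        activities.activities,
        index=activities.sample_ids,
        columns=activities.signature_ids,
    )
    df.index.name = "Sample"
    df.to_csv(path, sep="\t")


def apply_pseudocount(catalog: MutationCatalog, value: float = 1.0) -> MutationCatalog:
    """Return a copy of the catalogue with ``value`` added to every count.

    Pseudo-counts are used only where divisions or logarithms of counts
    appear (multiplicative residuals); the Poisson likelihood itself is
    always evaluated on raw counts, where zeros are valid observations.
    """
    if value <= 0:
        raise ValueError("pseudocount must be positive")
    return replace(catalog, counts=catalog.counts + value)
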