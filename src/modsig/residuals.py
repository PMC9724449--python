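"""Residual diagnostics of an additive signature fit.

Two per-sample, per-channel residuals between observed counts X and
model-predicted counts Xhat are used:

    additive:        X - Xhat
    multiplicative:  (X + 1) / (Xhat + 1)

(the pseudo-count of 1 on both sides keeps the ratio finite).  Samples
are then compared by the correlation of their 96-channel residual
profiles and grouped by complete-linkage hierarchical clustering on the
distance 1 - correlation.  If the additive model explained the data up
to Poisson noise the residual correlations would carry essentially no
structure — which is exactly what the Poisson-resampling null control
checks.  Clusters are ranked by the entropy of their cancer-type
composition: low entropy means the residual pattern is specific to one
tumour type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import entropy as _shannon_entropy

from .catalogs import MutationCatalog

Flavour = Literal["additive", "multiplicative"]

DEFAULT_CORRELATION_THRESHOLD = 0.75
DEFAULT_MIN_CLUSTER_SIZE = 10


@dataclass
class ResidualMatrix:
    """Per-sample residual profiles of one flavour."""

    flavour: Flavour
    values: np.ndarray  # (n_samples, 96)
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-sample cluster id, 1-based
    linkage_threshold: float
    n_clusters: int
    ordering: np.ndarray  # dendrogram leaf order (permutation of samples)
    sample_ids: list[str]


@dataclass
class ClusterSummary:
    cluster_id: int
    size: int
    entropy: float
    label_composition: dict[str, int]
    mean_residual_profile: np.ndarray


def compute_residuals(
    observed: MutationCatalog,
    predicted: np.ndarray,
    flavour: Flavour,
    pseudocount: float = 1.0,
) -> ResidualMatrix:
    """Element-wise additive or multiplicative residuals.

    For the multiplicative flavour the pseudo-count is added to both the
    observed and the predicted counts, so the result is strictly
    positive and finite even at empty channels.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != observed.counts.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.counts.shape}, predicted {predicted.shape}"
        )
    if flavour == "additive":
        values = observed.counts - predicted
    elif flavour == "multiplicative":
        denom = predicted + pseudocount
        if np.any(denom <= 0):
            raise ValueError("predicted + pseudocount must be positive")
        values = (observed.counts + pseudocount) / denom
    else:
        raise ValueError(f"unknown residual flavour {flavour!r}")
    return ResidualMatrix(flavour, values, list(observed.sample_ids))


def poisson_resample_control(catalog: MutationCatalog, seed: int) -> MutationCatalog:
    """Draw a synthetic catalogue using the observed counts as Poisson rates.

    This is the null control for the residual analysis: a model that
    reproduced every observed count exactly would leave residuals that
    look like this resample divided by (or minus) its own rates.
    """
    rng = np.random.default_rng(seed)
    counts = rng.poisson(catalog.counts).astype(float)
    return MutationCatalog(
        list(catalog.sample_ids), counts, catalog.scheme, catalog.cancer_types
    )


def residual_correlation_matrix(
    residuals: ResidualMatrix, method: Literal["pearson", "spearman"] = "pearson"
) -> np.ndarray:
    """Sample-by-sample correlation of residual profiles.

    Pairs involving a constant profile (undefined correlation) are
    reported as 0 with a warning; the diagonal is always 1.
    """
    V = residuals.values
    if V.shape[0] < 2:
        raise ValueError("need at least two samples to correlate")
    if method == "spearman":
        from scipy.stats import rankdata

        V = rankdata(V, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = V.std(axis=1)
    constant = sd == 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant residual profile(s); "
            "their pairwise correlations are reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    centred = V - V.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * np.sqrt(V.shape[1]))
    Z = centred / denom[:, None]
    corr = Z @ Z.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def cluster_by_residual_correlation(
    corr: np.ndarray, threshold: float = DEFAULT_CORRELATION_THRESHOLD,
    sample_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Complete-linkage clustering on distance 1 - correlation.

    Flat clusters are cut where the complete-linkage merge distance
    exceeds 1 - threshold, i.e. every pair inside a cluster correlates
    above the threshold.  The dendrogram leaf order is retained for
    heat-map rendering.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="complete")
    labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
    order = leaves_list(Z)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(corr.shape[0])]
    return ClusterAssignment(
        labels=labels,
        linkage_threshold=threshold,
        n_clusters=int(labels.max()),
        ordering=order,
        sample_ids=list(ids),
    )


def cluster_entropy(
    assignment: ClusterAssignment,
    labels: list[str],
    residuals: ResidualMatrix | None = None,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[ClusterSummary]:
    """Summarise clusters of at least ``min_size`` samples, sorted by entropy.

    Entropy S = -sum_i p_i log p_i (natural log) of the cancer-type
    frequencies inside the cluster; S = 0 iff the cluster is a single
    type.  Smaller clusters are excluded.
    """
    if len(labels) != len(assignment.labels):
        raise ValueError("labels must align with clustered samples")
    labels_arr = np.asarray(labels, dtype=object)
    out: list[ClusterSummary] = []
    for cid in np.unique(assignment.labels):
        members = np.flatnonzero(assignment.labels == cid)
        if members.size < min_size:
            continue
        types, counts = np.unique(labels_arr[members], return_counts=True)
        S = float(_shannon_entropy(counts))  # natural log
        profile = (
            residuals.values[members].mean(axis=0)
            if residuals is not None
            else np.full(96, np.nan)
        )
        out.append(
            ClusterSummary(
                cluster_id=int(cid),
                size=int(members.size),
                entropy=S,
                label_composition={str(t): int(n) for t, n in zip(types, counts)},
                mean_residual_profile=profile,
            )
        )
    out.sort(key=lambda s: (s.entropy, -s.size))
    return out
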