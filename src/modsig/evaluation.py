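"""Scoring and reporting: cosine similarity, MSE, modulation impact, and
per-group (cancer-type) comparison tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogs import MutationCatalog, SignatureSet
from .channels import BASE_CLASSES
from .inference import FitResult
from .model import ModulatoryFit, additive_reconstruction, modulation_factors


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u| |v|); raises on zero vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def mse(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared element-wise difference."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError(f"shape mismatch {estimate.shape} vs {truth.shape}")
    return float(np.mean((estimate - truth) ** 2))


def impact_profile(fit: ModulatoryFit) -> np.ndarray:
    """Sample-averaged modulation per channel, <1 + c[k] r[j]>_k."""
    return modulation_factors(fit).mean(axis=0)


@dataclass
class GroupReport:
    group_label: str
    n_samples: int
    total_gain: float
    gain_per_mutation: float
    impact: np.ndarray
    mse_additive: float
    mse_extended: float
    mse_ratio: float
    mse_by_class_additive: dict[str, float]
    mse_by_class_extended: dict[str, float]


def _group_metrics(
    label: str,
    counts: np.ndarray,
    result: FitResult,
    signatures: SignatureSet,
) -> GroupReport:
    Xhat_add = additive_reconstruction(result.additive_activities, signatures)
    Xhat_ext = additive_reconstruction(result.activities, signatures)
    pred_ext = modulation_factors(result.modulatory) * Xhat_ext
    total = max(float(counts.sum()), 1.0)
    m_add = mse(Xhat_add, counts)
    m_ext = mse(pred_ext, counts)
    cls_add, cls_ext = {}, {}
    for cls in BASE_CLASSES:
        idx = signatures.scheme.class_indices(cls)
        cls_add[cls] = mse(Xhat_add[:, idx], counts[:, idx])
        cls_ext[cls] = mse(pred_ext[:, idx], counts[:, idx])
    return GroupReport(
        group_label=label,
        n_samples=counts.shape[0],
        total_gain=result.gain,
        gain_per_mutation=result.gain / total,
        impact=impact_profile(result.modulatory),
        mse_additive=m_add,
        mse_extended=m_ext,
        mse_ratio=m_add / m_ext if m_ext > 0 else np.inf,
        mse_by_class_additive=cls_add,
        mse_by_class_extended=cls_ext,
    )


def group_report(
    observed: MutationCatalog,
    signatures: SignatureSet,
    results: dict[str, FitResult],
    labels: list[str],
) -> list[GroupReport]:
    """Per-group modulation reports, sorted by descending normalized gain.

    ``results`` maps each group label (e.g. cancer type) to the fit of
    that group's samples; ``labels`` assigns each catalogue sample to a
    group.  MSEs compare predicted with raw observed counts under both
    models; the per-base-class breakdown averages over the 16 channels
    of each class.
    """
    if len(labels) != observed.n_samples:
        raise ValueError("labels must align with catalogue samples")
    labels_arr = np.asarray(labels, dtype=object)
    reports = []
    for label, result in results.items():
        members = np.flatnonzero(labels_arr == label)
        if members.size == 0:
            raise ValueError(f"group {label!r} has no samples in the catalogue")
        if result.activities.activities.shape[0] != members.size:
            raise ValueError(f"fit for group {label!r} does not match its sample count")
        reports.append(
            _group_metrics(label, observed.counts[members], result, signatures)
        )
    reports.sort(key=lambda g: g.gain_per_mutation, reverse=True)
    return reports


def group_report_table(reports: list[GroupReport]) -> pd.DataFrame:
    """Flatten group reports into a tidy table (one row per group)."""
    rows = []
    for g in reports:
        row = {
            "group": g.group_label,
            "n_samples": g.n_samples,
            "total_gain": g.total_gain,
            "gain_per_mutation": g.gain_per_mutation,
            "mse_additive": g.mse_additive,
            "mse_extended": g.mse_extended,
            "mse_ratio": g.mse_ratio,
        }
        for cls in BASE_CLASSES:
            row[f"mse_add[{cls}]"] = g.mse_by_class_additive[cls]
            row[f"mse_ext[{cls}]"] = g.mse_by_class_extended[cls]
        rows.append(row)
    return pd.DataFrame(rows)
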