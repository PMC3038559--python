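"""Undirected functional connectivity: Pearson, Fisher z, group Z-matrix.

Per subject, connectivity between two ROI series X and Y is the sample
Pearson coefficient

    r = sum_i (X_i - X̄)(Y_i - Ȳ) / sqrt(sum (X_i - X̄)^2 sum (Y_i - Ȳ)^2).

For group analysis each r is variance-stabilised with the Fisher
transform z = arctanh(r) and the cohort is summarised per ROI pair by
the Z-matrix

    Z_ij = mean_s(z_s,ij) / SD_s(z_s,ij),

the cross-subject average correlation normalised by the between-subject
deviation, with the diagonal set to 1 by convention (its SD is zero).
Significance per pair comes from a one-sample t test of the subject
Fisher-z values against zero (t = Z * sqrt(n), df = n - 1), Bonferroni-
corrected over the R(R-1)/2 unique pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import ROITimeSeriesSet
from .edges import Edge, SignificantEdgeList

__all__ = [
    "SubjectCorrMatrix",
    "GroupZMatrix",
    "pearson_matrix",
    "fisher_z",
    "cohort_correlations",
    "group_z_matrix",
    "correlation_edges",
]

logger = logging.getLogger(__name__)

#: Corrected-p cutoffs defining significance tiers 1, 2, 3.
TIER_CUTOFFS = (0.005, 0.001, 0.0001)


@dataclass(frozen=True)
class SubjectCorrMatrix:
    """Symmetric Pearson correlation matrix for one subject."""

    r: np.ndarray
    roi_labels: tuple[str, ...]
    subject_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        m = self.r
        if m.shape != (len(self.roi_labels),) * 2:
            raise ValueError("correlation matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(m) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("correlation diagonal must be 1")


@dataclass(frozen=True)
class GroupZMatrix:
    """Cohort-level standardized Fisher-z connectivity.

    ``Z`` is mean/SD of the subject Fisher-z values (diagonal fixed at
    1); ``p`` holds uncorrected two-sided one-sample-t p-values;
    ``tiers`` the per-pair significance tier after Bonferroni correction
    (0 = not significant).  Pairs whose cross-subject SD is zero are
    marked with signed infinity in ``Z`` and recorded in
    ``degenerate_pairs``.
    """

    z_subject: np.ndarray  # (n_subjects, R, R)
    Z: np.ndarray
    p: np.ndarray
    tiers: np.ndarray
    roi_labels: tuple[str, ...]
    subject_ids: tuple[str, ...]
    degenerate_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def n_subjects(self) -> int:
        return self.z_subject.shape[0]

    @property
    def n_pairs(self) -> int:
        r = len(self.roi_labels)
        return r * (r - 1) // 2


def pearson_matrix(
    subject: np.ndarray,
    roi_labels: Sequence[str] | None = None,
    subject_id: str = "subject",
) -> SubjectCorrMatrix:
    """Sample Pearson correlation matrix of one (time x ROI) matrix."""
    x = np.asarray(subject, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (time x ROI) matrix")
    n, r = x.shape
    if roi_labels is None:
        roi_labels = tuple(f"roi{i}" for i in range(r))
    if n < 3:
        raise ValueError(f"subject {subject_id!r}: need >= 3 time points")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = ", ".join(str(roi_labels[j]) for j in np.where(sd == 0)[0])
        raise ValueError(
            f"subject {subject_id!r}: zero-variance ROI(s) {bad}; "
            "Pearson correlation is undefined"
        )
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SubjectCorrMatrix(corr, tuple(roi_labels), subject_id)


def fisher_z(r, clip: bool = False):
    """Fisher r-to-z transform ``z = arctanh(r) = 0.5 ln((1+r)/(1-r))``.

    Undefined at |r| >= 1; pass ``clip=True`` to explicitly clamp such
    values to just inside the open interval first.
    """
    arr = np.asarray(r, dtype=float)
    if clip:
        eps = np.finfo(float).eps
        arr = np.clip(arr, -1 + eps, 1 - eps)
    elif np.any(np.abs(arr) >= 1):
        raise ValueError(
            "fisher_z is undefined at |r| >= 1; pass clip=True to clamp "
            "explicitly"
        )
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def cohort_correlations(ts: ROITimeSeriesSet) -> list[SubjectCorrMatrix]:
    """Per-subject Pearson matrices for a cohort."""
    return [
        pearson_matrix(mat, ts.roi_labels, subject_id=sid) for sid, mat in ts
    ]


def group_z_matrix(
    cohort_r: Sequence[SubjectCorrMatrix], alpha_family: float = 0.005
) -> GroupZMatrix:
    """Standardized group Fisher-z matrix with per-pair significance.

    Requires at least 3 subjects (the cross-subject SD is meaningless
    below that).  Off-diagonal subject correlations must satisfy
    |r| < 1 so the Fisher transform is finite.
    """
    if len(cohort_r) < 3:
        raise ValueError(
            f"group Z-matrix needs >= 3 subjects, got {len(cohort_r)}"
        )
    labels = cohort_r[0].roi_labels
    for m in cohort_r:
        if m.roi_labels != labels:
            raise ValueError("subject correlation matrices have mismatched ROI labels")
    r_dim = len(labels)
    n = len(cohort_r)
    off = ~np.eye(r_dim, dtype=bool)
    z = np.zeros((n, r_dim, r_dim))
    for s, m in enumerate(cohort_r):
        if np.any(np.abs(m.r[off]) >= 1):
            raise ValueError(
                f"subject {m.subject_id!r} has an off-diagonal correlation of "
                "+-1; Fisher transform undefined"
            )
        z[s][off] = np.arctanh(m.r[off])

    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        big_z = np.where(sd > 0, mean / sd, np.sign(mean) * np.inf)
        t = big_z * np.sqrt(n)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(np.isinf(big_z), np.where(mean != 0, 0.0, 1.0), p)
    np.fill_diagonal(big_z, 1.0)
    np.fill_diagonal(p, np.nan)

    degenerate = []
    iu = np.triu_indices(r_dim, k=1)
    for i, j in zip(*iu):
        if sd[i, j] == 0:
            degenerate.append((labels[i], labels[j]))
    if degenerate:
        logger.warning(
            "zero cross-subject SD for pair(s) %s; Z set to signed infinity",
            degenerate,
        )

    n_pairs = r_dim * (r_dim - 1) // 2
    p_corr = np.minimum(p * n_pairs, 1.0)
    tiers = np.zeros((r_dim, r_dim), dtype=int)
    for level, cutoff in enumerate(TIER_CUTOFFS, start=1):
        tiers[p_corr < cutoff] = level
    np.fill_diagonal(tiers, 0)

    return GroupZMatrix(
        z_subject=z,
        Z=big_z,
        p=p,
        tiers=tiers,
        roi_labels=labels,
        subject_ids=tuple(m.subject_id for m in cohort_r),
        degenerate_pairs=tuple(degenerate),
    )


def correlation_edges(
    gz: GroupZMatrix, alpha_family: float = 0.005
) -> SignificantEdgeList:
    """Undirected edges surviving Bonferroni correction.

    Pair (i, j) is included iff its uncorrected p is below
    ``alpha_family / n_pairs``; each edge carries the sign of Z and a
    significance tier graded on the corrected p.
    """
    labels = gz.roi_labels
    r_dim = len(labels)
    n_pairs = gz.n_pairs
    edges = []
    if alpha_family > 0:
        threshold = alpha_family / n_pairs
        iu = np.triu_indices(r_dim, k=1)
        for i, j in zip(*iu):
            p_ij = gz.p[i, j]
            if np.isnan(p_ij) or p_ij >= threshold:
                continue
            p_corr = min(p_ij * n_pairs, 1.0)
            tier = sum(p_corr < c for c in TIER_CUTOFFS)
            a, b = sorted((labels[i], labels[j]))
            edges.append(
                Edge(
                    source=a,
                    target=b,
                    weight=float(gz.Z[i, j]),
                    sign=int(np.sign(gz.Z[i, j])),
                    p_corrected=p_corr,
                    tier=tier,
                )
            )
    return SignificantEdgeList(
        directed=False,
        edges=tuple(edges),
        family_alpha=alpha_family,
        n_comparisons=n_pairs,
    )
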