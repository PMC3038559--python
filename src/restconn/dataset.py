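"""Cohort container for regional (ROI) time series.

A cohort is a set of subjects, each contributing one matrix of shape
(time points x ROIs) sampled at a common repetition time (TR).  All
subjects share the same ROI labels and sampling interval; individual
subjects may have different numbers of time points (e.g. after windowing
or discarding leading volumes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["ROITimeSeriesSet"]


@dataclass(frozen=True)
class ROITimeSeriesSet:
    """Multi-subject collection of ROI time-series matrices.

    Parameters
    ----------
    data
        One ``(n_timepoints, n_rois)`` float array per subject.
    roi_labels
        ROI names, shared by every subject; column order of ``data``.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    subject_ids
        One identifier per subject, unique within the cohort.
    """

    data: tuple[np.ndarray, ...]
    roi_labels: tuple[str, ...]
    tr_seconds: float
    subject_ids: tuple[str, ...]

    def __init__(
        self,
        data: Sequence[np.ndarray],
        roi_labels: Sequence[str],
        tr_seconds: float,
        subject_ids: Sequence[str] | None = None,
    ) -> None:
        arrays = tuple(np.asarray(a, dtype=float) for a in data)
        labels = tuple(str(lab) for lab in roi_labels)
        if subject_ids is None:
            subject_ids = tuple(f"sub-{i + 1:02d}" for i in range(len(arrays)))
        else:
            subject_ids = tuple(str(s) for s in subject_ids)
        object.__setattr__(self, "data", arrays)
        object.__setattr__(self, "roi_labels", labels)
        object.__setattr__(self, "tr_seconds", float(tr_seconds))
        object.__setattr__(self, "subject_ids", subject_ids)
        self._validate()

    def _validate(self) -> None:
        if len(self.roi_labels) != len(set(self.roi_labels)):
            raise ValueError("ROI labels must be unique")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if len(self.subject_ids) != len(self.data):
            raise ValueError(
                f"{len(self.subject_ids)} subject ids for {len(self.data)} matrices"
            )
        if len(self.subject_ids) != len(set(self.subject_ids)):
            raise ValueError("subject ids must be unique")
        r = len(self.roi_labels)
        for sid, mat in zip(self.subject_ids, self.data):
            if mat.ndim != 2 or mat.shape[1] != r:
                raise ValueError(
                    f"subject {sid!r}: expected (T, {r}) matrix, got shape {mat.shape}"
                )
            if mat.shape[0] < 2:
                raise ValueError(f"subject {sid!r}: fewer than 2 time points")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"subject {sid!r}: non-finite values in time series")

    # -- introspection -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(zip(self.subject_ids, self.data))

    def __len__(self) -> int:
        return self.n_subjects

    def subject(self, subject_id: str) -> np.ndarray:
        try:
            idx = self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"unknown subject id {subject_id!r}") from None
        return self.data[idx]

    # -- derivation ----------------------------------------------------
    def with_data(self, new_data: Sequence[np.ndarray]) -> "ROITimeSeriesSet":
        """Same cohort metadata with transformed per-subject matrices."""
        return ROITimeSeriesSet(
            new_data, self.roi_labels, self.tr_seconds, self.subject_ids
        )

    def map_subjects(self, fn) -> "ROITimeSeriesSet":
        """Apply ``fn(matrix) -> matrix`` to every subject."""
        return self.with_data([fn(mat) for mat in self.data])

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Per-subject DataFrames (columns = ROI labels)."""
        return {
            sid: pd.DataFrame(mat, columns=list(self.roi_labels))
            for sid, mat in self
        }
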