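"""Lightweight containers carried between pipeline stages.

Arrays are plain numpy; containers only enforce shape/consistency invariants
and carry the metadata (TR, ROI labels, sparsity) the downstream stages need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aal import AAL90_LABELS


@dataclass
class ROITimeSeries:
    """Per-subject ROI signal matrix.

    Parameters
    ----------
    data : ndarray, shape (n_rois, n_volumes)
        One row per region, one column per acquired volume. Units arbitrary.
    tr : float
        Repetition time in seconds.
    roi_labels : tuple of str
        Region names, one per row (AAL-90 by default).
    """

    data: np.ndarray
    tr: float = 2.0
    roi_labels: tuple[str, ...] = AAL90_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ROI time series must be 2-D (n_rois, n_volumes)")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ROI time series contains non-finite values")
        self.roi_labels = tuple(self.roi_labels)
        if len(self.roi_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {self.data.shape[0]} rows"
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.tr

    def copy_with(self, data: np.ndarray) -> "ROITimeSeries":
        return ROITimeSeries(data=data, tr=self.tr, roi_labels=self.roi_labels)


@dataclass
class MotionTrace:
    """Six rigid-body head-motion parameters per volume.

    ``translations`` are in millimetres (x, y, z), ``rotations`` in degrees
    (pitch, roll, yaw).  Must stay volume-aligned with the paired time series.
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        for name, arr in (("translations", self.translations),
                          ("rotations", self.rotations)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must have shape (n_volumes, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ValueError("translations and rotations differ in length")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    def as_matrix(self) -> np.ndarray:
        """(n_volumes, 6) matrix: 3 translations then 3 rotations."""
        return np.hstack([self.translations, self.rotations])


@dataclass
class FDSeries:
    """Framewise displacement per volume, with the scrubbing keep-mask."""

    fd: np.ndarray
    radius: float
    threshold: float
    keep_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1:
            raise ValueError("fd must be 1-D")
        if np.any(self.fd < 0):
            raise ValueError("fd must be nonnegative")
        self.keep_mask = self.fd <= self.threshold


@dataclass
class ExclusionReport:
    """Per-subject motion quality-control verdict."""

    subject_id: str
    kept_fraction: float
    max_translation_mm: float
    max_rotation_deg: float
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        valid = {"scrub_fraction", "translation_limit", "rotation_limit"}
        if not set(self.reasons) <= valid:
            raise ValueError(f"invalid exclusion reasons: {self.reasons}")

    @property
    def excluded(self) -> bool:
        return len(self.reasons) > 0


@dataclass
class ConnectivityMatrix:
    """Fisher-z transformed Pearson correlation matrix (zero diagonal)."""

    z: np.ndarray
    roi_labels: tuple[str, ...] = AAL90_LABELS

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise ValueError("z must be square")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite values (clip r before atanh)")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("z must be symmetric")
        if not np.allclose(np.diag(self.z), 0.0):
            raise ValueError("z diagonal must be zero")
        self.roi_labels = tuple(self.roi_labels)
        if len(self.roi_labels) != n:
            raise ValueError("label/matrix size mismatch")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected binary graph obtained by sparsity thresholding."""

    adjacency: np.ndarray
    sparsity: float
    roi_labels: tuple[str, ...] = AAL90_LABELS

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = a.shape[0]
        if a.ndim != 2 or a.shape[1] != n:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if not 0.0 < self.sparsity < 1.0:
            raise ValueError("sparsity must lie in (0, 1)")
        self.adjacency = a.astype(np.uint8)
        self.roi_labels = tuple(self.roi_labels)
        if len(self.roi_labels) != n:
            raise ValueError("label/matrix size mismatch")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges as (label_i, label_j) pairs, i < j in atlas order."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        on = self.adjacency[iu, ju] > 0
        return [(self.roi_labels[i], self.roi_labels[j])
                for i, j in zip(iu[on], ju[on])]
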