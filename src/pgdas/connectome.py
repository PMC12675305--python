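"""Functional-connectivity construction from ROI time series.

Per-subject functional connectivity (FC) is the Pearson correlation between
the BOLD time series of every pair of regions of interest (ROIs), passed
through the Fisher z-transform ``z = atanh(r)`` to improve normality. The
diagonal (self-connections) is stored as zero because self-connections are
excluded from every downstream analysis. A motion-scrubbing utility removes
high-movement volumes (framewise displacement above a threshold, together
with a window of neighbouring volumes) before correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "FCMatrix",
    "Parcellation",
    "scrub_mask",
    "compute_fc",
    "vectorize_upper",
    "devectorize",
    "read_timeseries",
    "read_fc_matrix",
    "write_fc_matrix",
    "read_parcellation",
]

#: clamp |r| below 1 so the Fisher transform stays finite
R_CLAMP = 1.0 - 1e-7


@dataclass
class RoiTimeSeries:
    """BOLD time series for one subject: T volumes x N ROIs."""

    subject_id: str
    data: np.ndarray
    fd: np.ndarray | None = None
    roi_labels: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D (volumes x ROIs) array")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 ROIs")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in time series of {self.subject_id!r}")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if self.fd.shape != (self.data.shape[0],):
                raise ValueError("fd length must equal the number of volumes")


@dataclass
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix with zero diagonal."""

    subject_id: str
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape != (n, n):
            raise ValueError("FC matrix must be square")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("FC matrix contains non-finite entries")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("FC diagonal must be exactly zero")

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]


@dataclass
class Parcellation:
    """Mapping from ROI index to brain-network label (e.g. the six
    Dosenbach networks DMN/FPN/CON/SMN/ON/CN)."""

    roi_labels: list[str]
    network_of: list[str]
    networks: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if len(self.roi_labels) != len(self.network_of):
            raise ValueError("roi_labels and network_of must align")
        if self.networks is None:
            seen: dict[str, None] = {}
            for lab in self.network_of:
                seen.setdefault(lab, None)
            self.networks = list(seen)
        missing = set(self.network_of) - set(self.networks)
        if missing:
            raise ValueError(f"network labels not listed in networks: {sorted(missing)}")
        if len(self.networks) < 2:
            raise ValueError("need at least 2 networks")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def indices_of(self, network: str) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.network_of) if lab == network])


def scrub_mask(fd: np.ndarray, threshold: float = 0.5, n_prior: int = 1,
               n_post: int = 2) -> np.ndarray:
    """Keep-mask for motion scrubbing.

    A volume is dropped iff its framewise displacement exceeds ``threshold``
    (mm) or it lies within ``n_prior`` volumes before / ``n_post`` volumes
    after such a flagged volume; windows are clipped at the series bounds.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(fd)) or np.any(fd < 0):
        raise ValueError("fd must be finite and non-negative")
    keep = np.ones(fd.size, dtype=bool)
    for t in np.flatnonzero(fd > threshold):
        lo = max(0, t - n_prior)
        hi = min(fd.size, t + n_post + 1)
        keep[lo:hi] = False
    return keep


def compute_fc(ts: RoiTimeSeries, keep: np.ndarray | None = None) -> FCMatrix:
    """Pearson-correlate retained volumes, Fisher-transform, zero the diagonal.

    Correlations are clamped to +/-(1 - 1e-7) before ``atanh`` so that
    perfectly (anti)correlated ROIs give large finite z values.
    """
    data = ts.data
    if keep is not None:
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (data.shape[0],):
            raise ValueError("keep mask length must equal the number of volumes")
        data = data[keep]
    if data.shape[0] < 3:
        raise ValueError(
            f"subject {ts.subject_id!r}: only {data.shape[0]} retained volumes; need >= 3")
    sd = data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ([ts.roi_labels[i] for i in bad[:5]] if ts.roi_labels
                 else [str(i) for i in bad[:5]])
        raise ValueError(f"zero-variance ROI(s) in {ts.subject_id!r}: {names}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FCMatrix(subject_id=ts.subject_id, z=z)


def vectorize_upper(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Row-major upper triangle (i<j), diagonal excluded: the node feature vector."""
    z = fc.z if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    iu = np.triu_indices(z.shape[0], k=1)
    return z[iu].copy()


def devectorize(vec: np.ndarray, subject_id: str = "") -> FCMatrix:
    """Inverse of :func:`vectorize_upper`."""
    vec = np.asarray(vec, dtype=float)
    # solve N(N-1)/2 = len for N
    n = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n * (n - 1) // 2 != vec.size:
        raise ValueError(f"length {vec.size} is not N(N-1)/2 for any integer N")
    z = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    z[iu] = vec
    z = z + z.T
    return FCMatrix(subject_id=subject_id, z=z)


# ----------------------------------------------------------------------- I/O

def read_timeseries(path: str | Path, subject_id: str | None = None,
                    fd: np.ndarray | None = None) -> RoiTimeSeries:
    """Read a delimited text file of one subject's ROI time series.

    Rows are volumes, columns are ROIs; the header row holds ROI labels.
    Delimiter is sniffed from the extension (.csv -> comma, else whitespace/tab).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    df = pd.read_csv(path, sep=sep)
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        fd=fd,
        roi_labels=[str(c) for c in df.columns],
    )


def read_fc_matrix(path: str | Path, subject_id: str | None = None) -> FCMatrix:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else None
    z = np.loadtxt(path, delimiter=sep)
    return FCMatrix(subject_id=subject_id or path.stem, z=z)


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    np.savetxt(path, fc.z, fmt="%.10g", delimiter="\t")


def read_parcellation(path: str | Path) -> Parcellation:
    """Two-column table (roi_label, network_label); header optional."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("parcellation table needs two columns (roi_label, network_label)")
    cols = list(df.columns)
    return Parcellation(roi_labels=[str(v) for v in df[cols[0]]],
                        network_of=[str(v) for v in df[cols[1]]])
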