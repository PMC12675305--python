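"""Population-graph construction.

Subjects are graph nodes; node features are the vectorized upper triangles
of their FC matrices. Edge weights combine an imaging-similarity kernel
(Gaussian kernel on the correlation distance between feature vectors) with
a phenotypic affinity score counting site agreement and age proximity:

    w_uv = exp(-d_uv^2 / (2 sigma^2)) * ( 1[site_u == site_v]
                                        + 1[|age_u - age_v| <= tau] )

so the phenotype gates the imaging similarity: subjects sharing neither
site nor age band get weight zero. The graph is sparsified to each node's
k strongest neighbours, symmetrized by elementwise maximum, and normalized
as A_hat = D^(-1/2) (W + I) D^(-1/2) for use by graph propagation layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectPhenotype",
    "PopulationGraph",
    "GraphConfig",
    "phenotypic_affinity",
    "feature_similarity",
    "pairwise_correlation_distance",
    "build_population_graph",
    "normalize_adjacency",
    "read_phenotypes",
]

#: accepted aliases for required/optional phenotype columns (ABIDE-style)
_COLUMN_ALIASES = {
    "subject_id": ["subject_id", "sub_id", "subid", "id"],
    "age": ["age", "age_at_scan"],
    "site": ["site", "site_id"],
    "sex": ["sex"],
    "fiq": ["fiq"],
    "viq": ["viq"],
    "piq": ["piq"],
    "ados_comm": ["ados_comm", "ados_communication"],
    "ados_social": ["ados_social"],
    "ados_total": ["ados_total"],
    "ados_severity": ["ados_severity", "ados_gotham_severity"],
}


@dataclass
class SubjectPhenotype:
    subject_id: str
    age: float | None
    site: str
    sex: str | None = None
    fiq: float | None = None
    viq: float | None = None
    piq: float | None = None
    ados_comm: float | None = None
    ados_social: float | None = None
    ados_total: float | None = None
    ados_severity: float | None = None

    def __post_init__(self):
        if not str(self.site):
            raise ValueError(f"subject {self.subject_id!r}: empty site label")
        if self.age is not None and not (self.age > 0):
            raise ValueError(f"subject {self.subject_id!r}: age must be positive")


@dataclass
class PopulationGraph:
    """Subject-level graph: features, sparse weighted adjacency, normalized operator."""

    subject_ids: list[str]
    features: np.ndarray            # S x F
    W: np.ndarray                   # S x S, symmetric, nonneg, zero diagonal
    A_hat: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        S = len(self.subject_ids)
        self.features = np.asarray(self.features, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.features.shape[0] != S or self.W.shape != (S, S):
            raise ValueError("features/adjacency do not match the subject list")
        if np.any(self.W < 0) or np.any(np.diag(self.W) != 0):
            raise ValueError("W must be non-negative with zero diagonal")
        if not np.allclose(self.W, self.W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        if self.A_hat is None:
            self.A_hat = normalize_adjacency(self.W)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass
class GraphConfig:
    """Knobs of the edge construction.

    age_tau : inclusive age-proximity window in years.
    sigma : kernel bandwidth on the correlation distance; None uses the
        median heuristic (median of all pairwise distances in the cohort).
    k_neighbors : per-node sparsification degree.
    """

    age_tau: float = 2.0
    sigma: float | None = None
    k_neighbors: int = 10


def phenotypic_affinity(u: SubjectPhenotype, v: SubjectPhenotype,
                        age_tau: float = 2.0) -> int:
    """Site-match plus inclusive age-proximity indicator: a score in {0, 1, 2}."""
    score = int(u.site == v.site)
    if u.age is None or v.age is None:
        logger.warning("missing age for %s or %s; age term treated as 0",
                       u.subject_id, v.subject_id)
    elif abs(u.age - v.age) <= age_tau:
        score += 1
    return score


def _corr_distance(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance feature vector")
    return 1.0 - float(xc @ yc) / (nx * ny)


def feature_similarity(x_u: np.ndarray, x_v: np.ndarray, sigma: float) -> float:
    """Gaussian kernel on the correlation distance d = 1 - corr(x_u, x_v)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x_u = np.asarray(x_u, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    if x_u.shape != x_v.shape:
        raise ValueError("feature vectors must have the same length")
    d = _corr_distance(x_u, x_v)
    return float(np.exp(-(d**2) / (2.0 * sigma**2)))


def pairwise_correlation_distance(features: np.ndarray) -> np.ndarray:
    """S x S matrix of correlation distances between feature rows."""
    X = np.asarray(features, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0)
        raise ValueError(f"zero-variance feature vector at rows {bad[:5].tolist()}")
    C = (Xc @ Xc.T) / np.outer(norms, norms)
    np.clip(C, -1.0, 1.0, out=C)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return D


def build_population_graph(features: np.ndarray,
                           phenotypes: list[SubjectPhenotype],
                           config: GraphConfig | None = None) -> PopulationGraph:
    """Assemble the cohort graph from feature rows and aligned phenotypes.

    Raw weights are imaging similarity times phenotypic affinity; each node
    keeps its ``k_neighbors`` largest weights, the result is symmetrized by
    elementwise maximum, and a node left with no positive edge (its affinity
    is zero against everyone) is attached to its nearest feature-similarity
    neighbour with a warning.
    """
    config = config or GraphConfig()
    X = np.asarray(features, dtype=float)
    S = X.shape[0]
    if S < 2:
        raise ValueError("need at least 2 subjects")
    if len(phenotypes) != S:
        raise ValueError("feature rows and phenotypes must align")

    D = pairwise_correlation_distance(X)
    if config.sigma is None:
        iu = np.triu_indices(S, k=1)
        sigma = float(np.median(D[iu]))
        if sigma <= 0:
            sigma = 1.0
    else:
        sigma = float(config.sigma)
    sim = np.exp(-(D**2) / (2.0 * sigma**2))

    aff = np.zeros((S, S))
    ages = np.array([np.nan if p.age is None else p.age for p in phenotypes])
    sites = np.array([p.site for p in phenotypes], dtype=object)
    site_match = (sites[:, None] == sites[None, :]).astype(float)
    with np.errstate(invalid="ignore"):
        age_match = (np.abs(ages[:, None] - ages[None, :]) <= config.age_tau).astype(float)
    age_match[np.isnan(ages)[:, None] | np.isnan(ages)[None, :]] = 0.0
    if np.any(np.isnan(ages)):
        logger.warning("missing ages: age-proximity term treated as 0 for those subjects")
    aff = site_match + age_match

    W_raw = sim * aff
    np.fill_diagonal(W_raw, 0.0)

    # per-node top-k sparsification
    k = min(config.k_neighbors, S - 1)
    W = np.zeros_like(W_raw)
    for i in range(S):
        order = np.argsort(W_raw[i])[::-1][:k]
        W[i, order] = W_raw[i, order]
    W = np.maximum(W, W.T)

    # re-attach nodes isolated by all-zero affinity
    sim_offdiag = sim.copy()
    np.fill_diagonal(sim_offdiag, -np.inf)
    for i in np.flatnonzero(W.sum(axis=1) == 0):
        j = int(np.argmax(sim_offdiag[i]))
        W[i, j] = W[j, i] = sim[i, j]
        logger.warning("subject %s isolated by zero affinity; attached to nearest "
                       "feature neighbour %s", phenotypes[i].subject_id,
                       phenotypes[j].subject_id)

    return PopulationGraph(
        subject_ids=[p.subject_id for p in phenotypes],
        features=X,
        W=W,
    )


def normalize_adjacency(W: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^(-1/2) (W + I) D^(-1/2)."""
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    A = W + np.eye(W.shape[0])
    d = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return A * np.outer(dinv, dinv)


def read_phenotypes(path) -> list[SubjectPhenotype]:
    """Phenotype CSV with required columns subject_id, age, site.

    ABIDE-style aliases (AGE_AT_SCAN, SITE_ID, ...) are accepted; optional
    IQ/ADOS columns may be missing or contain blanks, which become None.
    """
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in lower:
                resolved[canon] = lower[a]
                break
    for required in ("subject_id", "age", "site"):
        if required not in resolved:
            raise ValueError(f"phenotype table is missing a required column: {required!r}")

    def _get(row, canon, cast=float):
        col = resolved.get(canon)
        if col is None:
            return None
        v = row[col]
        if pd.isna(v):
            return None
        return cast(v)

    out = []
    for _, row in df.iterrows():
        out.append(SubjectPhenotype(
            subject_id=str(row[resolved["subject_id"]]),
            age=_get(row, "age"),
            site=str(row[resolved["site"]]),
            sex=_get(row, "sex", cast=str),
            fiq=_get(row, "fiq"), viq=_get(row, "viq"), piq=_get(row, "piq"),
            ados_comm=_get(row, "ados_comm"),
            ados_social=_get(row, "ados_social"),
            ados_total=_get(row, "ados_total"),
            ados_severity=_get(row, "ados_severity"),
        ))
    return out
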