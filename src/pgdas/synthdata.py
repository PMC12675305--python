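"""Synthetic multi-site FC cohorts with planted biotype structure.

The generator emulates the statistical structure of a multi-site
resting-state cohort: each subject's Fisher-z FC matrix is a network-block
pattern (higher within-network than between-network connectivity) plus a
biotype-specific block offset, a per-site scalar shift, and symmetric
subject-level noise. Clinical scores are coupled to connectivity through the
Frobenius norms of designated network blocks, with a per-biotype intercept
shift so the majority biotype scores higher on average — mirroring the
unbalanced minority/majority split and score ordering typical of
connectivity-based subtyping cohorts.

What it does NOT emulate: hemodynamics, head motion, atlas geometry,
scanner-specific autocorrelation, or any spatial embedding of ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import FCMatrix, Parcellation, RoiTimeSeries, vectorize_upper
from .popgraph import SubjectPhenotype

__all__ = [
    "SynthConfig",
    "SyntheticCohort",
    "default_networks",
    "generate_cohort",
    "generate_timeseries",
    "paperlike_default",
]

#: canonical six-network labels (default-mode, frontoparietal, cingulo-opercular,
#: sensorimotor, occipital, cerebellar)
SIX_NETWORKS = ("DMN", "FPN", "CON", "SMN", "ON", "CN")


def default_networks(n_rois: int, networks: tuple[str, ...] = SIX_NETWORKS) -> list[str]:
    """Assign n_rois ROIs to the networks in near-equal contiguous runs."""
    m = len(networks)
    base, extra = divmod(n_rois, m)
    sizes = [base + (1 if i < extra else 0) for i in range(m)]
    out: list[str] = []
    for lab, s in zip(networks, sizes):
        out.extend([lab] * s)
    return out


@dataclass
class SynthConfig:
    """Generating conditions for one synthetic cohort.

    ``biotype_block_offsets`` maps biotype index -> {(netA, netB): z offset};
    the default gives biotype 1 (the majority group) an extra +0.3 z on every
    between-network block involving CON or SMN, so the minority biotype 0 is
    the weakly connected one. ``score_blocks`` lists the blocks whose
    (z-scored) Frobenius norms drive the clinical score.
    """

    n_subjects: int = 200
    n_rois: int = 40
    network_labels: tuple[str, ...] = SIX_NETWORKS
    k_true: int = 2
    proportions: tuple[float, ...] = (0.25, 0.75)
    within_z: float = 0.4
    between_z: float = 0.1
    biotype_block_offsets: dict[int, dict[tuple[str, str], float]] | None = None
    site_count: int = 4
    site_offset_sd: float = 0.05
    subject_noise_sd: float = 0.1
    age_range: tuple[float, float] = (8.0, 35.0)
    score_weight: float = 1.0
    score_noise_sd: float = 0.5
    score_base: float = 12.0
    biotype_score_shift: tuple[float, ...] = (-0.5, 0.5)
    score_blocks: tuple[tuple[str, str], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("biotype proportions must sum to 1")
        if len(self.proportions) != self.k_true:
            raise ValueError("need one proportion per planted biotype")
        order = {n: i for i, n in enumerate(self.network_labels)}

        def canon(pair):
            a, b = pair
            return (a, b) if order[a] <= order[b] else (b, a)

        if self.biotype_block_offsets is None:
            offs: dict[tuple[str, str], float] = {}
            for a in ("CON", "SMN"):
                for b in self.network_labels:
                    if b != a:
                        offs[canon((a, b))] = 0.3
            self.biotype_block_offsets = {1: offs} if self.k_true > 1 else {}
        else:
            self.biotype_block_offsets = {
                k: {canon(p): v for p, v in d.items()}
                for k, d in self.biotype_block_offsets.items()}
        if self.score_blocks is None:
            keys = {k for d in self.biotype_block_offsets.values() for k in d}
            if not keys:
                keys = {canon((self.network_labels[0], self.network_labels[1]))}
            self.score_blocks = tuple(sorted(keys, key=lambda p: (order[p[0]],
                                                                  order[p[1]])))
        else:
            self.score_blocks = tuple(canon(p) for p in self.score_blocks)

    def parcellation(self) -> Parcellation:
        labels = default_networks(self.n_rois, self.network_labels)
        return Parcellation(
            roi_labels=[f"roi{i:03d}" for i in range(self.n_rois)],
            network_of=labels,
            networks=list(self.network_labels),
        )


@dataclass
class SyntheticCohort:
    fc: list[FCMatrix]
    phenotypes: list[SubjectPhenotype]
    scores: np.ndarray
    true_labels: np.ndarray
    parcellation: Parcellation
    config: SynthConfig = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.fc)

    def features(self) -> np.ndarray:
        """S x N(N-1)/2 node-feature matrix (upper-triangle FC vectors)."""
        return np.vstack([vectorize_upper(m) for m in self.fc])


def _block_offset_matrix(parc: Parcellation,
                         offsets: dict[tuple[str, str], float]) -> np.ndarray:
    n = parc.n_rois
    labels = np.array(parc.network_of)
    out = np.zeros((n, n))
    for (a, b), off in offsets.items():
        ia = labels == a
        ib = labels == b
        out[np.ix_(ia, ib)] += off
        if a != b:
            out[np.ix_(ib, ia)] += off
    np.fill_diagonal(out, 0.0)
    return out


def _base_pattern(parc: Parcellation, within_z: float, between_z: float) -> np.ndarray:
    labels = np.array(parc.network_of)
    same = labels[:, None] == labels[None, :]
    base = np.where(same, within_z, between_z)
    np.fill_diagonal(base, 0.0)
    return base


def _frob_norm_of_block(z: np.ndarray, parc: Parcellation, a: str, b: str) -> float:
    ia, ib = parc.indices_of(a), parc.indices_of(b)
    if a == b:
        sub = z[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        return float(np.sqrt(np.sum(sub[iu] ** 2)))
    return float(np.sqrt(np.sum(z[np.ix_(ia, ib)] ** 2)))


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Draw one cohort: FC matrices, phenotypes, scores, and true labels.

    Bit-reproducible from (config, seed): every random draw comes from a
    single generator in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    parc = config.parcellation()
    S, N = config.n_subjects, config.n_rois

    counts = np.floor(np.asarray(config.proportions) * S).astype(int)
    counts[-1] = S - counts[:-1].sum()
    labels = np.repeat(np.arange(config.k_true), counts)
    rng.shuffle(labels)

    sites = rng.integers(0, config.site_count, size=S)
    site_offsets = rng.normal(0.0, config.site_offset_sd, size=config.site_count)
    ages = rng.uniform(*config.age_range, size=S)

    base = _base_pattern(parc, config.within_z, config.between_z)
    biotype_mats = {
        b: _block_offset_matrix(parc, offs)
        for b, offs in config.biotype_block_offsets.items()
    }
    offdiag = ~np.eye(N, dtype=bool)

    fcs: list[FCMatrix] = []
    for s in range(S):
        z = base.copy()
        if int(labels[s]) in biotype_mats:
            z = z + biotype_mats[int(labels[s])]
        z[offdiag] += site_offsets[sites[s]]
        noise = rng.normal(0.0, config.subject_noise_sd, size=(N, N))
        z = z + (noise + noise.T) / 2.0
        np.fill_diagonal(z, 0.0)
        if np.max(np.abs(z)) > 6.0:
            raise ValueError("implausible connectivity: |z| > 6 after offsets")
        fcs.append(FCMatrix(subject_id=f"sub{s:04d}", z=z))

    # connectivity-coupled clinical score
    norms = np.array([[_frob_norm_of_block(m.z, parc, a, b)
                       for (a, b) in config.score_blocks] for m in fcs])
    sd = norms.std(axis=0)
    zn = np.divide(norms - norms.mean(axis=0), sd,
                   out=np.zeros_like(norms), where=sd > 0)
    shift = np.asarray(config.biotype_score_shift)[labels]
    scores = (config.score_base + shift
              + config.score_weight * zn.mean(axis=1)
              + rng.normal(0.0, config.score_noise_sd, size=S))

    phenotypes = [
        SubjectPhenotype(
            subject_id=f"sub{s:04d}",
            age=float(ages[s]),
            site=f"site{sites[s]}",
            sex="M",
            ados_total=float(scores[s]),
        )
        for s in range(S)
    ]
    return SyntheticCohort(fc=fcs, phenotypes=phenotypes, scores=scores,
                           true_labels=labels.astype(int), parcellation=parc,
                           config=config)


def _nearest_pd(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite correlation
    matrix by eigenvalue clipping followed by unit-diagonal rescaling."""
    w, V = np.linalg.eigh((corr + corr.T) / 2.0)
    w = np.clip(w, eps, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return A


def generate_timeseries(config: SynthConfig, t_volumes: int = 500) -> list[RoiTimeSeries]:
    """Draw ROI time series whose sample correlations recover the planted FC.

    Per subject, the target correlation matrix is tanh of the cohort z
    pattern, projected to the nearest positive-definite matrix, and
    ``t_volumes`` multivariate-normal volumes are sampled from it.
    """
    cohort = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out: list[RoiTimeSeries] = []
    for m in cohort.fc:
        corr = np.tanh(m.z)
        np.fill_diagonal(corr, 1.0)
        corr = _nearest_pd(corr)
        L = np.linalg.cholesky(corr)
        data = rng.standard_normal((t_volumes, corr.shape[0])) @ L.T
        out.append(RoiTimeSeries(subject_id=m.subject_id, data=data,
                                 roi_labels=list(cohort.parcellation.roi_labels)))
    return out


def paperlike_default() -> SynthConfig:
    """The frozen default cohort: 200 subjects, 40 ROIs, 6 networks, 4 sites,
    two planted biotypes in a 1:3 minority/majority split, seed 42."""
    return SynthConfig(seed=42)
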