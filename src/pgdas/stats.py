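"""Biotype characterization statistics.

Given biotype labels, three families of analyses describe and compare the
groups: (1) node- and network-level two-sample comparisons of connectivity
with Benjamini-Hochberg FDR control; (2) Spearman correlations between
network-block connectivity magnitude (Frobenius norms, z-scored across
subjects) and clinical scores, Bonferroni-corrected over the 21 unique
blocks of a 6-network parcellation; and (3) linear support-vector
regression predicting clinical scores from block norms under leave-one-out
cross-validation, with network-contribution feature weighting inside each
fold and a permutation test of the predicted-observed correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from .connectome import FCMatrix, Parcellation

__all__ = [
    "NetworkBlockProfile",
    "GroupComparisonResult",
    "PredictionResult",
    "block_order",
    "node_strength",
    "network_block_means",
    "frobenius_blocks",
    "block_profiles",
    "group_ttest_fdr",
    "zscore_columns",
    "correlate_blocks_symptoms",
    "svr_loocv_predict",
    "permutation_pvalue",
    "spearman_ci",
]


# ------------------------------------------------------------- block algebra

def block_order(parc: Parcellation) -> list[tuple[str, str]]:
    """Deterministic order of the M(M+1)/2 unique network blocks:
    within-network blocks first (network order), then between-network pairs
    in lexicographic network order."""
    nets = parc.networks
    order = [(n, n) for n in nets]
    order += [(nets[i], nets[j]) for i in range(len(nets))
              for j in range(i + 1, len(nets))]
    return order


def node_strength(fc: FCMatrix) -> np.ndarray:
    """Per-ROI mean z-connectivity to all other ROIs (diagonal excluded)."""
    z = fc.z
    n = z.shape[0]
    return (z.sum(axis=1)) / (n - 1)


def network_block_means(fc: FCMatrix, parc: Parcellation) -> np.ndarray:
    """M x M matrix of mean z-FC per network pair, ROI self-connections never
    counted; a single-ROI network has no within pairs and yields NaN."""
    if parc.n_rois != fc.n_rois:
        raise ValueError("parcellation does not cover this FC matrix")
    M = parc.n_networks
    out = np.zeros((M, M))
    idx = [parc.indices_of(n) for n in parc.networks]
    for a in range(M):
        for b in range(a, M):
            if a == b:
                ia = idx[a]
                if ia.size < 2:
                    out[a, a] = np.nan
                    continue
                sub = fc.z[np.ix_(ia, ia)]
                iu = np.triu_indices(ia.size, k=1)
                out[a, a] = sub[iu].mean()
            else:
                out[a, b] = out[b, a] = fc.z[np.ix_(idx[a], idx[b])].mean()
    return out


def frobenius_blocks(fc: FCMatrix, parc: Parcellation) -> np.ndarray:
    """Frobenius norm of each unique network block, in :func:`block_order`.

    A within-network block sums squares over unique ROI pairs i<j (each edge
    once, diagonal excluded); a between-network block sums over the full
    rectangular submatrix.
    """
    if parc.n_rois != fc.n_rois:
        raise ValueError("parcellation does not cover this FC matrix")
    idx = {n: parc.indices_of(n) for n in parc.networks}
    out = []
    for a, b in block_order(parc):
        if a == b:
            ia = idx[a]
            sub = fc.z[np.ix_(ia, ia)]
            iu = np.triu_indices(ia.size, k=1)
            out.append(np.sqrt(np.sum(sub[iu] ** 2)))
        else:
            out.append(np.sqrt(np.sum(fc.z[np.ix_(idx[a], idx[b])] ** 2)))
    return np.asarray(out)


@dataclass
class NetworkBlockProfile:
    """Per-subject network-block summaries."""

    subject_id: str
    block_means: np.ndarray
    frob_norms: np.ndarray
    blocks: list[tuple[str, str]]

    @classmethod
    def from_fc(cls, fc: FCMatrix, parc: Parcellation) -> "NetworkBlockProfile":
        return cls(subject_id=fc.subject_id,
                   block_means=network_block_means(fc, parc),
                   frob_norms=frobenius_blocks(fc, parc),
                   blocks=block_order(parc))


def block_profiles(fcs: list[FCMatrix], parc: Parcellation) -> pd.DataFrame:
    """Subjects x blocks table of Frobenius norms (columns "A-B")."""
    cols = [f"{a}-{b}" for a, b in block_order(parc)]
    data = np.vstack([frobenius_blocks(fc, parc) for fc in fcs])
    return pd.DataFrame(data, index=[fc.subject_id for fc in fcs], columns=cols)


# ------------------------------------------------------- group comparisons

@dataclass
class GroupComparisonResult:
    table: pd.DataFrame = field(repr=False)
    q: float = 0.05

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def group_ttest_fdr(values_a: np.ndarray, values_b: np.ndarray,
                    unit_names: list[str] | None = None,
                    q: float = 0.05) -> GroupComparisonResult:
    """Welch two-sample t-test per unit (ROI or block) with BH-FDR across units.

    ``values_a``/``values_b`` are (subjects x units) matrices for the two
    groups; Welch's form is used because biotype sizes are typically
    unbalanced. Both uncorrected and adjusted p-values are reported;
    rejections use the adjusted values at level ``q``.
    """
    A = np.atleast_2d(np.asarray(values_a, float))
    B = np.atleast_2d(np.asarray(values_b, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the unit axis")
    if min(A.shape[0], B.shape[0]) < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = sps.ttest_ind(A, B, axis=0, equal_var=False, nan_policy="omit")
    t = np.atleast_1d(np.asarray(t, float))
    p = np.atleast_1d(np.asarray(p, float))
    # zero-variance units with equal means (0/0) are no-difference, not NaN
    degenerate = np.isnan(t) & (np.abs(A.mean(axis=0) - B.mean(axis=0)) == 0)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    table = pd.DataFrame({
        "unit": unit_names if unit_names is not None else list(range(p.size)),
        "t": t, "p": p, "p_fdr": p_adj, "significant": reject,
    })
    return GroupComparisonResult(table=table, q=q)


def zscore_columns(X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Column-wise z-scoring across subjects; a constant column is an error
    naming the offending block."""
    X = np.asarray(X, float)
    sd = X.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        label = names[bad[0]] if names is not None else str(bad[0])
        raise ValueError(f"constant block across subjects: {label!r}")
    return (X - X.mean(axis=0)) / sd


def correlate_blocks_symptoms(norms: pd.DataFrame | np.ndarray,
                              scores: np.ndarray,
                              alpha: float = 0.05,
                              m: int | None = None) -> pd.DataFrame:
    """Spearman correlation of each (z-scored) block norm with a clinical
    score, Bonferroni-corrected: significant iff raw p < alpha/m.

    Missing scores are dropped pairwise-complete; ``m`` defaults to the
    number of blocks (21 for six networks).
    """
    if isinstance(norms, pd.DataFrame):
        names = list(norms.columns)
        X = norms.to_numpy(float)
    else:
        X = np.asarray(norms, float)
        names = [str(i) for i in range(X.shape[1])]
    y = np.asarray(scores, float)
    if y.size != X.shape[0]:
        raise ValueError("scores must align with subjects")
    ok = ~np.isnan(y)
    Xz = zscore_columns(X[ok], names)
    m = m if m is not None else X.shape[1]
    rows = []
    for j, name in enumerate(names):
        rho, p = sps.spearmanr(Xz[:, j], y[ok])
        rows.append({"block": name, "rho": float(rho), "p": float(p),
                     "significant": bool(p < alpha / m)})
    out = pd.DataFrame(rows)
    out.attrs["n_used"] = int(ok.sum())
    out.attrs["bonferroni_m"] = int(m)
    return out


# ------------------------------------------------------------- prediction

@dataclass
class PredictionResult:
    predicted: np.ndarray
    observed: np.ndarray
    spearman_rho: float
    n_used: int
    permutation_p: float | None = None
    permutation_p_smoothed: float | None = None
    ci95: tuple[float, float] | None = None


try:  # fast path: the libsvm backend without per-call estimator overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _libsvm = None


def _fit_linear_svr(X: np.ndarray, y: np.ndarray, C: float,
                    epsilon: float) -> tuple[np.ndarray, float]:
    """Linear epsilon-SVR returning (coef, intercept).

    Uses the libsvm backend directly when available (identical solution to
    ``SVR(kernel="linear")``, asserted in the test suite); otherwise the
    public estimator.
    """
    if _libsvm is not None:
        out = _libsvm.fit(np.ascontiguousarray(X), np.ascontiguousarray(y),
                          svm_type=3, kernel="linear", C=C, epsilon=epsilon,
                          tol=1e-3)
        sv, dual, intercept = out[1], out[3], out[4]
        return dual[0] @ sv, float(intercept[0])
    model = SVR(kernel="linear", C=C, epsilon=epsilon).fit(X, y)
    return model.coef_[0], float(model.intercept_[0])


class _LoocvMachine:
    """Precomputed LOOCV folds for one feature matrix.

    Fold-wise training standardization and feature ranks depend only on X,
    so they are computed once; each call with a (possibly permuted) target
    only ranks the target, derives the contribution-rate feature weights
    |Spearman rho| (normalized to sum 1), and fits the linear SVR.
    """

    def __init__(self, X: np.ndarray, C: float, epsilon: float):
        self.C, self.epsilon = C, epsilon
        n = X.shape[0]
        self.n = n
        self.folds = []
        for i in range(n):
            tr = np.arange(n) != i
            Xtr = X[tr]
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr_z = (Xtr - mu) / sd
            Xte_z = (X[i] - mu) / sd
            rxc = np.apply_along_axis(sps.rankdata, 0, Xtr_z)
            rxc -= rxc.mean(axis=0)
            rx_norm = np.sqrt((rxc**2).sum(axis=0))
            self.folds.append((tr, Xtr_z, Xte_z, rxc, rx_norm))

    def _weights(self, fold, y_train: np.ndarray) -> np.ndarray:
        _, _, _, rxc, rx_norm = fold
        ryc = sps.rankdata(y_train)
        ryc = ryc - ryc.mean()
        denom = rx_norm * np.sqrt((ryc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, ryc @ rxc / denom, 0.0)
        w = np.abs(rho)
        s = w.sum()
        return w / s if s > 0 else np.full(w.size, 1.0 / w.size)

    def predict(self, y: np.ndarray) -> np.ndarray:
        preds = np.empty(self.n)
        for i, fold in enumerate(self.folds):
            tr, Xtr_z, Xte_z, _, _ = fold
            ytr = y[tr]
            w = self._weights(fold, ytr)
            coef, b = _fit_linear_svr(Xtr_z * w, ytr, self.C, self.epsilon)
            preds[i] = (Xte_z * w) @ coef + b
        return preds


def _loocv_predict(X: np.ndarray, y: np.ndarray, C: float, epsilon: float) -> np.ndarray:
    """LOOCV linear-SVR predictions with per-fold standardization and
    contribution-rate feature weighting (both computed inside the fold)."""
    return _LoocvMachine(X, C, epsilon).predict(y)


def svr_loocv_predict(norms: pd.DataFrame | np.ndarray, scores: np.ndarray,
                      C: float = 1.0, epsilon: float = 0.1,
                      n_perm: int = 0, seed: int = 0) -> PredictionResult:
    """Predict a clinical score from network-block norms by linear SVR under
    leave-one-out cross-validation.

    Subjects with a missing target are excluded. Features are z-scored and
    contribution-weighted within each training fold (no leakage into the
    held-out subject). Reports the Spearman correlation between predicted
    and observed scores, its Fisher-z 95% CI, and — when ``n_perm`` > 0 —
    a target-permutation p-value.
    """
    X = norms.to_numpy(float) if isinstance(norms, pd.DataFrame) else np.asarray(norms, float)
    y = np.asarray(scores, float)
    ok = ~np.isnan(y)
    X, y = X[ok], y[ok]
    if y.size < 4:
        raise ValueError("need at least 4 subjects with complete scores")
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: all scores identical")
    preds = _loocv_predict(X, y, C, epsilon)
    rho = float(sps.spearmanr(preds, y)[0])
    result = PredictionResult(predicted=preds, observed=y, spearman_rho=rho,
                              n_used=int(y.size), ci95=spearman_ci(rho, y.size))
    if n_perm > 0:
        p_raw, p_smooth = permutation_pvalue(X, y, rho, n_perm=n_perm, seed=seed,
                                             C=C, epsilon=epsilon)
        result.permutation_p = p_raw
        result.permutation_p_smoothed = p_smooth
    return result


def permutation_pvalue(X: np.ndarray, y: np.ndarray, rho_obs: float,
                       n_perm: int = 1000, seed: int = 0,
                       C: float = 1.0, epsilon: float = 0.1) -> tuple[float, float]:
    """Permutation test of the LOOCV prediction correlation.

    Each permutation shuffles the target and reruns the full LOOCV pipeline.
    Returns the raw proportion of permuted correlations exceeding the
    observed one, and the smoothed variant (k+1)/(n_perm+1).
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    machine = _LoocvMachine(X, C, epsilon)
    count = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        preds = machine.predict(y_perm)
        if sps.spearmanr(preds, y_perm)[0] > rho_obs:
            count += 1
    return count / n_perm, (count + 1) / (n_perm + 1)


def spearman_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh(rho) ± z* / sqrt(n-3))."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    rho_c = float(np.clip(rho, -(1 - 1e-7), 1 - 1e-7))
    zstar = sps.norm.ppf(0.5 + level / 2.0)
    half = zstar / np.sqrt(n - 3)
    z = np.arctanh(rho_c)
    return float(np.tanh(z - half)), float(np.tanh(z + half))
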