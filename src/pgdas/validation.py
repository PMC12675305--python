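"""Internal validation of a clustering solution.

Two checks are provided, both label-free: (1) agreement of biotype
assignments across runs built from different parcellations of the same
cohort, and (2) bootstrap stability — repeatedly re-clustering random
half-samples (drawn with replacement), recording how often each cluster
number K wins the silhouette selection, and how well each replicate's
partition matches the full-sample solution after optimal label alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import TrainConfig, select_k

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityReport",
    "match_labels",
    "cross_parcellation_agreement",
    "bootstrap_k_frequencies",
]


@dataclass
class StabilityReport:
    """Outcome of the bootstrap-resampling validation."""

    k_frequencies: dict[int, int]
    modal_k: int
    stability_index_mean: float
    stability_index_sd: float
    per_replicate: pd.DataFrame = field(repr=False)
    n_completed: int = 0
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "k_frequencies": {int(k): int(v) for k, v in self.k_frequencies.items()},
            "modal_k": int(self.modal_k),
            "stability_index_mean": float(self.stability_index_mean),
            "stability_index_sd": float(self.stability_index_sd),
            "n_completed": int(self.n_completed),
            "n_skipped": int(self.n_skipped),
        }


def match_labels(labels_a: np.ndarray, labels_b: np.ndarray) -> tuple[dict[int, int], float]:
    """Optimal label alignment between two partitions of the same subjects.

    Solves a maximum-weight assignment on the contingency table (padding
    with zero rows/columns when the partitions use different numbers of
    labels) and returns the mapping from b-labels to a-labels together with
    the fraction of co-labeled subjects under that mapping.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    ua, ub = np.unique(a), np.unique(b)
    table = np.zeros((ub.size, ua.size))
    for i, lb in enumerate(ub):
        for j, la in enumerate(ua):
            table[i, j] = np.sum((b == lb) & (a == la))
    size = max(table.shape)
    padded = np.zeros((size, size))
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(-padded)
    mapping = {int(ub[r]): int(ua[c]) for r, c in zip(rows, cols)
               if r < ub.size and c < ua.size}
    matched = sum(padded[r, c] for r, c in zip(rows, cols))
    return mapping, float(matched / a.size)


def cross_parcellation_agreement(runs: dict[str, np.ndarray] | list[np.ndarray]) -> pd.DataFrame:
    """Pairwise percentage of subjects assigned to the same biotype across
    parcellation-specific runs, after optimal label alignment."""
    if isinstance(runs, dict):
        names = list(runs)
        vecs = [np.asarray(runs[n]) for n in names]
    else:
        names = [f"run{i}" for i in range(len(runs))]
        vecs = [np.asarray(v) for v in runs]
    n = vecs[0].size
    for v in vecs:
        if v.size != n:
            raise ValueError("all runs must cover the same subjects")
    M = np.full((len(vecs), len(vecs)), 100.0)
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            _, agree = match_labels(vecs[i], vecs[j])
            M[i, j] = M[j, i] = 100.0 * agree
    return pd.DataFrame(M, index=names, columns=names)


def bootstrap_k_frequencies(graph_builder, fit_config: TrainConfig,
                            B: int = 500, frac: float = 0.5,
                            k_range=range(2, 7), seed: int = 0,
                            full_labels: np.ndarray | None = None,
                            n_subjects: int | None = None) -> StabilityReport:
    """Bootstrap the cluster-number selection.

    Per replicate, ``floor(frac*S)`` subjects are drawn with replacement,
    duplicates are collapsed (a population graph cannot hold duplicate
    nodes), the graph is rebuilt on the sampled subjects via
    ``graph_builder(indices)``, and the silhouette selection runs over
    ``k_range``. The stability index of a replicate is its label agreement
    (after optimal alignment) with the full-sample solution restricted to
    the sampled subjects, evaluated at the modal K.

    ``graph_builder`` maps an array of subject indices (0..S-1) to a
    PopulationGraph; ``full_labels`` is the full-sample partition the index
    is computed against (at the modal K). If omitted, the stability index
    uses the modal-K labels of the full graph fit lazily built from
    ``graph_builder(arange(S))``.
    """
    if n_subjects is None:
        if full_labels is None:
            raise ValueError("provide n_subjects or full_labels")
        n_subjects = int(np.asarray(full_labels).size)
    rng = np.random.default_rng(seed)
    n_draw = int(np.floor(frac * n_subjects))
    k_list = list(k_range)
    records = []
    replicate_labels: list[tuple[np.ndarray, dict[int, np.ndarray]]] = []
    n_skipped = 0
    for b in range(B):
        idx = np.unique(rng.integers(0, n_subjects, size=n_draw))
        if idx.size < max(k_list) + 1:
            n_skipped += 1
            logger.warning("replicate %d: only %d unique subjects; skipped", b, idx.size)
            continue
        sub_graph = graph_builder(idx)
        best_k, sils, states = select_k(sub_graph, fit_config, k_list)
        records.append({"replicate": b, "chosen_k": best_k,
                        **{f"sil_k{k}": sils[k] for k in k_list}})
        replicate_labels.append((idx, {k: states[k].labels for k in k_list}))

    freqs = {k: 0 for k in k_list}
    for r in records:
        freqs[r["chosen_k"]] += 1
    modal_k = max(freqs, key=lambda k: (freqs[k], -k))

    if full_labels is None:
        full_graph = graph_builder(np.arange(n_subjects))
        from .model import fit as _fit
        from dataclasses import replace as _replace
        full_labels = _fit(full_graph, _replace(fit_config, k=modal_k)).labels
    full_labels = np.asarray(full_labels)

    agreements = []
    for (idx, by_k), rec in zip(replicate_labels, records):
        _, agree = match_labels(full_labels[idx], by_k[modal_k])
        rec["agreement"] = agree
        agreements.append(agree)
    agreements = np.asarray(agreements, float)

    return StabilityReport(
        k_frequencies=freqs,
        modal_k=int(modal_k),
        stability_index_mean=float(agreements.mean()) if agreements.size else float("nan"),
        stability_index_sd=float(agreements.std(ddof=1)) if agreements.size > 1 else float("nan"),
        per_replicate=pd.DataFrame.from_records(records),
        n_completed=len(records),
        n_skipped=n_skipped,
    )
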