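"""Consensus t-SNE/k-means subgroup discovery with stability scoring.

The procedure: compute a 1 − weighted-Pearson distance between samples over
the most variable probes; embed the precomputed distance with exact t-SNE in
two and three dimensions; partition each embedding with k-means for a grid of
cluster counts; repeat on random 80% subsamples, mapping held-out samples to
the label of their nearest sampled neighbour, and align every resampled
partition to the full-data reference partition with the Hungarian algorithm.
Per sample, the modal (most frequent) aligned label and its frequency — the
modal score — measure assignment stability. The (dimension, k) cell with the
best combined rank of mean modal score (reproducibility) and average
silhouette is selected, and samples are called classifiable when their modal
score exceeds 0.70 and their silhouette is positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

log = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "ConsensusResult",
    "CellResult",
    "weighted_pearson_distance",
    "tsne_embed",
    "kmeans_partition",
    "align_labels",
    "silhouette",
    "consensus_resample",
    "select_solution",
    "classify_samples",
    "run_consensus",
]


@dataclass
class ClusterParams:
    probe_weights: str = "sd"  # "sd" | "uniform"
    dims_grid: tuple[int, ...] = (2, 3)
    k_grid: tuple[int, ...] = tuple(range(2, 11))
    n_iter: int = 256
    subsample_frac: float = 0.8
    tsne_theta: float = 0.0  # exact method; kept for provenance
    tsne_max_iter: int = 5000
    tsne_perplexity: float = 30.0
    kmeans_restarts: int = 10
    modal_threshold: float = 0.70
    min_valid_frac: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.subsample_frac < 1:
            raise ValueError("subsample_frac must lie in (0, 1)")
        if min(self.k_grid) < 2:
            raise ValueError("k_grid minimum is 2")
        if self.probe_weights not in {"sd", "uniform"}:
            raise ValueError("probe_weights must be 'sd' or 'uniform'")


def _cell_seed(master: int, r: int, dim: int, k: int) -> int:
    """Derived seed for iteration r of grid cell (dim, k); r = -1 is the
    full-data reference run."""
    ss = np.random.SeedSequence((master, r + 1, dim, k))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# distance


def weighted_pearson_distance(
    beta: pd.DataFrame, weights: np.ndarray | None = None
) -> pd.DataFrame:
    """d(i, j) = 1 − weighted Pearson correlation between sample columns.

    ``weights`` is a nonnegative per-probe vector (default uniform; the
    pipeline default upweights by per-probe SD). Entries lie in [0, 2], the
    diagonal is zero.
    """
    X = beta.to_numpy(dtype=float)
    p, n = X.shape
    if p < 2:
        raise ValueError("need at least 2 probes")
    if weights is None:
        w = np.full(p, 1.0 / p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (p,) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be a nonnegative per-probe vector, not all zero")
        w = w / w.sum()
    mu = w @ X
    Xc = X - mu
    cov = (Xc * w[:, None]).T @ Xc
    var = np.diag(cov).copy()
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ValueError(
            f"zero weighted variance for sample(s) {list(beta.columns[bad])}: "
            "correlation undefined"
        )
    r = cov / np.sqrt(np.outer(var, var))
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=beta.columns, columns=beta.columns)


def probe_weights(beta: pd.DataFrame, scheme: str) -> np.ndarray | None:
    if scheme == "uniform":
        return None
    return beta.std(axis=1, ddof=1).to_numpy()


# ---------------------------------------------------------------------------
# embedding / partitioning


def tsne_embed(
    dist: pd.DataFrame | np.ndarray,
    dim: int,
    params: ClusterParams | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Exact t-SNE on a precomputed distance matrix -> n x dim coordinates."""
    params = params or ClusterParams()
    # copy: sklearn's precomputed-metric TSNE modifies its input in place
    D = np.array(dist, dtype=float, copy=True)
    n = D.shape[0]
    if params.tsne_perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity {params.tsne_perplexity} too large for n={n} "
            f"(needs perplexity < (n-1)/3)"
        )
    tsne = TSNE(
        n_components=dim,
        perplexity=params.tsne_perplexity,
        method="exact",  # theta = 0
        metric="precomputed",
        init="random",
        max_iter=params.tsne_max_iter,
        random_state=params.seed if seed is None else seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return tsne.fit_transform(D)


def kmeans_partition(
    embedding: np.ndarray, k: int, restarts: int = 10, seed: int = 0
) -> np.ndarray:
    """Best-inertia k-means over ``restarts`` greedy k-means++ starts."""
    n = embedding.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(embedding)


def align_labels(labels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rename ``labels`` to maximise overlap with ``reference``.

    Solved as maximum-weight bipartite matching (Hungarian algorithm) on the
    label contingency table over samples present in both partitions (entries
    of ``labels`` < 0 are treated as missing and passed through). Labels with
    no matched reference counterpart keep fresh ids. The partition itself is
    unchanged — only label names move.
    """
    labels = np.asarray(labels)
    reference = np.asarray(reference)
    present = labels >= 0
    if not present.any():
        raise ValueError("no overlapping samples between partitions")
    lab_ids = np.unique(labels[present])
    ref_ids = np.unique(reference[present])
    cont = np.zeros((lab_ids.size, ref_ids.size), dtype=int)
    li = {v: i for i, v in enumerate(lab_ids)}
    ri = {v: i for i, v in enumerate(ref_ids)}
    for a, b in zip(labels[present], reference[present]):
        cont[li[a], ri[b]] += 1
    rows, cols = linear_sum_assignment(cont, maximize=True)
    mapping = {lab_ids[r]: ref_ids[c] for r, c in zip(rows, cols)}
    fresh = int(ref_ids.max()) + 1 if ref_ids.size else 0
    for v in lab_ids:
        if v not in mapping:
            mapping[v] = fresh
            fresh += 1
    out = labels.copy()
    out[present] = [mapping[v] for v in labels[present]]
    return out


def silhouette(
    dist: pd.DataFrame | np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-sample and average silhouette on a precomputed distance matrix.

    s(i) = (b − a) / max(a, b); samples in singleton clusters score 0.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least 2 non-empty clusters")
    D = np.asarray(dist, dtype=float)
    s = silhouette_samples(D, labels, metric="precomputed")
    return s, float(s.mean())


# ---------------------------------------------------------------------------
# consensus


@dataclass
class CellResult:
    dim: int
    k: int
    reference: np.ndarray
    modal_labels: np.ndarray
    modal_scores: np.ndarray
    reproducibility: float
    sil_samples: np.ndarray
    sil_avg: float
    n_success: int
    n_iter: int
    valid: bool
    label_counts: np.ndarray = field(repr=False, default=None)


@dataclass
class ConsensusResult:
    cells: dict[tuple[int, int], CellResult]
    sample_ids: pd.Index
    params: ClusterParams
    selected: tuple[int, int] | None = None

    @property
    def grid(self) -> pd.DataFrame:
        rows = [
            {
                "dim": c.dim,
                "k": c.k,
                "reproducibility": c.reproducibility,
                "avg_silhouette": c.sil_avg,
                "valid": c.valid,
            }
            for c in self.cells.values()
        ]
        return pd.DataFrame(rows).sort_values(["dim", "k"]).reset_index(drop=True)

    def assignments(self, cell: tuple[int, int] | None = None) -> pd.DataFrame:
        cell = cell or self.selected
        c = self.cells[cell]
        flags = classify_samples(self, self.params.modal_threshold, cell)
        return pd.DataFrame(
            {
                "modal_cluster": c.modal_labels,
                "modal_score": c.modal_scores,
                "silhouette": c.sil_samples,
                "classifiable": flags,
            },
            index=self.sample_ids,
        )


def consensus_resample(
    dist: pd.DataFrame, params: ClusterParams | None = None
) -> ConsensusResult:
    """Run the resampling-consensus grid over (dimension, k).

    For each cell the full-data t-SNE/k-means partition anchors label
    alignment. Each of ``n_iter`` iterations clusters a random
    floor(subsample_frac * n) subset, maps held-out samples to their nearest
    sampled neighbour under ``dist``, and aligns to the anchor. Cells where
    fewer than ``min_valid_frac`` of iterations succeed are marked invalid.
    """
    params = params or ClusterParams()
    D = dist.to_numpy(dtype=float)
    n = D.shape[0]
    m = int(np.floor(params.subsample_frac * n))
    if params.tsne_perplexity >= (m - 1) / 3:
        raise ValueError(
            f"perplexity {params.tsne_perplexity} infeasible on subsamples of "
            f"size {m}; need n >= 3 * perplexity / subsample_frac"
        )

    max_k = max(params.k_grid)
    cells: dict[tuple[int, int], CellResult] = {}
    references: dict[tuple[int, int], np.ndarray] = {}
    counts: dict[tuple[int, int], np.ndarray] = {}
    success: dict[tuple[int, int], int] = {}

    for dim in params.dims_grid:
        emb = tsne_embed(D, dim, params, seed=_cell_seed(params.seed, -1, dim, 0))
        for k in params.k_grid:
            ref = kmeans_partition(
                emb, k, params.kmeans_restarts, seed=_cell_seed(params.seed, -1, dim, k)
            )
            references[(dim, k)] = ref
            counts[(dim, k)] = np.zeros((n, max_k + 1), dtype=np.int32)
            success[(dim, k)] = 0

    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xC0)))
    for r in range(params.n_iter):
        sampled = np.sort(rng.choice(n, size=m, replace=False))
        held = np.setdiff1d(np.arange(n), sampled)
        # nearest sampled neighbour of each held-out sample, under dist
        nearest = sampled[np.argmin(D[np.ix_(held, sampled)], axis=1)] if held.size else held
        sub = D[np.ix_(sampled, sampled)]
        for dim in params.dims_grid:
            try:
                emb = tsne_embed(sub, dim, params, seed=_cell_seed(params.seed, r, dim, 0))
            except Exception as exc:  # noqa: BLE001 — cell-level robustness
                log.warning("iteration %d dim %d embedding failed: %s", r, dim, exc)
                continue
            for k in params.k_grid:
                try:
                    lab_sub = kmeans_partition(
                        emb, k, params.kmeans_restarts, seed=_cell_seed(params.seed, r, dim, k)
                    )
                except Exception as exc:  # noqa: BLE001
                    log.warning("iteration %d cell (%d,%d) failed: %s", r, dim, k, exc)
                    continue
                full = np.empty(n, dtype=int)
                full[sampled] = lab_sub
                pos = {s: i for i, s in enumerate(sampled)}
                full[held] = [lab_sub[pos[nb]] for nb in nearest]
                aligned = align_labels(full, references[(dim, k)])
                # labels beyond max_k+1 can only appear via fresh ids; clip
                np.add.at(counts[(dim, k)], (np.arange(n), np.minimum(aligned, max_k)), 1)
                success[(dim, k)] += 1

    for (dim, k), ref in references.items():
        cnt = counts[(dim, k)]
        n_ok = success[(dim, k)]
        if n_ok == 0:
            cells[(dim, k)] = CellResult(
                dim, k, ref, ref.copy(), np.zeros(n), 0.0, np.zeros(n), -1.0,
                0, params.n_iter, False, cnt,
            )
            continue
        modal = cnt.argmax(axis=1)
        scores = cnt.max(axis=1) / n_ok
        try:
            sil_s, sil_a = silhouette(D, modal)
        except ValueError:  # modal partition collapsed to one cluster
            sil_s, sil_a = np.zeros(n), -1.0
        cells[(dim, k)] = CellResult(
            dim=dim, k=k, reference=ref, modal_labels=modal, modal_scores=scores,
            reproducibility=float(scores.mean()), sil_samples=sil_s, sil_avg=sil_a,
            n_success=n_ok, n_iter=params.n_iter,
            valid=n_ok >= params.min_valid_frac * params.n_iter,
            label_counts=cnt,
        )

    result = ConsensusResult(cells=cells, sample_ids=dist.index, params=params)
    result.selected = select_solution(result)
    return result


def select_solution(result: ConsensusResult) -> tuple[int, int]:
    """Pick the valid (dim, k) cell maximising the summed ranks of
    reproducibility and average silhouette; ties prefer smaller k, then
    smaller dim."""
    valid = [(key, c) for key, c in result.cells.items() if c.valid]
    if not valid:
        raise ValueError("no valid consensus cells")
    repro = rankdata([c.reproducibility for _, c in valid])
    sil = rankdata([c.sil_avg for _, c in valid])
    score = repro + sil
    best = max(
        range(len(valid)),
        key=lambda i: (score[i], -valid[i][0][1], -valid[i][0][0]),
    )
    return valid[best][0]


def classify_samples(
    result: ConsensusResult,
    modal_threshold: float = 0.70,
    cell: tuple[int, int] | None = None,
) -> np.ndarray:
    """classifiable ⇔ modal score > threshold (strict) AND silhouette > 0
    (strict), at the selected cell."""
    cell = cell or result.selected
    if cell is None:
        raise ValueError("no selected cell")
    c = result.cells[cell]
    return (c.modal_scores > modal_threshold) & (c.sil_samples > 0)


def run_consensus(beta: pd.DataFrame, params: ClusterParams | None = None) -> ConsensusResult:
    """Distance + consensus grid in one call (pipeline entry point)."""
    params = params or ClusterParams()
    w = probe_weights(beta, params.probe_weights)
    dist = weighted_pearson_distance(beta, w)
    return consensus_resample(dist, params)
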