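"""Kmer encoding of CDR signatures and 2D manifold projection.

Signatures are encoded as sparse counts of overlapping amino-acid kmers
(length 5 by default; only observed kmers are materialised, since the
full 20^5 vocabulary would be wasteful) and projected to two dimensions
with UMAP so that sequence-related clones land near each other.  The
selected candidates can then be overlaid on the full-repertoire
embedding to ask whether they form one sequence family or several.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

DEFAULT_K = 5
DEFAULT_N_NEIGHBORS = 15
DEFAULT_SEED = 42


@dataclass
class KmerMatrix:
    """Sparse signature-by-kmer occurrence counts."""

    counts: sparse.csr_matrix
    signatures: list[str]
    kmers: list[str]
    k: int

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.toarray(), index=self.signatures,
                            columns=self.kmers)

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


def kmer_encode(signatures: list[str], k: int = DEFAULT_K) -> KmerMatrix:
    """Count overlapping kmers per signature.

    A signature of length L >= k contributes exactly L - k + 1 window
    counts; shorter signatures get an all-zero row (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vocab: dict[str, int] = {}
    rows, cols, vals = [], [], []
    n_short = 0
    for i, sig in enumerate(signatures):
        if len(sig) < k:
            n_short += 1
            continue
        local: dict[int, int] = {}
        for j in range(len(sig) - k + 1):
            kmer = sig[j:j + k]
            idx = vocab.setdefault(kmer, len(vocab))
            local[idx] = local.get(idx, 0) + 1
        rows.extend([i] * len(local))
        cols.extend(local.keys())
        vals.extend(local.values())
    if n_short:
        warnings.warn(f"{n_short} signatures shorter than k={k} encoded as zero rows",
                      stacklevel=2)
    counts = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(signatures), max(len(vocab), 1)), dtype=np.int64)
    kmers = sorted(vocab, key=vocab.get)
    return KmerMatrix(counts=counts, signatures=list(signatures), kmers=kmers, k=k)


@dataclass
class Embedding2D:
    """2D coordinates per signature plus the projection parameters."""

    coordinates: pd.DataFrame  # index signature, columns x, y
    params: dict = field(default_factory=dict)

    def __getitem__(self, signature: str) -> tuple[float, float]:
        row = self.coordinates.loc[signature]
        if isinstance(row, pd.DataFrame):  # duplicated signature
            row = row.iloc[0]
        return float(row["x"]), float(row["y"])

    @property
    def diameter(self) -> float:
        xy = self.coordinates[["x", "y"]].to_numpy()
        return float(np.sqrt(((xy.max(0) - xy.min(0)) ** 2).sum()))


def embed(
    matrix: KmerMatrix,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    n_components: int = 2,
    metric: str = "euclidean",
    seed: int = DEFAULT_SEED,
) -> Embedding2D:
    """UMAP projection of a kmer matrix (deterministic under a fixed seed)."""
    import umap  # deferred: numba compilation makes this import heavy

    n = matrix.counts.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} signatures, got {n}")
    # identical kmer rows must land on coincident points: project unique
    # rows once and broadcast coordinates back to their duplicates
    csr = matrix.counts.tocsr().astype(np.float32)
    keys: dict[bytes, int] = {}
    row_to_unique = np.empty(n, dtype=np.int64)
    unique_rows = []
    for i in range(n):
        row = csr.getrow(i)
        key = row.indices.tobytes() + row.data.tobytes()
        if key not in keys:
            keys[key] = len(unique_rows)
            unique_rows.append(i)
        row_to_unique[i] = keys[key]
    sub = csr[unique_rows]
    k_eff = min(n_neighbors, max(sub.shape[0] - 1, 2))
    reducer = umap.UMAP(n_neighbors=k_eff, n_components=n_components,
                        metric=metric, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that random_state disables parallelism
        coords_unique = reducer.fit_transform(sub)
    coords = coords_unique[row_to_unique]
    df = pd.DataFrame(coords, columns=["x", "y"][:n_components],
                      index=pd.Index(matrix.signatures, name="signature"))
    return Embedding2D(coordinates=df, params={
        "k": matrix.k, "n_neighbors": n_neighbors, "n_components": n_components,
        "metric": metric, "seed": seed})


@dataclass
class OverlaySummary:
    """Candidate coordinates and cohesion of the candidate set."""

    candidates: pd.DataFrame  # x, y, nearest_candidate_distance, is_outlier
    n_outliers: int
    distance_cutoff: float
    quantile: float


def overlay_candidates(
    embedding: Embedding2D,
    selected_signatures: list[str],
    background_quantile: float = 0.25,
) -> OverlaySummary:
    """Flag selected candidates that sit apart from their peers.

    The low quantiles of the background's pairwise-distance distribution
    reflect within-cluster scales of the map; a candidate whose nearest
    fellow candidate is farther than the ``background_quantile`` of all
    background pairwise distances does not belong to any candidate
    cluster and is flagged as an outlier.  A single candidate has no
    peers and no outliers.
    """
    missing = [s for s in selected_signatures if s not in embedding.coordinates.index]
    if missing:
        raise KeyError(f"signatures absent from embedding: {missing[:3]}...")
    xy_all = embedding.coordinates[["x", "y"]].to_numpy()
    # a signature embedded several times contributes its first coordinates
    unique = embedding.coordinates[~embedding.coordinates.index.duplicated(keep="first")]
    cand_xy = unique.loc[selected_signatures, ["x", "y"]].to_numpy()

    from scipy.spatial.distance import pdist
    from sklearn.neighbors import NearestNeighbors

    if xy_all.shape[0] > 2048:  # cap the O(n^2) distance sample
        sub = np.random.default_rng(0).choice(xy_all.shape[0], 2048, replace=False)
        xy_bg = xy_all[sub]
    else:
        xy_bg = xy_all
    cutoff = float(np.quantile(pdist(xy_bg), background_quantile))

    n = len(selected_signatures)
    if n < 2:
        nnd = np.zeros(n)
    else:
        nn_cand = NearestNeighbors(n_neighbors=2).fit(cand_xy)
        nnd = nn_cand.kneighbors(cand_xy)[0][:, 1]
    outlier = nnd > cutoff
    df = pd.DataFrame({
        "x": cand_xy[:, 0], "y": cand_xy[:, 1],
        "nearest_candidate_distance": nnd, "is_outlier": outlier,
    }, index=pd.Index(selected_signatures, name="signature"))
    return OverlaySummary(candidates=df, n_outliers=int(outlier.sum()),
                          distance_cutoff=cutoff, quantile=background_quantile)


def plot_embedding(embedding: Embedding2D, selected_signatures=None, path=None):
    """Scatter of the embedding with candidates highlighted; saves to
    ``path`` when given, returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    xy = embedding.coordinates
    ax.scatter(xy["x"], xy["y"], s=4, c="lightgrey", label="repertoire")
    if selected_signatures:
        sel = xy.loc[selected_signatures]
        ax.scatter(sel["x"], sel["y"], s=16, c="crimson", label="candidates")
    ax.set_xlabel("UMAP-1")
    ax.set_ylabel("UMAP-2")
    ax.legend(frameon=False)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
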