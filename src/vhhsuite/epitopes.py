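"""Pairwise epitope matrices: overlap (virtual binning), similarity
tiers, and the incoherence between the two predictions.

Epitope predictions arrive as per-antibody maps of antigen residue
index (1-based) to a confidence tier (very_high / high / medium); the
docking and CDR-encoding engines that produce them are upstream of this
package.  Overlap between two antibodies counts shared predicted
residues across all three tiers and divides by the larger epitope;
competition is called when that ratio exceeds 0.3.  Similarity scores
map to tiered probabilities of sharing an epitope (above 50 -> 0.95,
30-50 -> 0.75).  The incoherence of a pair is its min-max-normalised
similarity minus its overlap: +1 flags sequence twins predicted to bind
disjoint epitopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

TIERS = ("very_high", "high", "medium")
COMPETITION_THRESHOLD = 0.3
SIMILARITY_HIGH = 50.0   # score above which shared-epitope probability is 0.95
SIMILARITY_MEDIUM = 30.0  # lower bound of the 0.75 probability band
DEFAULT_FLAG_THRESHOLD = 0.5


class EmptyEpitopeError(ValueError):
    """Overlap is undefined when one prediction has no residues."""


class DegenerateNormalizationError(ValueError):
    """Min-max normalisation is undefined for a constant similarity matrix."""


@dataclass
class EpitopePrediction:
    """Predicted epitope of one antibody on the antigen surface."""

    antibody_id: str
    residues: dict[int, str]  # residue index (1-based) -> tier

    def __post_init__(self):
        bad = {t for t in self.residues.values()} - set(TIERS)
        if bad:
            raise ValueError(f"unknown confidence tiers: {sorted(bad)}")

    @property
    def residue_set(self) -> frozenset[int]:
        return frozenset(self.residues)


def overlap_ratio(a: EpitopePrediction, b: EpitopePrediction) -> float:
    """Shared predicted residues over the larger epitope, all tiers equal."""
    ra, rb = a.residue_set, b.residue_set
    if not ra or not rb:
        raise EmptyEpitopeError(
            f"overlap undefined for empty epitope ({a.antibody_id!r}, {b.antibody_id!r})")
    return len(ra & rb) / max(len(ra), len(rb))


def competition_call(overlap: float, threshold: float = COMPETITION_THRESHOLD) -> bool:
    """Two antibodies compete when their overlap strictly exceeds the
    threshold (a ratio of exactly 0.3 is not a competition call)."""
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap ratio must be in [0, 1]")
    return overlap > threshold


def similarity_probability(score: float) -> float | None:
    """Tiered probability that two antibodies share an epitope.

    Above 50 -> 0.95; between 30 and 50 (inclusive) -> 0.75; below 30
    the similarity is uninformative and None ("unassessed") is returned.
    """
    if score < 0:
        raise ValueError("similarity scores are non-negative")
    if score > SIMILARITY_HIGH:
        return 0.95
    if score >= SIMILARITY_MEDIUM:
        return 0.75
    return None


def _offdiag_minmax(similarity: pd.DataFrame) -> tuple[float, float]:
    vals = similarity.to_numpy(dtype=float).copy()
    np.fill_diagonal(vals, np.nan)
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if hi == lo:
        raise DegenerateNormalizationError(
            "all off-diagonal similarities equal; min-max normalisation undefined")
    return float(lo), float(hi)


def incoherence(similarity: pd.DataFrame, overlap: pd.DataFrame,
                flag_threshold: float = DEFAULT_FLAG_THRESHOLD
                ) -> tuple[pd.DataFrame, int]:
    """Normalised-similarity-minus-overlap matrix and flagged-pair count.

    Similarity is min-max normalised over off-diagonal entries only
    (self-similarity would saturate the max), then the overlap matrix is
    subtracted elementwise.  Pairs with incoherence above
    ``flag_threshold`` are counted once each (upper triangle).
    """
    if list(similarity.index) != list(overlap.index) or \
            list(similarity.columns) != list(overlap.columns):
        raise ValueError("similarity and overlap must cover identical antibody sets")
    lo, hi = _offdiag_minmax(similarity)
    norm = (similarity - lo) / (hi - lo)
    inc = norm - overlap
    vals = inc.to_numpy(dtype=float)
    np.fill_diagonal(vals, np.nan)  # self-pairs carry no incoherence signal
    inc = pd.DataFrame(vals, index=inc.index, columns=inc.columns)
    tri = np.triu(np.ones(inc.shape, dtype=bool), k=1)
    n_flagged = int((inc.to_numpy()[tri] > flag_threshold).sum())
    return inc, n_flagged


@dataclass
class PairMatrices:
    """All pairwise matrices for one antibody panel."""

    overlap: pd.DataFrame
    competition: pd.DataFrame
    similarity: pd.DataFrame
    probability: pd.DataFrame  # 0.95 / 0.75 / NaN (unassessed)
    incoherence: pd.DataFrame
    n_incoherent: int
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD
    site_components: list[set[str]] = field(default_factory=list)


def compute_pair_matrices(
    predictions: list[EpitopePrediction],
    similarity: pd.DataFrame,
    competition_threshold: float = COMPETITION_THRESHOLD,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
) -> PairMatrices:
    """Build overlap/competition/probability/incoherence from predictions
    and an externally supplied similarity matrix."""
    names = [p.antibody_id for p in predictions]
    if list(similarity.index) != names or list(similarity.columns) != names:
        similarity = similarity.loc[names, names]
    n = len(names)
    ov = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ov[i, j] = ov[j, i] = overlap_ratio(predictions[i], predictions[j])
    overlap = pd.DataFrame(ov, index=names, columns=names)
    comp = overlap.map(lambda o: competition_call(o, competition_threshold))
    prob = similarity.map(lambda s: similarity_probability(s) or np.nan)
    inc, n_flagged = incoherence(similarity, overlap, flag_threshold)
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if comp.iloc[i, j]:
                graph.add_edge(names[i], names[j])
    components = [set(c) for c in nx.connected_components(graph)]
    return PairMatrices(overlap=overlap, competition=comp, similarity=similarity,
                        probability=prob, incoherence=inc, n_incoherent=n_flagged,
                        flag_threshold=flag_threshold, site_components=components)


def read_epitope_tsv(path) -> list[EpitopePrediction]:
    """Read per-antibody predictions from a long TSV
    (antibody_id, residue_index, tier)."""
    df = pd.read_csv(path, sep="\t")
    preds = []
    for ab, grp in df.groupby("antibody_id", sort=True):
        preds.append(EpitopePrediction(
            str(ab), dict(zip(grp["residue_index"].astype(int), grp["tier"]))))
    return preds


def plot_heatmap(matrix: pd.DataFrame, path=None, title: str = "", cmap: str = "viridis"):
    """Heat map of a pairwise matrix; saves to ``path`` when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap=cmap)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def write_epitope_tsv(predictions: list[EpitopePrediction], path) -> None:
    rows = [
        {"antibody_id": p.antibody_id, "residue_index": r, "tier": t}
        for p in predictions for r, t in sorted(p.residues.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
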