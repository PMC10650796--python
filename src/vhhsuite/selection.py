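"""Counts-per-million normalisation and multiplexed candidate selection.

A signature cluster becomes a candidate when it is present above a
minimum CPM in at least one target-positive condition and at or below a
maximum CPM (strict absence by default) in every negative-control
condition.  Candidates are ranked by raw cluster size, the empirical
predictor of binding affinity in this kind of campaign.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .design import PanningDesign, design_from_columns


class IntegrityError(ValueError):
    """Counts inconsistent with the declared sequencing totals."""


class SchemaError(ValueError):
    """Count matrix columns do not match the panning design."""


@dataclass
class CountMatrix:
    """Raw and CPM cluster-by-condition counts.

    ``cpm[c, k] = 1e6 * raw[c, k] / totals[k]``; when the matrix is
    built from already-normalised values (a printed report), ``raw`` is
    None and ``total_raw`` carries the reported cluster sizes.
    """

    cpm: pd.DataFrame
    raw: pd.DataFrame | None = None
    total_raw: pd.Series | None = None

    def __post_init__(self):
        if self.total_raw is None:
            source = self.raw if self.raw is not None else self.cpm
            self.total_raw = source.sum(axis=1)

    @property
    def clusters(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def condition_names(self) -> list[str]:
        return list(self.cpm.columns)


def normalize_cpm(raw: pd.DataFrame, design: PanningDesign) -> CountMatrix:
    """Scale each condition column to counts per million of its total.

    Columns whose declared total is zero must be all-zero and stay zero.
    """
    cols = [c for c in raw.columns if c != "total_raw"]
    missing = set(cols) - set(design.condition_names)
    if missing:
        raise SchemaError(f"count columns not in design: {sorted(missing)}")
    counts = raw[cols]
    cpm = pd.DataFrame(0.0, index=counts.index, columns=cols)
    for col in cols:
        total = design.totals.get(col, int(counts[col].sum()))
        col_sum = int(counts[col].sum())
        if col_sum > total:
            raise IntegrityError(
                f"condition {col!r}: counts sum {col_sum} exceeds declared total {total}")
        if total > 0:
            cpm[col] = 1e6 * counts[col] / total
        elif col_sum > 0:
            raise IntegrityError(f"condition {col!r} has counts but zero total")
    return CountMatrix(cpm=cpm, raw=counts.copy(), total_raw=counts.sum(axis=1))


@dataclass
class SelectionResult:
    """Clusters passing the multiplexed rule, ranked by raw size."""

    selected: pd.DataFrame  # cpm rows of selected clusters, ranked
    total_raw: pd.Series
    positive_hits: dict[str, list[str]]
    max_cpm: pd.Series
    control_max_cpm: float
    positive_min_cpm: float

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.selected.index)

    def __len__(self) -> int:
        return len(self.selected)


def select_candidates(
    matrix: CountMatrix,
    design: PanningDesign,
    control_max_cpm: float = 0.0,
    positive_min_cpm: float = 1.0,
) -> SelectionResult:
    """Apply the positive-presence / control-absence rule and rank.

    A cluster is selected iff its CPM strictly exceeds
    ``positive_min_cpm`` in at least one positive condition and is at
    most ``control_max_cpm`` in every control condition.  Ranking is by
    total raw count descending, ties broken by signature.
    """
    if control_max_cpm < 0 or positive_min_cpm < 0:
        raise ValueError("thresholds must be non-negative")
    missing = (set(design.positive_names) | set(design.control_names)) - set(matrix.condition_names)
    if missing:
        raise SchemaError(f"design conditions absent from matrix: {sorted(missing)}")
    cpm = matrix.cpm
    pos_cols = [c for c in design.positive_names if c in cpm.columns]
    ctl_cols = [c for c in design.control_names if c in cpm.columns]
    pos_ok = (cpm[pos_cols] > positive_min_cpm).any(axis=1)
    ctl_ok = (cpm[ctl_cols] <= control_max_cpm).all(axis=1) if ctl_cols else True
    keep = cpm.index[pos_ok & ctl_ok]
    total = matrix.total_raw.loc[keep]
    order = sorted(keep, key=lambda c: (-total[c], str(c)))
    selected = cpm.loc[order]
    hits = {
        c: [col for col in pos_cols if cpm.at[c, col] > positive_min_cpm]
        for c in order
    }
    return SelectionResult(
        selected=selected,
        total_raw=total.loc[order],
        positive_hits=hits,
        max_cpm=selected[pos_cols].max(axis=1),
        control_max_cpm=control_max_cpm,
        positive_min_cpm=positive_min_cpm,
    )


def cluster_report(result: SelectionResult) -> pd.DataFrame:
    """One row per selected cluster: per-condition CPM plus total_raw."""
    if len(result) == 0:
        raise ValueError("empty selection result")
    report = result.selected.copy()
    report["total_raw"] = result.total_raw
    report.index.name = "cluster"
    return report


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cluster")


def result_from_report(report: pd.DataFrame, design: PanningDesign | None = None,
                       control_max_cpm: float = 0.0,
                       positive_min_cpm: float = 1.0) -> SelectionResult:
    """Rebuild a SelectionResult from an emitted report table."""
    cpm = report.drop(columns=["total_raw"])
    design = design or design_from_columns(cpm.columns)
    matrix = CountMatrix(cpm=cpm, total_raw=report["total_raw"])
    return select_candidates(matrix, design, control_max_cpm, positive_min_cpm)


# ---------------------------------------------------------------------------
# packaged fixture: the published 34-cluster selection table
# ---------------------------------------------------------------------------

def load_table1() -> tuple[CountMatrix, PanningDesign]:
    """The packaged 34-cluster selection table (values per million as
    printed; empty cells are zeros; the Total column is the raw cluster
    size).  Returns the count matrix and the matching 12-condition design."""
    ref = importlib.resources.files("vhhsuite.data") / "table1.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="cluster")
    total = df["total"]
    cpm = df.drop(columns=["total"]).astype(float)
    design = design_from_columns(cpm.columns)
    matrix = CountMatrix(cpm=cpm, total_raw=total)
    return matrix, design


def recovery_metrics(result: SelectionResult, target_signatures: set[str],
                     background_signatures: set[str]) -> dict[str, float]:
    """Sensitivity and precision of a selection against simulation truth."""
    selected = set(result.cluster_ids)
    tp = len(selected & target_signatures)
    sensitivity = tp / len(target_signatures) if target_signatures else float("nan")
    precision = tp / len(selected) if selected else float("nan")
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_selected": float(len(selected)),
        "n_background_selected": float(len(selected & background_signatures)),
    }
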