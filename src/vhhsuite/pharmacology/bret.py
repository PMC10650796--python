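"""BRET kinetic-trace processing and plate-based screening calls.

Kinetic BRET ratios are normalised to percent of the maximal agonist
response, summarised by the area under the curve after stimulation, and
those AUCs feed the dose-response fits.  The reporter-gene screen and
the split-luciferase (NanoBiT) ligand-competition readout are simple
normalised-luminescence comparisons against a non-relevant control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"


def normalize_percent_max(traces: pd.DataFrame, reference: str,
                          condition_col: str = "condition",
                          signal_col: str = "signal") -> pd.DataFrame:
    """Scale every trace so the reference condition's maximum is 100.

    ``traces`` is long-form with at least (time, signal, condition)
    columns; the same scale factor 100/max(reference) is applied to all
    conditions, so amplitudes stay comparable across conditions.
    """
    ref = traces.loc[traces[condition_col] == reference, signal_col]
    if ref.empty:
        raise KeyError(f"reference condition {reference!r} not present")
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference maximum must be positive")
    out = traces.copy()
    out[signal_col] = out[signal_col] * (100.0 / ref_max)
    return out


def auc(time, signal, from_stimulation: float = 0.0,
        baseline_subtract: bool = True) -> float:
    """Trapezoidal area under a kinetic trace after the stimulation time.

    When ``baseline_subtract`` is on, the mean signal before stimulation
    is removed first (zero if there are no pre-stimulation points).
    """
    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    post = time >= from_stimulation
    if post.sum() < 2:
        raise ValueError("need at least two points after stimulation")
    y = signal.copy()
    if baseline_subtract:
        pre = time < from_stimulation
        if pre.any():
            y = y - float(signal[pre].mean())
    return float(np.trapezoid(y[post], time[post]))


@dataclass
class ReporterResult:
    """One candidate's reporter-gene call relative to the NR control."""

    candidate: str
    percent_of_control: float
    spread: float  # replicate SD on the percent scale
    label: str     # positive / negative / neutral


def classify_reporter(candidates: dict[str, np.ndarray], nr_control,
                      margin: float = 2.0) -> list[ReporterResult]:
    """Classify candidates by luminescence relative to the NR control.

    Each candidate's replicates are expressed as a percentage of the
    NR-control mean.  A candidate is called positive when its mean
    percent exceeds 100 by more than ``margin`` replicate SDs, negative
    when below by the same margin, neutral otherwise.  The control
    itself scores 100 by construction.
    """
    nr_mean = float(np.mean(nr_control))
    if nr_mean <= 0:
        raise ValueError("NR control mean must be positive")
    out = []
    for name, reps in candidates.items():
        pct = 100.0 * np.asarray(reps, dtype=float) / nr_mean
        mean_pct = float(pct.mean())
        spread = float(pct.std(ddof=1)) if pct.size > 1 else 0.0
        if mean_pct - 100.0 > margin * spread:
            label = POSITIVE
        elif mean_pct - 100.0 < -margin * spread:
            label = NEGATIVE
        else:
            label = NEUTRAL
        out.append(ReporterResult(name, mean_pct, spread, label))
    return out


@dataclass
class CompetitionVerdict:
    """Plateau-ratio comparison of luminescence with/without competitor."""

    ratio: float
    ci_low: float
    ci_high: float
    competes: bool


def nanobit_competition(competitor_traces, nr_traces,
                        plateau_fraction: float = 0.2,
                        alpha: float = 0.05) -> CompetitionVerdict:
    """Call ligand competition from split-luciferase plateau ratios.

    ``competitor_traces`` and ``nr_traces`` are (n_replicates, n_times)
    arrays of luminescence.  The steady-state plateau is the mean over
    the last ``plateau_fraction`` of the trace; the per-replicate
    plateau ratio (competitor / NR mean plateau) gets a t-interval, and
    "no competition" is declared when that interval contains 1.
    """
    comp = np.atleast_2d(np.asarray(competitor_traces, dtype=float))
    nr = np.atleast_2d(np.asarray(nr_traces, dtype=float))
    k = max(1, int(round(plateau_fraction * comp.shape[1])))
    comp_plateau = comp[:, -k:].mean(axis=1)
    nr_plateau = float(nr[:, -k:].mean())
    ratios = comp_plateau / nr_plateau
    mean = float(ratios.mean())
    if ratios.size > 1:
        sem = float(ratios.std(ddof=1) / np.sqrt(ratios.size))
        tcrit = stats.t.ppf(1 - alpha / 2, ratios.size - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    else:
        lo = hi = mean
    tol = 1e-9  # guard against zero-width CIs from identical replicates
    return CompetitionVerdict(ratio=mean, ci_low=lo, ci_high=hi,
                              competes=not (lo - tol <= 1.0 <= hi + tol))
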