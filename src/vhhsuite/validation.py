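"""Canonical recovery protocols run against synthetic ground truth.

These functions pin down the study conditions used to validate the
pipeline — the panning recovery simulation and the Monte-Carlo
dose-response recovery — so that tests, scripts and documentation all
exercise exactly the same protocol.
"""

from __future__ import annotations

import numpy as np

from .design import default_design
from .pharmacology.doseresponse import FourPLModel, FourPLParams
from .selection import normalize_cpm, recovery_metrics, select_candidates
from .synthetic import (
    POOL_ID,
    make_manifest,
    make_repertoire,
    fsh_dose_grid,
    simulate_dose_response,
    simulate_panning,
)

# Reference 4PL parameters of the PRC1-potentiated responses: cAMP
# production (AUC units) and miniGs recruitment (percent of maximal
# agonist response).  Baselines are zero because responses are
# baseline-subtracted AUCs.
PRC1_CAMP = FourPLParams(bottom=0.0, emax=34.52, ec50=0.15e-9, hill=1.0)
PRC1_MGS = FourPLParams(bottom=0.0, emax=100.0, ec50=2.5e-9, hill=1.0)
CAMP_NOISE_SD = 6.65  # response units, the reported dispersion of the top plateau
MGS_NOISE_SD = 10.0   # 10% of the normalised maximum

# Panning recovery conditions: 300 tracked clones spiked with 10 target
# and 5 background binders inside a 4e7-member library, 1e5 reads per
# condition on the 12-condition design.
RECOVERY_N_CLONES = 300
RECOVERY_N_TARGET = 10
RECOVERY_N_BACKGROUND = 5
RECOVERY_LIBRARY_SIZE = 40_000_000
RECOVERY_READS = 100_000


def ec50_recovery(
    truth: FourPLParams,
    noise_sd: float,
    n_replicates: int = 4,
    n_repeats: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo EC50 recovery on the half-log dose grid.

    Each repeat simulates one experiment (``n_replicates`` replicate
    responses per dose with additive Gaussian noise) and refits the 4PL
    with the bottom pinned at zero.  Returns the median and quartiles of
    the fitted EC50 over repeats, in molar.
    """
    doses = fsh_dose_grid()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    fitted = []
    for s in rep_seeds:
        data = simulate_dose_response(truth, doses, n_replicates=n_replicates,
                                      noise_sd=noise_sd, seed=int(s))
        res = FourPLModel(data["dose"].to_numpy(), data["response"].to_numpy()) \
            .fit(fix_bottom=0.0)
        fitted.append(res.ec50)
    fitted = np.array(fitted)
    return {
        "median_ec50": float(np.median(fitted)),
        "q25": float(np.percentile(fitted, 25)),
        "q75": float(np.percentile(fitted, 75)),
        "n_repeats": n_repeats,
    }


def selection_recovery(seed: int = 0) -> dict[str, float]:
    """One full panning recovery run at the canonical conditions.

    Simulates the 12-condition campaign at the recovery scale, applies
    the strict selection rule (present in a positive condition, absent
    from every control) and scores the selected set against the truth
    manifest.  Returns sensitivity, precision, the selected count and
    the number of background binders selected.
    """
    design = default_design()
    clones = make_repertoire(RECOVERY_N_CLONES, seed=seed)
    truth = make_manifest(clones, design, n_target=RECOVERY_N_TARGET,
                          n_background=RECOVERY_N_BACKGROUND,
                          library_size=RECOVERY_LIBRARY_SIZE, seed=seed)
    counts = simulate_panning(truth, design, reads_per_condition=RECOVERY_READS,
                              seed=seed)
    raw = counts.drop(index=POOL_ID)
    design = design.with_totals({c: int(counts[c].sum()) for c in counts.columns})
    matrix = normalize_cpm(raw, design)
    result = select_candidates(matrix, design)
    return recovery_metrics(result, truth.target_binders, truth.background_binders)
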