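"""Shared fixtures: small synthetic campaigns generated at test time."""

from __future__ import annotations

import pandas as pd
import pytest

from vhhsuite.design import CONTROL, POSITIVE, Condition, PanningDesign, default_design
from vhhsuite.synthetic import (
    TruthManifest,
    emit_reads,
    make_manifest,
    make_repertoire,
    simulate_panning,
)


@pytest.fixture(scope="session")
def design() -> PanningDesign:
    return default_design()


@pytest.fixture(scope="session")
def two_condition_design() -> PanningDesign:
    """Minimal design: one positive modality over rounds 1-3 + one control."""
    return PanningDesign([
        Condition("target", 1, POSITIVE),
        Condition("target", 2, POSITIVE),
        Condition("target", 3, POSITIVE),
        Condition("mock", 3, CONTROL),
    ])


def manifest_with_factors(clones, factors: pd.DataFrame, **kw) -> TruthManifest:
    """Build a manifest with hand-set per-modality factors."""
    return TruthManifest(clones=clones, factors=factors, **kw)


@pytest.fixture(scope="session")
def small_clones():
    return make_repertoire(20, seed=3)


@pytest.fixture(scope="session")
def campaign(tmp_path_factory, design):
    """A zero-error FASTQ campaign: 200 clones, 250 reads per condition."""
    outdir = tmp_path_factory.mktemp("campaign")
    clones = make_repertoire(200, seed=11)
    truth = make_manifest(clones, design, n_target=8, n_background=4, seed=11)
    counts = simulate_panning(truth, design, reads_per_condition=250, seed=11)
    paths = emit_reads(clones, counts, outdir / "fastq", seed=11)
    return {"clones": clones, "truth": truth, "counts": counts,
            "fastq_dir": outdir / "fastq", "paths": paths, "design": design}
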