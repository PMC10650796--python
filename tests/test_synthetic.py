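"""Ground-truth generator: determinism, conservation, closed-form limits."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy import stats

from vhhsuite.design import CONTROL, POSITIVE
from vhhsuite.pharmacology import FourPLParams, LangmuirParams, association, fourpl
from vhhsuite.synthetic import (
    POOL_ID,
    DegenerateSimulationError,
    TruthManifest,
    expected_frequencies,
    make_manifest,
    make_repertoire,
    simulate_bli_traces,
    simulate_bret_trace,
    simulate_dose_response,
    simulate_epitopes,
    simulate_panning,
)


class TestMakeRepertoire:
    def test_translation_round_trip(self):
        clone = make_repertoire(1, seed=7)[0]
        assert str(Seq(clone.nucleotide).translate()) == clone.protein

    def test_architecture_and_signature(self):
        clone = make_repertoire(1, seed=7)[0]
        assert clone.protein.startswith("QVQLVESGG")
        assert clone.signature == clone.cdr1 + clone.cdr2 + clone.cdr3
        for cdr in (clone.cdr1, clone.cdr2, clone.cdr3):
            assert cdr in clone.protein

    def test_determinism(self):
        a = make_repertoire(500, seed=1)
        b = make_repertoire(500, seed=1)
        assert [(c.clone_id, c.nucleotide) for c in a] == \
               [(c.clone_id, c.nucleotide) for c in b]

    def test_signature_duplicates_rare(self):
        clones = make_repertoire(500, seed=1)
        sigs = [c.signature for c in clones]
        dup_frac = 1 - len(set(sigs)) / len(sigs)
        assert dup_frac < 0.01

    @pytest.mark.parametrize("bad", [{"cdr1": (0, 3)}, {"cdr3": (9, 4)}])
    def test_impossible_ranges_rejected(self, bad):
        with pytest.raises(ValueError):
            make_repertoire(3, cdr_length_ranges=bad, seed=0)

    def test_requires_at_least_one_clone(self):
        with pytest.raises(ValueError):
            make_repertoire(0)


class TestSimulatePanning:
    def test_single_clone_takes_all_reads(self, two_condition_design):
        clones = make_repertoire(1, seed=2)
        factors = pd.DataFrame(
            {"target": [5.0], "mock": [0.5]},
            index=pd.Index([clones[0].clone_id], name="clone_id"))
        truth = TruthManifest(clones=clones, factors=factors)
        counts = simulate_panning(truth, two_condition_design, 1000, seed=0)
        assert (counts.sum(axis=0) == 1000).all()
        assert (counts.loc[clones[0].clone_id] == 1000).all()

    def test_two_clone_closed_form_frequency(self, two_condition_design):
        """With factors (2, 1) and a uniform start, the expected frequency
        of the favoured clone after round t is 2^t / (2^t + 1)."""
        clones = make_repertoire(2, seed=4)
        ids = [c.clone_id for c in clones]
        factors = pd.DataFrame({"target": [2.0, 1.0], "mock": [1.0, 1.0]},
                               index=pd.Index(ids, name="clone_id"))
        truth = TruthManifest(clones=clones, factors=factors)
        n = 100_000
        counts = simulate_panning(truth, two_condition_design, n, seed=9)
        for t in (1, 2, 3):
            expected = 2**t / (2**t + 1)
            np.testing.assert_allclose(
                expected_frequencies(truth, "target", t)[0], expected, rtol=1e-12)
            observed = counts.loc[ids[0], f"target_r{t}"] / n
            sd = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * sd

    def test_neutral_factors_stay_uniform(self, two_condition_design):
        """All factors equal -> counts consistent with a uniform multinomial."""
        clones = make_repertoire(50, seed=5)
        truth = make_manifest(clones, two_condition_design, n_target=0,
                              n_background=0, nonspecific_factor=1.0, seed=5)
        counts = simulate_panning(truth, two_condition_design, 100_000, seed=5)
        chi2 = stats.chisquare(counts["target_r3"]).pvalue
        assert chi2 > 0.001

    def test_counts_conserved_exactly(self, design, small_clones):
        truth = make_manifest(small_clones, design, n_target=3, n_background=2, seed=0)
        counts = simulate_panning(truth, design, 12345, seed=0)
        assert (counts.sum(axis=0) == 12345).all()

    def test_pool_row_present_and_conserved(self, design, small_clones):
        truth = make_manifest(small_clones, design, n_target=3, n_background=2,
                              library_size=1_000_000, seed=0)
        counts = simulate_panning(truth, design, 50_000, seed=0)
        assert POOL_ID in counts.index
        assert (counts.sum(axis=0) == 50_000).all()

    def test_enrichment_direction(self, two_condition_design, small_clones):
        """Expected frequency of an amplified clone strictly increases
        over rounds, and empirically at 1e5 reads within sampling error."""
        truth = make_manifest(small_clones, two_condition_design, n_target=1,
                              n_background=0, seed=1)
        target = next(iter(truth.target_binders))
        idx = truth.clone_ids.index(target)
        freqs = [expected_frequencies(truth, "target", t)[idx] for t in range(4)]
        assert all(b > a for a, b in zip(freqs, freqs[1:]))
        counts = simulate_panning(truth, two_condition_design, 100_000, seed=1)
        obs = [counts.loc[target, f"target_r{t}"] / 100_000 for t in (1, 2, 3)]
        for o, e in zip(obs, freqs[1:]):
            assert abs(o - e) < 3 * np.sqrt(e * (1 - e) / 100_000) + 1e-9

    def test_determinism(self, design, small_clones):
        truth = make_manifest(small_clones, design, seed=2, n_target=3, n_background=2)
        a = simulate_panning(truth, design, 1000, seed=2)
        b = simulate_panning(truth, design, 1000, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_probability_is_degenerate(self, two_condition_design, small_clones):
        ids = [c.clone_id for c in small_clones]
        factors = pd.DataFrame(0.0, index=pd.Index(ids, name="clone_id"),
                               columns=["target", "mock"])
        truth = TruthManifest(clones=small_clones, factors=factors)
        with pytest.raises(DegenerateSimulationError):
            simulate_panning(truth, two_condition_design, 100, seed=0)


class TestManifest:
    def test_target_binder_factor_invariants(self, design, small_clones):
        truth = make_manifest(small_clones, design, n_target=5, n_background=3, seed=6)
        control_mods = {c.modality for c in design.conditions if c.role == CONTROL}
        positive_mods = {c.modality for c in design.conditions if c.role == POSITIVE}
        for cid in truth.target_binders:
            row = truth.factors.loc[cid]
            assert any(row[m] > 1 for m in positive_mods)
            assert all(row[m] <= 1 for m in control_mods)
        for cid in truth.background_binders:
            assert (truth.factors.loc[cid] > 1).all()

    def test_tsv_round_trip(self, design, small_clones, tmp_path):
        truth = make_manifest(small_clones, design, n_target=4, n_background=2,
                              library_size=500_000, seed=8)
        path = tmp_path / "manifest.tsv"
        truth.to_tsv(path)
        back = TruthManifest.from_tsv(path)
        assert back.target_binders == truth.target_binders
        assert back.background_binders == truth.background_binders
        assert back.library_size == truth.library_size
        pd.testing.assert_frame_equal(back.factors, truth.factors)
        assert [(c.clone_id, c.nucleotide, c.protein) for c in back.clones] == \
               [(c.clone_id, c.nucleotide, c.protein) for c in truth.clones]


class TestSimulateEpitopes:
    def test_single_site_all_compete(self):
        from vhhsuite.epitopes import competition_call, overlap_ratio

        preds, _, _ = simulate_epitopes(6, n_sites=1, seed=0)
        for i in range(len(preds)):
            for j in range(i + 1, len(preds)):
                assert competition_call(overlap_ratio(preds[i], preds[j]))

    def test_disjoint_sites_no_overlap(self):
        from vhhsuite.epitopes import overlap_ratio

        preds, _, site_of = simulate_epitopes(6, n_sites=6, seed=0)
        for i in range(6):
            for j in range(i + 1, 6):
                assert overlap_ratio(preds[i], preds[j]) == 0.0

    def test_similarity_separates_sites(self):
        _, sim, site_of = simulate_epitopes(12, n_sites=3, seed=1)
        names = list(sim.index)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if site_of[a] == site_of[b]:
                    assert sim.loc[a, b] > 50
                else:
                    assert sim.loc[a, b] < 30

    def test_too_many_sites_rejected(self):
        with pytest.raises(ValueError):
            simulate_epitopes(2, n_sites=3)


class TestTraces:
    def test_association_asymptote_and_half_saturation(self):
        p = LangmuirParams(3.19e4, 1.59e-3, 1.0)
        req = association(1e9, p.kd, p.kon, p.koff, p.rmax)  # t -> infinity at C = K_D
        np.testing.assert_allclose(req, p.rmax / 2, rtol=1e-12)

    def test_kobs_arithmetic(self):
        # k_obs = k_on*C + k_off at C = 100 nM
        kobs = 3.19e4 * 100e-9 + 1.59e-3
        np.testing.assert_allclose(kobs, 4.78e-3, rtol=1e-12)

    def test_noiseless_traces_match_closed_form(self):
        p = LangmuirParams(3.19e4, 1.59e-3, 1.0)
        t = np.linspace(0, 100, 51)
        traces = simulate_bli_traces(p, [50e-9], t, t_dissoc=200.0)
        kobs = p.kon * 50e-9 + p.koff
        req = p.rmax * 50e-9 / (50e-9 + p.kd)
        expected = req * (1 - np.exp(-kobs * t))
        np.testing.assert_allclose(traces[0], expected, rtol=1e-10)

    def test_noiseless_dose_response_exact(self):
        truth = FourPLParams(0.0, 100.0, 1e-9, 1.2)
        doses = np.logspace(-10, -7, 6)
        df = simulate_dose_response(truth, doses, n_replicates=2, noise_sd=0.0)
        expected = fourpl(df["dose"].to_numpy(), 0.0, 100.0, 1e-9, 1.2)
        np.testing.assert_allclose(df["response"].to_numpy(), expected, rtol=1e-10)

    def test_bret_trace_baseline_and_plateau(self):
        t = np.arange(0, 3600, 60.0)
        sig = simulate_bret_trace(80.0, t, t_stim=300.0, tau=200.0)
        assert (sig[t < 300] == 0).all()
        np.testing.assert_allclose(sig[-1], 80.0, rtol=1e-6)

    def test_trace_determinism(self):
        p = LangmuirParams(1e5, 1e-3, 1.0)
        t = np.linspace(0, 50, 20)
        a = simulate_bli_traces(p, [1e-8], t, 30.0, noise_sd=0.1, seed=4)
        b = simulate_bli_traces(p, [1e-8], t, 30.0, noise_sd=0.1, seed=4)
        np.testing.assert_array_equal(a, b)
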