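# vhhsuite

Selecting modulatory VHHs (nanobodies) against a membrane receptor by
multiplexed phage display produces millions of NGS reads across a dozen
panning conditions — and a handful of downstream pharmacology assays for
the candidates that survive. `vhhsuite` implements that computational
workflow end to end, for teams running phage-display campaigns against
hard targets such as GPCRs:

- **Repertoire processing** — paired amplicon reads are adapter-trimmed
  and overlap-merged, the reading frame is fixed by a conserved FR1
  protein label, CDRs are extracted, and clones are collapsed into
  non-redundant clusters keyed by their *signature* (CDR1+CDR2+CDR3).
- **Multiplexed candidate selection** — cluster counts are normalised
  per million per condition; a cluster is a candidate iff it is present
  in at least one target-positive condition and absent from every
  negative control, ranked by raw cluster size.
- **Sequence-space embedding** — signatures are encoded as sparse
  amino-acid 5-mer count vectors and projected to 2D with UMAP
  (n_neighbors=15, Euclidean), with candidate overlay and outlier calls.
- **Epitope matrices** — pairwise epitope overlap
  O = |shared residues| / max(|epitope A|, |epitope B|) with competition
  called at O > 0.3; similarity-score tiers (probability 0.95 above 50,
  0.75 for 30–50); and the incoherence matrix, min–max-normalised
  similarity minus overlap.
- **Pharmacology** — BLI double referencing and global 1:1 Langmuir
  fits (k_on, k_off, K_D = k_off/k_on); BRET kinetic normalisation to
  percent of maximal agonist response, trapezoidal AUC, and 4PL
  dose-response fits y = bottom + (Emax − bottom)/(1 + (EC50/x)^h);
  reporter-gene and split-luciferase competition calls.
- **Synthetic campaigns** — a generator that emulates the whole study
  with known ground truth: geometric round-over-round enrichment with
  washing depletion, multinomial read sampling, paired FASTQ emission,
  planted epitope sites, and noisy binding/signalling traces.

## Worked example

Fit 1:1 binding kinetics to noisy synthetic sensorgrams generated at
k_on = 3.19e4 1/(M·s), k_off = 1.59e-3 1/s:

```python
import numpy as np
from vhhsuite.pharmacology import LangmuirModel, LangmuirParams
from vhhsuite.synthetic import simulate_bli_traces

truth = LangmuirParams(kon=3.19e4, koff=1.59e-3, rmax=1.2)
t = np.arange(0.0, 251.0, 1.0)
concs = [12.5e-9, 25e-9, 50e-9, 100e-9, 200e-9]
traces = simulate_bli_traces(truth, concs, t, t_dissoc=100.0,
                             noise_sd=0.024, seed=12)
print(LangmuirModel(t, traces, concs, t_dissoc=100.0).fit().summary())
```

```
1:1 Langmuir kinetic fit
==============================================
parameter       estimate       std err
----------------------------------------------
k_on           3.232e+04      1.26e+03   1/(M*s)
k_off           0.001584      5.96e-05   1/s
R_max              1.189        0.0383   RU
K_D            4.901e-08      2.92e-09   M
----------------------------------------------
residual RMS: 0.02404 RU over 1255 points, 5 concentrations
```

The global fit over five analyte concentrations recovers the rates
within their standard errors; K_D lands at 49.0 nM versus the 49.8 nM
implied by the generating constants.

Candidate selection on the packaged published count table:

```python
from vhhsuite.selection import load_table1, select_candidates

matrix, design = load_table1()
result = select_candidates(matrix, design)
print(len(result), result.cluster_ids[0], int(result.total_raw.iloc[0]))
# 34 PRC1 45099
```

All 34 reported clusters pass the strict positive-presence /
control-absence rule, and the largest cluster (PRC1, 45,099 reads)
ranks first.

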