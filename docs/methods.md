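# Methods

## The selection problem

A multiplexed phage-display campaign pans VHH libraries against several
physical presentations of the target receptor (whole cells, membranes,
proteoliposomes, recombinant ectodomain with and without an MBP fusion,
an N-terminal peptide), each with matched negative controls and two or
three rounds of selection. NGS of every round yields per-condition read
counts for each clone. The computational task is to find clones
specifically enriched by the target: present in at least one
target-positive condition, absent from every control.

`vhhsuite` operates on *signature clusters*: clones are identified by
the concatenation of their three CDRs, so two clones differing only in
framework residues are the same cluster. Counts are normalised per
million within each condition (CPM) before thresholding, which makes
conditions of different sequencing depth comparable.

### Selection rule

A cluster is selected iff CPM > `positive_min_cpm` (default 1) in at
least one positive condition **and** CPM ≤ `control_max_cpm` (default
0, strict absence) in all control conditions. Strict absence is the
deliberate default — at realistic library sizes a specific clone is
never sampled in a control — but the threshold is exposed because
index-hopping and contamination make strict zero fragile on real
instruments. Ranking is by raw cluster size, descending (ties broken
lexicographically by signature); cluster size is the campaign's
empirical predictor of affinity. An optional round-over-round
fold-change filter exists but is off by default: presence/absence is
the primary published criterion, and the two-round conditions give the
fold filter little to work with.

## Synthetic campaigns and what they do (not) show

The generator emulates the study's structure with known ground truth.

*Enrichment model.* Between rounds, clone frequencies update
geometrically, p_i ∝ p_i · a_{i,m}, where a_{i,m} is the clone's
per-round factor in modality m; after t rounds from a uniform start the
expected frequency is a^t / Σ a^t, which gives closed-form oracles for
tests. Panning physically washes unbound phage away, so the baseline
factor for a non-binder is `nonspecific_factor` = 0.2 per round (a
20-fold per-round enrichment of a binder with a = 4 over background,
typical of phage panning). Spiked target binders take a = 4 in one
randomly chosen positive modality and the non-specific factor
everywhere else, controls included; sticky background binders take
a = 3 in *every* condition, the failure mode the control filter must
remove. Read counts are multinomial at the configured depth, so
condition totals are conserved exactly.

*Library scale.* The tracked repertoire (default 300 clones for
count-level studies, 5000 for FASTQ-level runs) can be embedded in an
untracked pool representing the remainder of an immune library
(`library_size`, default 4×10⁷ in the recovery protocol — a realistic
immune VHH library diversity). The pool behaves as non-specific mass
and appears as one pseudo-row in count tables; it is what makes strict
control absence attainable, because any individual clone's control
frequency is ~1/L.

*Reads.* Amplicons are adapter + CDS + reverse-complemented adapter;
paired 250-nt reads are the amplicon's ends, overlapping by
construction. Sequencing error is an optional uniform substitution rate,
default 0. Quality strings are constant Q40 — quality realism is out of
scope; quality only enters the merge consensus (higher base wins).

*What passing tests do not show.* Real repertoires have skewed clone
abundances, PCR bias, chimeras and position-dependent error profiles;
none are modelled. Recovery rates measured here characterise the
selection rule under the stated enrichment model, not any instrument.

### Recovery protocol (canonical conditions)

300 tracked clones (10 targets, 5 background) in a 4×10⁷ library,
10⁵ reads per condition on the 12-condition design, strict selection.
Expected per-target selection probability is ≈0.99
((1−e^(−λ_pos))·e^(−4R/L) with λ_pos ≈ 20), so ≥90% sensitivity with
zero background selections is the expected outcome, and the suite
asserts it at a fixed seed.

## Repertoire processing

Merging scans suffix/prefix overlaps from longest to shortest and
accepts the first with mismatch fraction ≤ 0.1 (minimum overlap 10 nt);
mismatches resolve toward the higher-quality base. Frame detection
translates all six frames and requires the conserved 9-aa FR1 label in
exactly one: zero hits reject as `no_anchor`, several as
`ambiguous_frame`, and a stop codon after the label as `internal_stop`.
CDR delimitation is motif-anchored: the four framework sequences of the
scaffold must occur in order and tile the protein; the three gaps are
the CDRs. The default scheme uses a camelid VHH scaffold with
Chothia-like boundaries and is configurable. Every stage returns
rejections with reason codes, and count conservation (reads in = passed
+ rejected) holds at each stage. All intervals are 0-based half-open
internally, 1-based in reports.

De-duplication happens once, at the protein signature level; whether to
pre-collapse at the nucleotide level is moot for counting because the
grouping key is the signature either way.

## Embedding

Signatures become sparse counts of overlapping 5-mers (only observed
k-mers are materialised; the full 20⁵ vocabulary never is). UMAP runs
with n_neighbors = 15, two components, Euclidean metric, fixed seed
(default 42 — reproducibility matters more than any particular value).
Duplicate rows are collapsed before projection and share coordinates
afterwards, so identical signatures are exactly coincident. Candidates
are overlaid by flagging any whose nearest fellow candidate is farther
than the 0.25 quantile of the background's pairwise-distance
distribution: low quantiles of that distribution reflect within-cluster
scales of the map, so a candidate beyond them belongs to no candidate
cluster. The quantile is configurable; there is no published
quantitative criterion for "clustered together", so this rule is the
package's own. Candidates are embedded jointly with the full set (not
transformed post hoc) and flagged afterwards.

## Epitope matrices

Overlap counts predicted epitope residues of the three confidence tiers
(very_high/high/medium) with equal weight — the tiers are counted
jointly upstream, and tier weighting would add a free parameter with no
calibration data. Competition is strict: O > 0.3. Similarity scores map
to shared-epitope probabilities of 0.95 (score > 50) and 0.75
(30 ≤ score ≤ 50); below 30 the pair is reported unassessed, not zero.
Incoherence is S̃ − O with S̃ min–max-normalised over off-diagonal
entries only (self-similarity would saturate the max); its diagonal is
undefined and reported as NaN. Pairs with incoherence above a
configurable flag threshold (default 0.5) are counted; the threshold
behind any particular published incoherence count is not recoverable,
so the default is not tuned to reproduce one.

## Pharmacology

*BLI.* Double referencing subtracts the non-relevant-control and blank
sensorgrams and re-zeroes at association start. The 1:1 model is
R(t) = R_eq(C)(1 − e^(−k_obs t)) with k_obs = k_on·C + k_off and
R_eq = R_max·C/(C + K_D) in association, R₀e^(−k_off(t−t_d)) in
dissociation, fitted globally (k_on, k_off, R_max shared across
concentrations) — the standard, better-conditioned treatment for
sensorgram series; rates are parameterised on the log scale for
positivity. Standard errors come from the Jacobian at the optimum, K_D's
by the delta method. K_D ≡ k_off/k_on holds as an identity. (The rate
constants' units are 1/(M·s) and 1/s, as the 1:1 model requires.)

*BRET.* Kinetic traces are normalised so the maximal agonist response
is 100%; the AUC is trapezoidal over the post-stimulation window after
subtracting the pre-stimulation mean. AUC is linear and additive over
windows, which the suite asserts.

*Dose-response.* y = bottom + (Emax − bottom)/(1 + (EC50/x)^h), EC50
parameterised internally as log EC50, Hill free by default,
initialisation from response quartiles and the half-response dose.
`fit(fix_bottom=0.0)` pins the lower plateau: baseline-subtracted AUCs
are zero at zero dose by construction, and when the EC50 sits below the
lowest dose of the half-log grid a free bottom is not identifiable (it
rides a bottom/EC50/Hill ridge; noiseless fits are exact either way,
noisy free-bottom fits are biased). Fit comparison reports the EC50
fold-shift, Emax ratio and approximate 95% CI overlap — a coarse
screen, deliberately, rather than a formal ANOVA, which is standard
machinery orthogonal to this pipeline.

*Monte-Carlo EC50 recovery.* Each repeat simulates one experiment of 4
replicate responses per dose on the 10^−9.5–10^−6.5 M half-log grid
with additive Gaussian noise, refits with bottom pinned, and the median
fitted EC50 over 200 repeats is reported. Noise SDs: 6.65 response
units for the cAMP condition (the reported dispersion of its top
plateau) and 10% of the normalised maximum for miniGs recruitment
(whose dispersion is not reported; 10% is a typical BRET assay spread).
The median EC50 is slightly right-skewed when the true EC50 lies below
the dose grid — a property of the design, visible in the reported
quartiles.

*Screening calls.* Reporter-gene candidates are expressed as percent of
the non-relevant-control mean and called positive/negative when the
mean departs from 100 by more than `margin` (default 2) replicate SDs.
The split-luciferase competition verdict compares steady-state plateaus
(mean over the last 20% of the trace) as a ratio with a t-interval;
"no competition" means the interval contains 1.

## Orchestration

One YAML config drives synth → repertoire → select → embed
sequentially on one machine. Every stage's outputs are SHA-256-hashed
into a run manifest; reruns with the same seeds are hash-identical, and
`--resume` skips stages whose recorded outputs verify. A stage failure
halts the run with the stage name — no silent partial results.

## Problem sizes

Defaults are chosen so a full validation pass (suite plus recovery
protocols) completes on a single CPU in a couple of minutes: 200–5000
clone repertoires for sequence-level runs, count-level recovery at
4×10⁷ library scale (which costs nothing extra — the pool is one
multinomial category), 200 Monte-Carlo repeats for EC50 recovery, and
120-signature embeddings for neighbourhood-purity checks.

## Known limitations

- The enrichment model has no PCR bias, chimera formation or
  phage-growth kinetics; factors are constant across rounds.
- CDR annotation assumes the configured framework anchors; heavily
  mutated frameworks would need a profile-based annotator.
- The similarity scores consumed by the epitope matrices are external
  inputs; the package neither docks nor encodes CDR structure.
- CI-overlap reporting is not a significance test.
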