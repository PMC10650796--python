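"""Synthetic data with known ground truth for the whole pipeline.

Generates VHH repertoires with the FR1..FR4 / CDR1..3 architecture,
round-over-round panning count dynamics with spiked target binders and
sticky background binders, paired amplicon reads, epitope predictions
with a planted site structure, and noisy binding/signalling traces.

The enrichment model is geometric: a clone with per-modality binding
factor a grows as p_i(t) proportional to p_i(t-1) * a between rounds, so
after t rounds from a uniform start the expected frequency of clone i in
modality m is a_{i,m}^t / sum_j a_{j,m}^t.  Panning rounds wash unbound
phage away, so clones that do not bind a condition's surface carry a
depletion factor below 1 there; spiked target binders amplify (a > 1) in
their positive modality and are washed like any non-binder elsewhere,
while sticky background binders amplify everywhere, controls included.
A campaign can embed the tracked clones in an untracked "pool"
representing the remainder of a large immune library; the pool behaves
as non-specific mass and appears as a single pseudo-row in count tables.
Counts are multinomial at the configured sequencing depth, so condition
totals are conserved exactly.  All randomness flows from explicit
integer seeds and the output is byte-reproducible.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .design import POSITIVE, PanningDesign, default_design
from .epitopes import EpitopePrediction, TIERS
from .pharmacology.doseresponse import FourPLParams, fourpl
from .pharmacology.langmuir import LangmuirParams, sensorgram
from .repertoire import FrameworkScheme

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

DEFAULT_CDR_RANGES = {"cdr1": (5, 9), "cdr2": (6, 11), "cdr3": (8, 19)}
DEFAULT_ADAPTER = "ACACGACGCTCTTCCGATCT"
POOL_ID = "__pool__"


class DegenerateSimulationError(RuntimeError):
    """Raised when a panning condition has zero total clone probability."""


@dataclass
class CloneRecord:
    """One synthetic VHH clone with its coding sequence and architecture."""

    clone_id: str
    nucleotide: str
    protein: str
    cdr1: str
    cdr2: str
    cdr3: str

    @property
    def signature(self) -> str:
        return self.cdr1 + self.cdr2 + self.cdr3


@dataclass
class TruthManifest:
    """Ground truth of a simulated campaign.

    ``factors`` is a (clone x modality) table of per-round amplification
    factors a_{i,m}; target binders have a > 1 in at least one positive
    modality and a <= 1 in every control modality, background binders
    are enriched in controls too.  ``library_size`` above the number of
    tracked clones adds an untracked pool with the non-specific factor.
    """

    clones: list[CloneRecord]
    factors: pd.DataFrame  # index clone_id, columns modality names
    target_binders: set[str] = field(default_factory=set)
    background_binders: set[str] = field(default_factory=set)
    seed: int = 0
    library_size: int | None = None
    pool_factor: float = 1.0

    def __post_init__(self):
        ids = [c.clone_id for c in self.clones]
        if set(ids) != set(self.factors.index):
            raise ValueError("factors must cover exactly the manifest clones")
        if (self.factors.to_numpy() < 0).any():
            raise ValueError("binding factors must be >= 0")

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    def clone(self, clone_id: str) -> CloneRecord:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise KeyError(clone_id)

    def to_tsv(self, path_or_buf) -> None:
        df = self.factors.copy()
        df.insert(0, "protein_seq", [c.protein for c in self.clones])
        df.insert(0, "nucleotide", [c.nucleotide for c in self.clones])
        df.insert(0, "cdr3", [c.cdr3 for c in self.clones])
        df.insert(0, "cdr2", [c.cdr2 for c in self.clones])
        df.insert(0, "cdr1", [c.cdr1 for c in self.clones])
        df["is_target_binder"] = [int(i in self.target_binders) for i in df.index]
        df["is_background_binder"] = [int(i in self.background_binders) for i in df.index]
        df["seed"] = self.seed
        df["library_size"] = self.library_size if self.library_size is not None else -1
        df["pool_factor"] = self.pool_factor
        df.to_csv(path_or_buf, sep="\t", index_label="clone_id")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "TruthManifest":
        df = pd.read_csv(path_or_buf, sep="\t", index_col="clone_id")
        meta = ["cdr1", "cdr2", "cdr3", "nucleotide", "protein_seq",
                "is_target_binder", "is_background_binder", "seed",
                "library_size", "pool_factor"]
        clones = [
            CloneRecord(cid, row["nucleotide"], row["protein_seq"],
                        row["cdr1"], row["cdr2"], row["cdr3"])
            for cid, row in df.iterrows()
        ]
        factors = df.drop(columns=meta)
        lib = int(df["library_size"].iloc[0]) if len(df) else -1
        return cls(
            clones=clones,
            factors=factors,
            target_binders={i for i in df.index if df.loc[i, "is_target_binder"]},
            background_binders={i for i in df.index if df.loc[i, "is_background_binder"]},
            seed=int(df["seed"].iloc[0]) if len(df) else 0,
            library_size=None if lib < 0 else lib,
            pool_factor=float(df["pool_factor"].iloc[0]) if len(df) else 1.0,
        )


@dataclass(frozen=True)
class SyntheticAssayTruth:
    """Generating parameters for the binding and signalling simulations."""

    langmuir: LangmuirParams
    fourpl: FourPLParams
    noise_sd: float = 0.0
    seed: int = 0


# ---------------------------------------------------------------------------
# repertoire generation
# ---------------------------------------------------------------------------

def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    # one uniform draw per residue, scaled to that residue's codon count
    u = rng.random(len(protein))
    return "".join(
        _CODONS[aa][int(u[i] * len(_CODONS[aa]))] for i, aa in enumerate(protein)
    )


def make_repertoire(
    n_clones: int,
    cdr_length_ranges: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    scheme: FrameworkScheme | None = None,
) -> list[CloneRecord]:
    """Generate VHH clones sharing a framework scaffold with random CDRs.

    Each clone is FR1+CDR1+FR2+CDR2+FR3+CDR3+FR4 on the protein level,
    with CDR lengths drawn uniformly from the configured ranges and the
    nucleotide sequence a random synonymous reverse translation.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    ranges = dict(DEFAULT_CDR_RANGES)
    if cdr_length_ranges:
        ranges.update(cdr_length_ranges)
    for name, (lo, hi) in ranges.items():
        if not (1 <= lo <= hi):
            raise ValueError(f"impossible length range for {name}: ({lo}, {hi})")
    scheme = scheme or FrameworkScheme()
    rng = np.random.default_rng(seed)
    aas = list(AA_ALPHABET)
    clones = []
    width = len(str(n_clones - 1)) if n_clones > 1 else 1
    for i in range(n_clones):
        cdrs = {}
        for name in ("cdr1", "cdr2", "cdr3"):
            lo, hi = ranges[name]
            length = int(rng.integers(lo, hi + 1))
            cdrs[name] = "".join(rng.choice(aas, size=length))
        protein = (scheme.fr1 + cdrs["cdr1"] + scheme.fr2 + cdrs["cdr2"]
                   + scheme.fr3 + cdrs["cdr3"] + scheme.fr4)
        nt = _reverse_translate(protein, rng)
        clones.append(CloneRecord(f"clone{i:0{width}d}", nt, protein, **cdrs))
    return clones


def make_manifest(
    clones: list[CloneRecord],
    design: PanningDesign | None = None,
    n_target: int = 10,
    n_background: int = 5,
    target_factor: float = 4.0,
    background_factor: float = 3.0,
    nonspecific_factor: float = 0.2,
    library_size: int | None = None,
    seed: int = 0,
) -> TruthManifest:
    """Spike target binders and sticky background binders into a repertoire.

    Panning washes deplete anything that does not bind, so the baseline
    per-round factor is ``nonspecific_factor`` (< 1).  Target binders
    amplify by ``target_factor`` in one randomly chosen positive
    modality and are washed like non-binders everywhere else, controls
    included; background binders amplify by ``background_factor`` in
    every modality — the target-independent stickiness the
    negative-control filter must remove.  ``library_size`` larger than
    the tracked repertoire embeds it in an untracked non-specific pool.
    """
    design = design or default_design()
    if n_target + n_background > len(clones):
        raise ValueError("not enough clones for the requested binders")
    if not 0 < nonspecific_factor <= 1:
        raise ValueError("nonspecific_factor must be in (0, 1]")
    if library_size is not None and library_size < len(clones):
        raise ValueError("library_size smaller than the tracked repertoire")
    rng = np.random.default_rng(seed)
    modalities = design.modalities
    positive_mods = sorted({c.modality for c in design.conditions if c.role == POSITIVE})
    ids = [c.clone_id for c in clones]
    chosen = rng.choice(len(ids), size=n_target + n_background, replace=False)
    targets = {ids[i] for i in chosen[:n_target]}
    background = {ids[i] for i in chosen[n_target:]}
    factors = pd.DataFrame(nonspecific_factor, index=pd.Index(ids, name="clone_id"),
                           columns=modalities)
    for cid in sorted(targets):
        mod = positive_mods[int(rng.integers(len(positive_mods)))]
        factors.loc[cid, mod] = target_factor
    for cid in sorted(background):
        factors.loc[cid, :] = background_factor
    return TruthManifest(clones=clones, factors=factors, target_binders=targets,
                         background_binders=background, seed=seed,
                         library_size=library_size, pool_factor=nonspecific_factor)


# ---------------------------------------------------------------------------
# panning dynamics and reads
# ---------------------------------------------------------------------------

def expected_frequencies(manifest: TruthManifest, modality: str, rounds: int,
                         start: np.ndarray | None = None) -> np.ndarray:
    """Deterministic limit of the geometric update after ``rounds`` rounds.

    When the manifest embeds the clones in a larger library, the last
    entry of the returned vector is the untracked pool's frequency.
    """
    a = manifest.factors[modality].to_numpy(dtype=float)
    n = a.size
    if manifest.library_size is not None and manifest.library_size > n:
        pool_mass = (manifest.library_size - n) / manifest.library_size
        a = np.append(a, manifest.pool_factor)
        p = np.append(np.full(n, 1.0 / manifest.library_size), pool_mass)
    else:
        p = np.full(n, 1.0 / n)
    if start is not None:
        p = np.asarray(start, dtype=float)
    w = p * a**rounds
    total = w.sum()
    if total <= 0:
        raise DegenerateSimulationError(f"zero total probability in modality {modality!r}")
    return w / total


def simulate_panning(
    manifest: TruthManifest,
    design: PanningDesign | None = None,
    reads_per_condition: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial clone counts for every condition in the design.

    Each condition's counts sum exactly to ``reads_per_condition``.
    """
    design = design or default_design()
    missing = set(design.modalities) - set(manifest.factors.columns)
    if missing:
        raise ValueError(f"manifest lacks factors for modalities: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    has_pool = (manifest.library_size is not None
                and manifest.library_size > len(manifest.clones))
    counts = {}
    for cond in design.conditions:
        p = expected_frequencies(manifest, cond.modality, cond.round)
        counts[cond.name] = rng.multinomial(reads_per_condition, p)
    index = manifest.clone_ids + ([POOL_ID] if has_pool else [])
    return pd.DataFrame(counts, index=pd.Index(index, name="clone_id"))


def _phred_string(qual: np.ndarray) -> str:
    return "".join(chr(q + 33) for q in qual)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    bases = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(bases.size) < error_rate
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in np.nonzero(hit)[0]:
        choices = alphabet[alphabet != bases[i]]
        bases[i] = rng.choice(choices)
    return bases.tobytes().decode()


def emit_reads(
    clones: list[CloneRecord],
    counts: pd.DataFrame,
    outdir,
    read_length: int = 250,
    adapter: str = DEFAULT_ADAPTER,
    error_rate: float = 0.0,
    min_overlap: int = 10,
    seed: int = 0,
) -> dict[str, tuple[str, str]]:
    """Write paired FASTQ files per condition from a clone count table.

    The amplicon is adapter + coding sequence + reverse-complemented
    adapter; the forward read is its prefix and the reverse read the
    reverse complement of its suffix, so the pair reconstructs the
    amplicon by overlap merging.  Returns condition -> (R1, R2) paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    by_id = {c.clone_id: c for c in clones}
    paths: dict[str, tuple[str, str]] = {}
    for cond in counts.columns:
        r1_path = outdir / f"{cond}_R1.fastq"
        r2_path = outdir / f"{cond}_R2.fastq"
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            n = 0
            for cid, count in counts[cond].items():
                if count == 0:
                    continue
                clone = by_id[cid]
                amplicon = adapter + clone.nucleotide + str(Seq(adapter).reverse_complement())
                if read_length >= len(amplicon):
                    raise ValueError(
                        f"read_length {read_length} >= amplicon length {len(amplicon)}")
                if 2 * read_length - len(amplicon) < min_overlap:
                    raise ValueError("reads too short to overlap by the configured minimum")
                fwd_t = amplicon[:read_length]
                rev_t = str(Seq(amplicon[-read_length:]).reverse_complement())
                for _ in range(int(count)):
                    fwd = _apply_errors(fwd_t, error_rate, rng)
                    rev = _apply_errors(rev_t, error_rate, rng)
                    qual = "I" * read_length  # Q40, Sanger/Illumina 1.8+ offset 33
                    rid = f"{cond}:{cid}:{n}"
                    f1.write(f"@{rid}/1\n{fwd}\n+\n{qual}\n")
                    f2.write(f"@{rid}/2\n{rev}\n+\n{qual}\n")
                    n += 1
        paths[cond] = (str(r1_path), str(r2_path))
    return paths


# ---------------------------------------------------------------------------
# epitope predictions with a planted site structure
# ---------------------------------------------------------------------------

def simulate_epitopes(
    n_antibodies: int,
    n_residues: int = 350,
    n_sites: int = 3,
    epitope_size: int = 12,
    site_size: int = 15,
    seed: int = 0,
) -> tuple[list[EpitopePrediction], pd.DataFrame, dict[str, int]]:
    """Epitope predictions and similarity scores with known site truth.

    Sites are disjoint residue blocks on the antigen; every antibody's
    epitope is a random ``epitope_size``-subset of its site's block, so
    same-site overlap is at least (2*epitope_size - site_size)/epitope_size
    (0.75 at the defaults, above the 0.3 competition threshold) and
    cross-site overlap is exactly 0.  Similarity scores are high within
    a site (above 50) and low across (below 30).

    Returns (predictions, similarity matrix, antibody -> site map).
    """
    if n_sites > n_antibodies:
        raise ValueError("need at least one antibody per site")
    if n_sites * site_size > n_residues:
        raise ValueError("antigen too small for the requested disjoint sites")
    if epitope_size > site_size:
        raise ValueError("epitope_size cannot exceed site_size")
    rng = np.random.default_rng(seed)
    gap = n_residues // n_sites
    blocks = [np.arange(s * gap + 1, s * gap + 1 + site_size) for s in range(n_sites)]
    names = [f"ab{i:02d}" for i in range(n_antibodies)]
    # round-robin assignment guarantees every site is populated
    site_of = {name: i % n_sites for i, name in enumerate(names)}
    predictions = []
    for name in names:
        block = blocks[site_of[name]]
        residues = rng.choice(block, size=epitope_size, replace=False)
        tiers = rng.choice(TIERS, size=epitope_size)
        predictions.append(EpitopePrediction(name, dict(zip(sorted(residues.tolist()), tiers))))
    sim = np.empty((n_antibodies, n_antibodies))
    for i in range(n_antibodies):
        sim[i, i] = 100.0
        for j in range(i + 1, n_antibodies):
            if site_of[names[i]] == site_of[names[j]]:
                s = rng.uniform(55.0, 85.0)
            else:
                s = rng.uniform(5.0, 25.0)
            sim[i, j] = sim[j, i] = s
    similarity = pd.DataFrame(sim, index=names, columns=names)
    return predictions, similarity, site_of


# ---------------------------------------------------------------------------
# binding and signalling traces
# ---------------------------------------------------------------------------

def simulate_bli_traces(
    params: LangmuirParams,
    concentrations,
    timegrid,
    t_dissoc: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Noisy 1:1 sensorgrams, one row per analyte concentration."""
    timegrid = np.asarray(timegrid, dtype=float)
    concentrations = np.atleast_1d(np.asarray(concentrations, dtype=float))
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(timegrid) <= 0):
        raise ValueError("timegrid must be strictly increasing")
    rng = np.random.default_rng(seed)
    clean = np.vstack([sensorgram(timegrid, c, params, t_dissoc) for c in concentrations])
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return clean


def simulate_bret_trace(
    amplitude: float,
    timegrid,
    t_stim: float = 0.0,
    tau: float = 300.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """One BRET kinetic trace: flat baseline, then a saturating rise.

    After stimulation the signal follows amplitude*(1 - exp(-(t-t_stim)/tau)),
    the shape of second-messenger accumulation under sustained stimulation.
    """
    timegrid = np.asarray(timegrid, dtype=float)
    rng = np.random.default_rng(seed)
    signal = np.where(timegrid < t_stim, 0.0,
                      amplitude * (1.0 - np.exp(-(timegrid - t_stim) / tau)))
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return signal


def simulate_dose_response(
    params: FourPLParams,
    doses,
    n_replicates: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate dose-response observations from a 4PL with Gaussian noise.

    Returns a long DataFrame (dose, replicate, response), the shape the
    dose-response model consumes directly.
    """
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        clean = fourpl(doses, params.bottom, params.emax, params.ec50, params.hill)
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
        rows.append(pd.DataFrame({"dose": doses, "replicate": rep, "response": noisy}))
    return pd.concat(rows, ignore_index=True)


def make_family_repertoire(
    n_families: int = 3,
    n_per_family: int = 40,
    n_mutations: int = 2,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Signatures in distinct sequence families (shared CDR cores with
    point variants), with family labels for neighbourhood-purity checks.

    Each family descends from one founder clone; members carry up to
    ``n_mutations`` random CDR substitutions relative to the founder.
    Returns (signatures, family label per signature).
    """
    rng = np.random.default_rng(seed)
    founders = make_repertoire(n_families, seed=seed)
    aas = list(AA_ALPHABET)
    signatures, labels = [], []
    for fam, clone in enumerate(founders):
        base = clone.signature
        for _ in range(n_per_family):
            sig = list(base)
            k = int(rng.integers(0, n_mutations + 1))
            for pos in rng.choice(len(sig), size=k, replace=False):
                sig[pos] = aas[int(rng.integers(len(aas)))]
            signatures.append("".join(sig))
            labels.append(fam)
    return signatures, np.array(labels)


def fsh_dose_grid(n: int = 7) -> np.ndarray:
    """Half-log FSH concentration grid from 10^-9.5 to 10^-6.5 M."""
    return np.logspace(-9.5, -6.5, n)
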