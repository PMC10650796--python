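"""End-to-end orchestration: synth -> repertoire -> select -> embed.

One YAML config drives a run; every stage writes its outputs into the
run directory and records them (with content hashes) in a manifest, so
reruns are verifiable and a partial run can resume from completed
stages.  Stages execute sequentially on one machine.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .design import PanningDesign, default_design
from .embedding import embed as embed_op
from .embedding import kmer_encode, overlay_candidates
from .repertoire import process_fastq_dir, write_cluster_table
from .selection import cluster_report, normalize_cpm, select_candidates, write_report
from .synthetic import (
    DEFAULT_ADAPTER,
    make_manifest,
    make_repertoire,
    emit_reads,
    simulate_panning,
)

log = logging.getLogger("vhhsuite")

STAGES = ("synth", "repertoire", "select", "embed")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and reason."""

    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    outdir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    design_path: str | None = None
    # synth stage
    n_clones: int = 5000
    n_target: int = 10
    n_background: int = 5
    target_factor: float = 4.0
    background_factor: float = 3.0
    nonspecific_factor: float = 0.2
    reads_per_condition: int = 1000
    read_length: int = 250
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.0
    # select stage
    control_max_cpm: float = 0.0
    positive_min_cpm: float = 1.0
    # embed stage
    kmer_k: int = 5
    n_neighbors: int = 15
    embed_seed: int = 42

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("at least one stage must be enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Per-run record of stage outputs, hashes, seeds and versions."""

    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"version": __version__, "python": sys.version.split()[0],
                           "stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_done(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        return all(Path(p).exists() and _sha256(Path(p)) == h
                   for p, h in entry["outputs"].items())

    def record(self, stage: str, outputs: list[Path], **extra) -> None:
        self.data["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs}, **extra}
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage; no
    partial stage output is recorded in the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = RunManifest(outdir / "run_manifest.json")
    design = (PanningDesign.from_yaml(config.design_path)
              if config.design_path else default_design())
    design.to_yaml(outdir / "design.yaml")

    enabled = [s for s in STAGES if s in config.stages]
    for stage in enabled:
        if resume and manifest.stage_done(stage):
            log.info("stage %s already complete; skipping", stage)
            continue
        log.info("running stage %s", stage)
        try:
            if stage == "synth":
                _stage_synth(config, design, outdir, manifest)
            elif stage == "repertoire":
                _stage_repertoire(config, design, outdir, manifest)
            elif stage == "select":
                _stage_select(config, design, outdir, manifest)
            elif stage == "embed":
                _stage_embed(config, outdir, manifest)
        except StageError:
            raise
        except Exception as exc:  # halt with stage name, never a silent partial
            raise StageError(stage, str(exc)) from exc
    return outdir


def _stage_synth(config, design, outdir, manifest):
    clones = make_repertoire(config.n_clones, seed=config.seed)
    truth = make_manifest(clones, design, n_target=config.n_target,
                          n_background=config.n_background,
                          target_factor=config.target_factor,
                          background_factor=config.background_factor,
                          nonspecific_factor=config.nonspecific_factor,
                          seed=config.seed)
    counts = simulate_panning(truth, design, config.reads_per_condition, seed=config.seed)
    truth_path = outdir / "truth_manifest.tsv"
    truth.to_tsv(truth_path)
    counts_path = outdir / "true_counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    fastq_dir = outdir / "fastq"
    paths = emit_reads(clones, counts, fastq_dir, read_length=config.read_length,
                       adapter=config.adapter, error_rate=config.error_rate,
                       seed=config.seed)
    outputs = [truth_path, counts_path]
    outputs += [Path(p) for pair in paths.values() for p in pair]
    manifest.record("synth", outputs, seed=config.seed)


def _stage_repertoire(config, design, outdir, manifest):
    clusters, counts = process_fastq_dir(str(outdir / "fastq"), design.condition_names,
                                         adapter=config.adapter)
    if clusters.empty:
        raise StageError("repertoire", "no reads processed")
    clusters_path = outdir / "clusters.tsv"
    write_cluster_table(clusters, clusters_path)
    rej_path = outdir / "rejections.tsv"
    counts.rejection_table().to_csv(rej_path, sep="\t", index=False)
    manifest.record("repertoire", [clusters_path, rej_path],
                    pairs_in=counts.pairs_in, merged=counts.merged,
                    translated=counts.translated, annotated=counts.annotated,
                    rejected=counts.n_rejected)


def _stage_select(config, design, outdir, manifest):
    from .repertoire import read_cluster_table

    clusters = read_cluster_table(outdir / "clusters.tsv")
    raw = clusters.drop(columns=["total_raw"])
    design = design.with_totals({c: int(raw[c].sum()) for c in raw.columns})
    matrix = normalize_cpm(raw, design)
    result = select_candidates(matrix, design, config.control_max_cpm,
                               config.positive_min_cpm)
    if len(result) == 0:
        raise StageError("select", "no clusters passed the selection rule")
    report = cluster_report(result)
    report_path = outdir / "selection_report.tsv"
    write_report(report, report_path)
    manifest.record("select", [report_path], n_selected=len(result),
                    control_max_cpm=config.control_max_cpm,
                    positive_min_cpm=config.positive_min_cpm)


def _stage_embed(config, outdir, manifest):
    from .repertoire import read_cluster_table
    from .selection import read_report

    clusters = read_cluster_table(outdir / "clusters.tsv")
    signatures = list(clusters.index)
    matrix = kmer_encode(signatures, k=config.kmer_k)
    embedding = embed_op(matrix, n_neighbors=config.n_neighbors, seed=config.embed_seed)
    coords_path = outdir / "embedding.tsv"
    embedding.coordinates.to_csv(coords_path, sep="\t")
    outputs = [coords_path]
    report_path = outdir / "selection_report.tsv"
    if report_path.exists():
        selected = [s for s in read_report(report_path).index if s in set(signatures)]
        if len(selected) >= 1:
            overlay = overlay_candidates(embedding, selected)
            overlay_path = outdir / "candidate_overlay.tsv"
            overlay.candidates.to_csv(overlay_path, sep="\t")
            outputs.append(overlay_path)
    manifest.record("embed", outputs, seed=config.embed_seed, k=config.kmer_k)
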