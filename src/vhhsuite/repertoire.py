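"""Repertoire processing: paired reads -> merged amplicons -> translated,
CDR-annotated VHH records -> non-redundant signature clusters.

The identity key for clustering is the VHH "signature": the three CDR
amino-acid sequences concatenated in order.  Two clones that differ only
in framework residues therefore collapse into one cluster.

Every stage is conservative about failure: a read pair that cannot be
merged, translated or annotated is returned as a :class:`Rejection` with
a machine-readable reason code and is counted, never silently dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

# Camelid heavy-chain-variable framework scaffold used as the default
# annotation scheme.  FR boundaries approximate the Chothia delimitation;
# the first nine FR1 residues double as the conserved "protein label"
# that fixes the reading frame.
DEFAULT_FR1 = "QVQLVESGGGLVQAGGSLRLSCAAS"
DEFAULT_FR2 = "WFRQAPGKEREFVA"
DEFAULT_FR3 = "RFTISRDNAKNTVYLQMNSLKPEDTAVYYCAA"
DEFAULT_FR4 = "WGQGTQVTVSS"
DEFAULT_FR1_ANCHOR = DEFAULT_FR1[:9]

REJECT_NO_OVERLAP = "no_overlap"
REJECT_NO_ANCHOR = "no_anchor"
REJECT_AMBIGUOUS_FRAME = "ambiguous_frame"
REJECT_INTERNAL_STOP = "internal_stop"
REJECT_UNANNOTATABLE = "unannotatable"


@dataclass(frozen=True)
class Rejection:
    """A record that failed a processing stage, with a reason code."""

    reason: str
    stage: str
    detail: str = ""


@dataclass(frozen=True)
class FrameworkScheme:
    """CDR delimitation rules: the four framework anchor sequences.

    A protein is annotatable when all four anchors occur once, in order,
    and tile the sequence together with the three CDR gaps between them.
    """

    fr1: str = DEFAULT_FR1
    fr2: str = DEFAULT_FR2
    fr3: str = DEFAULT_FR3
    fr4: str = DEFAULT_FR4

    @property
    def fr1_anchor(self) -> str:
        return self.fr1[:9]


@dataclass
class Annotation:
    """FR/CDR segmentation of a VHH protein (0-based half-open spans)."""

    protein: str
    spans: dict[str, tuple[int, int]]

    def segment(self, name: str) -> str:
        a, b = self.spans[name]
        return self.protein[a:b]

    @property
    def signature(self) -> str:
        return self.segment("cdr1") + self.segment("cdr2") + self.segment("cdr3")


@dataclass
class VHHRecord:
    nucleotide: str
    protein: str
    annotation: Annotation
    condition: str = ""

    @property
    def signature(self) -> str:
        return self.annotation.signature


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _strip_adapter(read: str, qual: Sequence[int], adapter: str):
    if adapter and read.startswith(adapter):
        read, qual = read[len(adapter):], qual[len(adapter):]
    # read-through into the far adapter on short inserts
    if adapter:
        tail = _revcomp(adapter)
        pos = read.find(tail)
        if pos >= 0:
            read, qual = read[:pos], qual[:pos]
    return read, qual


def trim_and_merge(
    forward: str,
    reverse: str,
    forward_qual: Sequence[int] | None = None,
    reverse_qual: Sequence[int] | None = None,
    adapter: str = "",
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
):
    """Adapter-trim a read pair and merge it over its 3' overlap.

    Returns the merged nucleotide string, or a :class:`Rejection` with
    reason ``no_overlap`` when no suffix/prefix alignment of at least
    ``min_overlap`` bases stays under the mismatch budget.  Mismatched
    overlap positions are resolved toward the higher-quality base.
    """
    fq = list(forward_qual) if forward_qual is not None else [40] * len(forward)
    rq = list(reverse_qual) if reverse_qual is not None else [40] * len(reverse)
    fwd, fq = _strip_adapter(forward, fq, adapter)
    rev, rq = _strip_adapter(reverse, rq, adapter)
    rc = _revcomp(rev)
    rcq = rq[::-1]

    f_arr = np.frombuffer(fwd.encode(), dtype=np.uint8)
    r_arr = np.frombuffer(rc.encode(), dtype=np.uint8)
    best = None
    for olap in range(min(len(fwd), len(rc)), min_overlap - 1, -1):
        diff = f_arr[len(fwd) - olap:] != r_arr[:olap]
        if int(diff.sum()) <= max_mismatch_frac * olap:
            best = (olap, np.nonzero(diff)[0])
            break
    if best is None:
        return Rejection(REJECT_NO_OVERLAP, "merge")

    olap, mism = best
    head = fwd[: len(fwd) - olap]
    consensus = list(fwd[len(fwd) - olap:])
    for i in mism:
        if rcq[i] > fq[len(fwd) - olap + i]:
            consensus[i] = rc[i]
    return head + "".join(consensus) + rc[olap:]


@dataclass
class TranslationResult:
    nucleotide: str  # coding-strand orientation
    protein: str
    strand: int  # +1 or -1
    frame: int  # 0..2 offset on the coding strand


def detect_frame_and_translate(merged: str, fr1_anchor: str = DEFAULT_FR1_ANCHOR):
    """Translate all six frames and pick the one containing the FR1 anchor.

    The VHH protein is taken from the anchor occurrence onward.  A stop
    codon after the anchor start is an ``internal_stop`` rejection; an
    anchor found in more than one frame is ``ambiguous_frame``.
    """
    if len(fr1_anchor) < 6:
        raise ValueError("FR1 anchor must be at least 6 aa")
    hits = []
    for strand, seq in ((1, merged), (-1, _revcomp(merged))):
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3 * len(fr1_anchor):
                continue
            prot = str(Seq(sub).translate())
            idx = prot.find(fr1_anchor)
            if idx >= 0:
                hits.append((strand, frame, seq, prot, idx))
    if not hits:
        return Rejection(REJECT_NO_ANCHOR, "translate")
    if len(hits) > 1:
        return Rejection(REJECT_AMBIGUOUS_FRAME, "translate")
    strand, frame, seq, prot, idx = hits[0]
    vhh = prot[idx:]
    if "*" in vhh:
        return Rejection(REJECT_INTERNAL_STOP, "translate")
    return TranslationResult(nucleotide=seq, protein=vhh, strand=strand, frame=frame)


def annotate_cdrs(protein: str, scheme: FrameworkScheme | None = None):
    """Segment a VHH protein into FR1..FR4 and CDR1..3 by anchor matching.

    The four framework anchors must occur in order; FR1 must start the
    protein and FR4 must end it so that the seven segments partition it.
    Anything else is an ``unannotatable`` rejection.
    """
    scheme = scheme or FrameworkScheme()
    frs = [("fr1", scheme.fr1), ("fr2", scheme.fr2), ("fr3", scheme.fr3), ("fr4", scheme.fr4)]
    spans: dict[str, tuple[int, int]] = {}
    cursor = 0
    for name, motif in frs:
        idx = protein.find(motif, cursor)
        if idx < 0:
            return Rejection(REJECT_UNANNOTATABLE, "annotate", f"missing {name}")
        spans[name] = (idx, idx + len(motif))
        cursor = idx + len(motif)
    if spans["fr1"][0] != 0 or spans["fr4"][1] != len(protein):
        return Rejection(REJECT_UNANNOTATABLE, "annotate", "segments do not tile protein")
    for cdr, left, right in (("cdr1", "fr1", "fr2"), ("cdr2", "fr2", "fr3"), ("cdr3", "fr3", "fr4")):
        spans[cdr] = (spans[left][1], spans[right][0])
    order = ["fr1", "cdr1", "fr2", "cdr2", "fr3", "cdr3", "fr4"]
    return Annotation(protein=protein, spans={k: spans[k] for k in order})


def collapse(records: pd.DataFrame | Iterable[VHHRecord]) -> pd.DataFrame:
    """Group annotated records into non-redundant signature clusters.

    Accepts either a long DataFrame with ``signature`` and ``condition``
    columns (an optional ``count`` column carries multiplicities) or an
    iterable of :class:`VHHRecord`.  Returns a wide table indexed by
    signature with one integer count column per condition plus
    ``total_raw``.  Record conservation holds: the sum of all counts
    equals the number of input records.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [{"signature": r.signature, "condition": r.condition} for r in records]
        )
    if records.empty:
        return pd.DataFrame(columns=["total_raw"]).rename_axis("signature")
    df = records.copy()
    if "count" not in df.columns:
        df["count"] = 1
    wide = (
        df.pivot_table(index="signature", columns="condition", values="count",
                       aggfunc="sum", fill_value=0)
        .astype(int)
    )
    wide.columns.name = None
    wide["total_raw"] = wide.sum(axis=1)
    return wide


@dataclass
class PipelineCounts:
    """Per-stage conservation ledger for one processing run."""

    pairs_in: int = 0
    merged: int = 0
    translated: int = 0
    annotated: int = 0
    rejections: list[dict] = field(default_factory=list)

    def reject(self, read_id: str, condition: str, rej: Rejection) -> None:
        self.rejections.append(
            {"read_id": read_id, "condition": condition, "stage": rej.stage,
             "reason": rej.reason, "detail": rej.detail}
        )

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def rejection_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejections,
                            columns=["read_id", "condition", "stage", "reason", "detail"])


def process_read_pairs(
    pairs: Iterable[tuple[str, str, str]],
    condition: str,
    adapter: str = "",
    scheme: FrameworkScheme | None = None,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    counts: PipelineCounts | None = None,
) -> tuple[list[VHHRecord], PipelineCounts]:
    """Run merge -> frame detection -> annotation over (id, fwd, rev) pairs."""
    scheme = scheme or FrameworkScheme()
    counts = counts or PipelineCounts()
    out: list[VHHRecord] = []
    for read_id, fwd, rev in pairs:
        counts.pairs_in += 1
        merged = trim_and_merge(fwd, rev, adapter=adapter, min_overlap=min_overlap,
                                max_mismatch_frac=max_mismatch_frac)
        if isinstance(merged, Rejection):
            counts.reject(read_id, condition, merged)
            continue
        counts.merged += 1
        trans = detect_frame_and_translate(merged, scheme.fr1_anchor)
        if isinstance(trans, Rejection):
            counts.reject(read_id, condition, trans)
            continue
        counts.translated += 1
        ann = annotate_cdrs(trans.protein, scheme)
        if isinstance(ann, Rejection):
            counts.reject(read_id, condition, ann)
            continue
        counts.annotated += 1
        out.append(VHHRecord(nucleotide=trans.nucleotide, protein=trans.protein,
                             annotation=ann, condition=condition))
    return out, counts


def process_fastq_dir(
    fastq_dir: str,
    conditions: Sequence[str],
    adapter: str = "",
    scheme: FrameworkScheme | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, PipelineCounts]:
    """Process ``<condition>_R1.fastq`` / ``_R2.fastq`` pairs into clusters."""
    counts = PipelineCounts()
    records: list[VHHRecord] = []
    for cond in conditions:
        r1 = os.path.join(fastq_dir, f"{cond}_R1.fastq")
        r2 = os.path.join(fastq_dir, f"{cond}_R2.fastq")
        if not (os.path.exists(r1) and os.path.exists(r2)):
            continue
        fwd = list(SeqIO.parse(r1, "fastq"))
        rev = list(SeqIO.parse(r2, "fastq"))
        pairs = [(f.id, str(f.seq), str(r.seq)) for f, r in zip(fwd, rev, strict=True)]
        recs, counts = process_read_pairs(pairs, cond, adapter=adapter, scheme=scheme,
                                          counts=counts, **kwargs)
        records.extend(recs)
    return collapse(records), counts


def write_cluster_table(clusters: pd.DataFrame, path: str) -> None:
    clusters.to_csv(path, sep="\t")


def read_cluster_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="signature")


def write_signature_fasta(clusters: pd.DataFrame, path: str) -> None:
    """FASTA of the non-redundant signatures, ids carrying cluster sizes."""
    with open(path, "w") as fh:
        for i, (sig, row) in enumerate(clusters.iterrows()):
            fh.write(f">cluster{i}|total={int(row['total_raw'])}\n{sig}\n")
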