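"""Hierarchical small-RNA annotation against reference ncRNA/mRNA sets.

Reads are matched against reference classes in a fixed priority order
(miRNA before tRNA before rRNA before other ncRNA before mRNA) with the
same mismatch tolerance used for genomic mapping; a read is assigned to
the highest-priority class containing a match.  Reads matching no
reference but mapping to the genome form the "intergenic" fraction —
the piRNA candidate pool used for cluster prediction.

Also provided: detection of 3' tRNA fragments (3' tRFs; reads whose 3'
terminus coincides with the mature tRNA 3' end including the
non-template CCA), and an arithmetical estimator of the genuine
primary-piRNA fraction from the 5' U composition of annotated versus
unannotated 24-29 nt reads.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pirnakit.align import Genome, filter_alignments, map_reads
from pirnakit.reads import CollapsedRead

DEFAULT_PRIORITY = {"miRNA": 0, "tRNA": 1, "rRNA": 2, "other_ncRNA": 3, "mRNA": 4}
INTERGENIC = "intergenic"
PIRNA_LENGTH_RANGE = (24, 29)


@dataclass
class ReferenceSet:
    """A FASTA reference class for hierarchical annotation."""

    class_name: str
    records: list[tuple[str, str]]  # (name, sequence)
    priority: int | None = None

    def __post_init__(self) -> None:
        if self.priority is None:
            self.priority = DEFAULT_PRIORITY.get(self.class_name, 99)
        self.records = [
            (n, s.upper().replace("U", "T")) for n, s in self.records
        ]

    @classmethod
    def from_fasta(cls, class_name: str, path, priority: int | None = None):
        from Bio import SeqIO

        recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        return cls(class_name, recs, priority)


@dataclass
class AnnotationRecord:
    """Class assignment of one collapsed read."""

    read: CollapsedRead
    assigned_class: str
    subtype: str = ""
    ref_name: str = ""


def annotate_reads(
    reads: Iterable[CollapsedRead],
    refs: Sequence[ReferenceSet],
    max_internal: int = 1,
    max_3p_nt: int = 2,
    max_mismatch: int = 3,
) -> list[AnnotationRecord]:
    """Assign each read to the highest-priority matching reference class.

    Matching uses the genomic-mapping tolerance (up to ``max_mismatch``
    total, at most ``max_internal`` internal and ``max_3p_nt``
    non-template 3' mismatches).  Reads matching no class are assigned
    "intergenic"; priorities with unique ranks are required.
    """
    reads = list(reads)
    prios = [r.priority for r in refs]
    if len(set(prios)) != len(prios):
        raise ValueError("reference priorities must be unique")
    remaining: dict[str, CollapsedRead] = {r.sequence: r for r in reads}
    out: list[AnnotationRecord] = []
    for ref in sorted(refs, key=lambda r: r.priority):
        if not ref.records:
            warnings.warn(f"reference class {ref.class_name!r} is empty; skipped")
            continue
        if not remaining:
            break
        seqs = dict(ref.records)
        if ref.class_name == "tRNA":
            # mature tRNAs carry a non-template 3' CCA; extend so 3' tRFs match
            seqs = {n: s + "CCA" for n, s in seqs.items()}
        ref_genome = Genome(seqs)
        alns = map_reads(list(remaining.values()), ref_genome, max_mismatch)
        mapped = filter_alignments(alns, max_3p_nt, max_internal)
        for a in mapped.alignments:
            if a.read.sequence in remaining:
                out.append(
                    AnnotationRecord(a.read, ref.class_name, ref_name=a.chrom)
                )
                del remaining[a.read.sequence]
    for r in remaining.values():
        out.append(AnnotationRecord(r, INTERGENIC))
    order = {r.sequence: i for i, r in enumerate(reads)}
    out.sort(key=lambda rec: order[rec.read.sequence])
    return out


def class_summary(records: Iterable[AnnotationRecord]) -> dict[str, dict]:
    """Count-weighted per-class read counts and percentages."""
    counts: dict[str, int] = {}
    total = 0
    for rec in records:
        counts[rec.assigned_class] = counts.get(rec.assigned_class, 0) + rec.read.count
        total += rec.read.count
    return {
        cls: {"reads": n, "percent": 100.0 * n / total if total else 0.0}
        for cls, n in sorted(counts.items(), key=lambda kv: -kv[1])
    }


def detect_3p_trfs(
    records: list[AnnotationRecord],
    trna_refs: ReferenceSet,
    max_internal: int = 1,
    max_3p_nt: int = 2,
    max_mismatch: int = 3,
) -> list[AnnotationRecord]:
    """Mark tRNA-matching reads as 3' tRFs.

    Each mature tRNA is extended with the non-template CCA before
    matching; a read is a 3' tRF iff it aligns sense within the extended
    tRNA with its 3' terminus exactly at the extended 3' end.  The
    subtype carries the isoacceptor name, e.g. "3p-tRF/tRNA-Gly-TCC".
    Records are updated in place and returned.
    """
    trna_records = [rec for rec in records if rec.assigned_class == "tRNA"]
    if not trna_records or not trna_refs.records:
        return records
    extended = {name: seq + "CCA" for name, seq in trna_refs.records}
    ref_genome = Genome(extended)
    reads = [rec.read for rec in trna_records]
    alns = map_reads(reads, ref_genome, max_mismatch)
    mapped = filter_alignments(alns, max_3p_nt, max_internal)
    hits: dict[str, str] = {}
    for a in mapped.alignments:
        if a.strand == "+" and a.end == len(extended[a.chrom]):
            hits.setdefault(a.read.sequence, a.chrom)
    for rec in trna_records:
        name = hits.get(rec.read.sequence)
        if name is not None:
            rec.subtype = f"3p-tRF/{name}"
    return records


@dataclass
class PrimaryFractionEstimate:
    """5'U-based estimate of the genuine primary-piRNA fraction.

    The unannotated 24-29 nt pool is modelled as a two-component mixture
    of genuine primary piRNAs (5'U fraction ``u_ref``, taken from
    cluster-mapped reads) and background (5'U fraction ``u_bg``, taken
    from annotated reads in the same length window); the observed 5'U
    fraction ``u_obs`` then determines the mixing proportion

        f_pi = (u_obs - u_bg) / (u_ref - u_bg), clamped to [0, 1].
    """

    u_obs: float
    u_bg: float
    u_ref: float
    f_pi: float
    estimated_primary_count: float
    undefined: bool = False


def _u_fraction(reads: Iterable[CollapsedRead], length_range) -> tuple[float, int]:
    lo, hi = length_range
    tot = u = 0
    for r in reads:
        if lo <= len(r.sequence) <= hi:
            tot += r.count
            if r.sequence[0] == "T":
                u += r.count
    return (u / tot if tot else math.nan), tot


def estimate_primary_fraction(
    records: Iterable[AnnotationRecord],
    clustered_reads: Iterable[CollapsedRead],
    length_range: tuple[int, int] = PIRNA_LENGTH_RANGE,
) -> PrimaryFractionEstimate:
    """Estimate the primary-piRNA fraction of the unannotated read pool.

    All fractions are count-weighted and restricted to ``length_range``
    (24-29 nt by default, the piRNA length window).  A degenerate
    reference (``u_ref == u_bg``) flags the estimate as undefined.
    """
    records = list(records)
    unannot = [r.read for r in records if r.assigned_class == INTERGENIC]
    annot = [r.read for r in records if r.assigned_class != INTERGENIC]
    u_obs, n_unannot = _u_fraction(unannot, length_range)
    u_bg, _ = _u_fraction(annot, length_range)
    u_ref, _ = _u_fraction(clustered_reads, length_range)
    if math.isnan(u_obs) or math.isnan(u_bg) or math.isnan(u_ref):
        raise ValueError(
            "need annotated, unannotated and clustered reads in the "
            f"{length_range} nt window"
        )
    if u_ref == u_bg:
        return PrimaryFractionEstimate(u_obs, u_bg, u_ref, math.nan, math.nan, True)
    f_pi = min(1.0, max(0.0, (u_obs - u_bg) / (u_ref - u_bg)))
    return PrimaryFractionEstimate(u_obs, u_bg, u_ref, f_pi, f_pi * n_unannot)


def write_annotation_tsv(records: Iterable[AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\tclass\tsubtype\treference\n")
        for rec in records:
            fh.write(
                f"{rec.read.sequence}\t{rec.read.count}\t{rec.assigned_class}\t"
                f"{rec.subtype}\t{rec.ref_name}\n"
            )


def write_class_summary_tsv(summary: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("class\treads\tpercent\n")
        for cls, d in summary.items():
            fh.write(f"{cls}\t{d['reads']}\t{d['percent']:.2f}\n")
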